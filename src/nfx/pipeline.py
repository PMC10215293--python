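"""End-to-end study orchestration.

``run_study`` turns a conforming dataset directory into a reproducible
bundle of tidy result tables: band-resolved connectivity and its group
contrasts, fNIRS stage means and task-activation contrasts, HRV features,
per-subject slopes and slope contrasts, subject-table delta contrasts
with baseline-homogeneity exclusions, correlation tables, and a
provenance record. Re-running on identical inputs and config yields
byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from . import stats as gstats
from .eeg import BANDS, connectivity_pipeline
from .fnirs import TaskSchedule, mbll_invert, reject_artifacts, stage_means
from .hrv import clean_rr, contrast_slopes, hrv_features, slopes_table
from .synth import StudyData

log = logging.getLogger("nfx")

__all__ = ["StudyConfig", "run_study", "write_study_dataset"]


@dataclass
class StudyConfig:
    dataset_dir: str
    out_dir: str
    epoch_len_s: float = 1.0
    amp_threshold_uv: float = 100.0
    coh_window_s: float = 10.0
    coh_overlap: float = 0.5
    spike_z: float = 5.0
    alpha: float = 0.05
    es_min: float = 0.75
    contrast_pairs: tuple[tuple[str, str], ...] = (("EMS", "control"), ("hypoxia", "control"))
    fnirs_baseline: tuple[float, float] = (0.06, 0.025)  # HbO0, Hb0 mmol/L for TSI
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("epoch_len_s", "amp_threshold_uv", "coh_window_s", "spike_z", "es_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        if "contrast_pairs" in doc:
            doc["contrast_pairs"] = tuple(tuple(p) for p in doc["contrast_pairs"])
        if "fnirs_baseline" in doc:
            doc["fnirs_baseline"] = tuple(doc["fnirs_baseline"])
        return cls(**doc)


def write_study_dataset(study: StudyData, directory: str | Path) -> Path:
    """Write an in-memory synthetic study in the conforming dataset layout."""
    directory = Path(directory)
    (directory / "eeg").mkdir(parents=True, exist_ok=True)
    (directory / "fnirs").mkdir(exist_ok=True)
    (directory / "rr").mkdir(exist_ok=True)
    study.subjects.to_csv(directory / "subjects.csv", index=False)
    study.table.to_csv(directory / "table.csv", index=False, float_format=nio.FLOAT_FMT)
    for rec in study.eeg:
        nio.write_eeg_csv(rec, directory / "eeg" / f"{rec.subject_id}_{rec.session}_{rec.condition}.csv")
    for od, _truth in study.fnirs:
        nio.write_fnirs(od, directory / "fnirs", f"{od.subject_id}_{od.session}")
    nio.write_schedule_yaml(study.schedule, directory / "fnirs" / "schedule.yaml")
    nio.write_rr_long(study.rr, directory / "rr" / "rr_long.csv")
    return directory


def _fc_deltas(fc: pd.DataFrame) -> pd.DataFrame:
    """Post-minus-pre connectivity deltas in the tidy delta schema."""
    wide = fc.pivot_table(
        index=["subject_id", "group", "condition", "method", "band", "pair", "kind"],
        columns="session", values="value", aggfunc="first",
    ).reset_index()
    for col in ("pre", "post"):
        if col not in wide:
            wide[col] = np.nan
    wide = wide.dropna(subset=["pre", "post"])
    wide["delta"] = wide["post"] - wide["pre"]
    wide["variable"] = (
        wide["pair"] + "|" + wide["band"] + "|" + wide["condition"] + "|" + wide["method"]
    )
    return wide


def _contrast_fc(deltas: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    cc = gstats.ContrastConfig(alpha=config.alpha, es_min=config.es_min,
                               contrast_pairs=config.contrast_pairs)
    tidy = deltas[["subject_id", "group", "variable", "delta"]]
    out = gstats.delta_contrasts(tidy, families={"fc": sorted(tidy["variable"].unique())}, config=cc)
    if out.empty:
        return out
    parts = out["variable"].str.split("|", expand=True)
    out = out.assign(channels=parts[0], band=parts[1], condition=parts[2], method=parts[3])
    cols = ["channels", "band", "condition", "method", "group", "raw_p", "adjusted_p",
            "effect_size", "power", "direction", "significant"]
    return out[cols].sort_values(["condition", "method", "band", "channels", "group"]).reset_index(drop=True)


def _anova_fc(deltas: pd.DataFrame) -> pd.DataFrame:
    rows = []
    keys = ["condition", "method", "band", "pair"]
    for key, sub in deltas[deltas["kind"] == "pair"].groupby(keys, sort=True):
        groups = [g["delta"].to_numpy() for _, g in sub.groupby("group", sort=True)]
        if len(groups) < 2 or any(len(g) < 3 for g in groups):
            continue
        f, p, degen = gstats.anova_connectivity(groups)
        rows.append(dict(zip(keys, key)) | dict(F=f, p=p, degenerate=degen))
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> dict:
    """Run every available modality of a dataset and write the result bundle.

    Missing modality directories are tolerated with a warning; schema
    violations raise with the offending file named. Returns the bundle as
    a dict of DataFrames (plus the provenance dict).
    """
    root = Path(config.dataset_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    warnings: list[str] = []
    provenance: dict = {
        # Paths are environment-specific and excluded so that re-runs on the
        # same inputs produce byte-identical provenance.
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()
                   if k not in ("dataset_dir", "out_dir")},
        "filter_spec": "order-4 zero-phase Butterworth band-pass",
        "bands": {b.name: [b.lo, b.hi] for b in BANDS.values()},
        "warnings": warnings,
    }
    subjects = pd.read_csv(root / "subjects.csv") if (root / "subjects.csv").exists() else None
    group_of = dict(zip(subjects["subject_id"], subjects["group"])) if subjects is not None else {}

    # ------------------------------------------------------------------ EEG
    eeg_dir = root / "eeg"
    if eeg_dir.is_dir() and any(eeg_dir.glob("*.csv")):
        fc_frames = []
        epoch_counts = {}
        for path in sorted(eeg_dir.glob("*.csv")):
            sid, session, condition = path.stem.split("_", 2)
            try:
                rec = nio.read_eeg_csv(path, subject_id=sid, group=group_of.get(sid, ""),
                                       session=session, condition=condition)
                results = connectivity_pipeline(
                    rec, epoch_len=config.epoch_len_s, amp_threshold=config.amp_threshold_uv,
                    coh_window_s=config.coh_window_s, coh_overlap=config.coh_overlap,
                )
            except ValueError as err:
                raise ValueError(f"{path}: {err}") from err
            epoch_counts[path.stem] = dict(kept=results[0].n_epochs_kept,
                                           rejected=results[0].n_epochs_rejected)
            fc_frames.append(nio.connectivity_to_frame(results))
        fc = pd.concat(fc_frames, ignore_index=True)
        bundle["connectivity"] = fc
        deltas = _fc_deltas(fc)
        bundle["connectivity_contrasts"] = _contrast_fc(deltas, config)
        bundle["connectivity_anova"] = _anova_fc(deltas)
        provenance["eeg_epochs"] = epoch_counts
    else:
        warnings.append("EEG modality absent; connectivity tables skipped")

    # ---------------------------------------------------------------- fNIRS
    fnirs_dir = root / "fnirs"
    if fnirs_dir.is_dir() and any(fnirs_dir.glob("*_meta.json")):
        schedule = (
            nio.read_schedule_yaml(fnirs_dir / "schedule.yaml")
            if (fnirs_dir / "schedule.yaml").exists()
            else TaskSchedule.two_back_default()
        )
        provenance["fnirs_schedule_total_s"] = schedule.total_duration
        provenance["fnirs_schedule_consistent_with_stated_total"] = schedule.consistent_with_stated_total
        mean_frames, mask_rows = [], []
        for meta_path in sorted(fnirs_dir.glob("*_meta.json")):
            stem = meta_path.name[: -len("_meta.json")]
            od = nio.read_fnirs(fnirs_dir, stem)
            hemo = mbll_invert(od, baseline=config.fnirs_baseline)
            hemo = reject_artifacts(hemo, spike_z=config.spike_z)
            mean_frames.append(stage_means(hemo, schedule))
            for ch in range(hemo.n_channels):
                mask_rows.append(
                    dict(subject_id=od.subject_id, session=od.session, channel=ch + 1,
                         masked_fraction=float(hemo.mask[ch].mean()),
                         unusable=bool(hemo.channel_unusable[ch]))
                )
        sm = pd.concat(mean_frames, ignore_index=True)
        sm.insert(2, "group", sm["subject_id"].map(group_of).fillna(""))
        bundle["fnirs_stage_means"] = sm
        bundle["fnirs_mask"] = pd.DataFrame(mask_rows)
        # Task-activation contrast: delta of block-stage means, post - pre.
        act = (
            sm[sm["stage_kind"] == "block"]
            .groupby(["subject_id", "group", "session", "channel", "measure"], sort=True)["mean"]
            .mean()
            .reset_index()
        )
        act["variable"] = act["measure"] + "_ch" + act["channel"].astype(str)
        tidy = act.rename(columns={"mean": "value"})[
            ["subject_id", "group", "session", "variable", "value"]
        ]
        fnirs_deltas, _ = gstats.compute_deltas(tidy)
        cc = gstats.ContrastConfig(alpha=config.alpha, es_min=config.es_min,
                                   contrast_pairs=config.contrast_pairs)
        bundle["fnirs_contrasts"] = gstats.delta_contrasts(
            fnirs_deltas, families={"fnirs": sorted(fnirs_deltas["variable"].unique())}, config=cc
        )
    else:
        warnings.append("fNIRS modality absent; hemodynamics tables skipped")

    # ------------------------------------------------------------------ HRV
    rr_path = root / "rr" / "rr_long.csv"
    if rr_path.exists():
        series = [s for s in nio.read_rr_long(rr_path) if s.daypart == "morning"]
        feat_rows = []
        for s in series:
            cleaned = clean_rr(s.rr, subject_id=s.subject_id, group=s.group,
                               date=s.date, daypart=s.daypart)
            if not cleaned.usable:
                continue
            feat_rows.append(
                dict(subject_id=s.subject_id, group=s.group, date=str(s.date),
                     **hrv_features(cleaned).to_dict())
            )
        feats = pd.DataFrame(feat_rows)
        day0 = feats.groupby("subject_id")["date"].transform("min")
        feats["day"] = (pd.to_datetime(feats["date"]) - pd.to_datetime(day0)).dt.days
        bundle["hrv_features"] = feats
        slopes = slopes_table(feats.drop(columns=["date"]))
        bundle["hrv_slopes"] = slopes
        contrasts = []
        for grp, ctrl in config.contrast_pairs:
            c = contrast_slopes(slopes, grp, control=ctrl, alpha=config.alpha, es_min=config.es_min)
            if not c.empty:
                contrasts.append(c)
        bundle["hrv_contrasts"] = (
            pd.concat(contrasts, ignore_index=True) if contrasts else pd.DataFrame()
        )
    else:
        warnings.append("RR modality absent; HRV tables skipped")

    # ---------------------------------------------------------- subject table
    table_path = root / "table.csv"
    if table_path.exists():
        table = pd.read_csv(table_path)
        variables = sorted(table["variable"].unique())
        excl_rows = []
        for var in variables:
            verdict = gstats.baseline_homogeneity(table, var, alpha=config.alpha)
            excl_rows.append(dict(variable=var, verdict=verdict["verdict"],
                                  excluded=verdict["excluded"]))
        exclusions = pd.DataFrame(excl_rows)
        bundle["baseline_exclusions"] = exclusions
        usable = exclusions.query("not excluded")["variable"].tolist()
        deltas, n_missing = gstats.compute_deltas(table[table["variable"].isin(usable)])
        provenance["table_missing_deltas"] = n_missing
        cc = gstats.ContrastConfig(alpha=config.alpha, es_min=config.es_min,
                                   contrast_pairs=config.contrast_pairs)
        bundle["table_contrasts"] = gstats.delta_contrasts(
            deltas, families={"table": usable}, config=cc
        )
        bundle["correlations"] = gstats.correlation_matrix(table, usable)
        if "connectivity" in bundle:
            fc_pairs = bundle["connectivity"]
            bundle["fc_correlations"] = gstats.fc_correlation_summary(
                fc_pairs[(fc_pairs["kind"] == "pair") & (fc_pairs["method"] == "COH")],
                table, usable, alpha=config.alpha,
            )
    else:
        warnings.append("subject table absent; delta/correlation tables skipped")

    for w in warnings:
        log.warning(w)
    for name, df in bundle.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format=nio.FLOAT_FMT)
    (out / "provenance.json").write_text(json.dumps(provenance, sort_keys=True, indent=1))
    bundle["provenance"] = provenance
    return bundle
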