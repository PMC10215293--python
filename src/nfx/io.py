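"""Reading and writing the dataset and result formats.

Dataset layout (one directory per study)::

    subjects.csv                       subject_id, group
    table.csv                          tidy subject table (pre/post scores)
    eeg/{subject}_{session}_{condition}.csv     time_s + one column per channel
    fnirs/{subject}_{session}_od{wavelength}.csv
    fnirs/{subject}_{session}_meta.json         fs, wavelengths, distances
    fnirs/schedule.yaml                         task timeline
    rr/rr_long.csv                     subject_id, group, date, daypart, rr_ms

EEG can also be read from EDF (one recording per file, labels in the
header) when mne is installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .eeg import CHANNELS_1020, ConnectivityResult, EegRecording
from .fnirs import OpticalDensitySeries, Stage, TaskSchedule
from .hrv import RrSeries

__all__ = [
    "read_eeg_csv", "write_eeg_csv", "read_eeg_edf",
    "read_fnirs", "write_fnirs",
    "read_schedule_yaml", "write_schedule_yaml",
    "read_rr_long", "write_rr_long",
    "connectivity_to_frame",
]

FLOAT_FMT = "%.10g"  # fixed text formatting so re-runs are byte-identical


def write_eeg_csv(rec: EegRecording, path: str | Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(rec.channel_labels):
        df[ch] = rec.samples[i]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_eeg_csv(
    path: str | Path, subject_id: str = "", group: str = "",
    session: str = "pre", condition: str = "open-eye",
) -> EegRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing 'time_s' column")
    channels = [c for c in df.columns if c != "time_s"]
    bad = [c for c in channels if c not in CHANNELS_1020]
    if bad:
        raise ValueError(f"{path}: unknown channel labels {bad}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: too short")
    fs = 1.0 / np.median(np.diff(t))
    return EegRecording(
        samples=df[channels].to_numpy().T, fs=float(round(fs, 6)),
        channel_labels=tuple(channels), subject_id=subject_id, group=group,
        session=session, condition=condition,
    )


def read_eeg_edf(path: str | Path, **labels) -> EegRecording:
    """Read one EDF recording (requires mne)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - environment dependent
        raise ImportError("EDF input needs the optional 'mne' dependency") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [ch for ch in raw.ch_names if ch in CHANNELS_1020]
    if not picks:
        raise ValueError(f"{path}: no 10-20 channels among {raw.ch_names}")
    data = raw.get_data(picks=picks) * 1e6  # volts -> µV
    return EegRecording(samples=data, fs=float(raw.info["sfreq"]),
                        channel_labels=tuple(picks), **labels)


def write_fnirs(od: OpticalDensitySeries, directory: str | Path, stem: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(od.od[od.wavelengths[0]].shape[1]) / od.fs
    for lam in od.wavelengths:
        df = pd.DataFrame({"time_s": t})
        for ch in range(od.n_channels):
            df[f"ch{ch + 1}"] = od.od[lam][ch]
        df.to_csv(directory / f"{stem}_od{lam}.csv", index=False, float_format=FLOAT_FMT)
    meta = {
        "fs": od.fs,
        "wavelengths": list(od.wavelengths),
        "distances_cm": list(map(float, od.distances_cm)),
        "subject_id": od.subject_id,
        "session": od.session,
    }
    (directory / f"{stem}_meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))


def read_fnirs(directory: str | Path, stem: str) -> OpticalDensitySeries:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    od = {}
    for lam in meta["wavelengths"]:
        df = pd.read_csv(directory / f"{stem}_od{lam}.csv")
        cols = [c for c in df.columns if c != "time_s"]
        od[int(lam)] = df[cols].to_numpy().T
    return OpticalDensitySeries(
        od=od, fs=float(meta["fs"]), distances_cm=np.asarray(meta["distances_cm"]),
        subject_id=meta.get("subject_id", ""), session=meta.get("session", "pre"),
    )


def write_schedule_yaml(schedule: TaskSchedule, path: str | Path) -> None:
    doc = {
        "stated_total_s": schedule.stated_total_s,
        "stages": [
            {"kind": s.kind, "onset": s.onset, "duration": s.duration, "label": s.label}
            for s in schedule.stages
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_schedule_yaml(path: str | Path) -> TaskSchedule:
    doc = yaml.safe_load(Path(path).read_text())
    stages = tuple(
        Stage(s["kind"], float(s["onset"]), float(s["duration"]), s.get("label", ""))
        for s in doc["stages"]
    )
    return TaskSchedule(stages, stated_total_s=doc.get("stated_total_s"))


def write_rr_long(series_list: Iterable[RrSeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for k, v in enumerate(s.rr):
            rows.append(
                dict(subject_id=s.subject_id, group=s.group, date=str(s.date),
                     daypart=s.daypart, beat_index=k, rr_ms=float(v))
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_rr_long(path: str | Path) -> list[RrSeries]:
    df = pd.read_csv(path)
    out = []
    keys = ["subject_id", "group", "date", "daypart"]
    for (sid, grp, date, daypart), sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("beat_index")
        out.append(
            RrSeries(rr=sub["rr_ms"].to_numpy(float), date=date, daypart=daypart,
                     subject_id=sid, group=grp)
        )
    return out


def connectivity_to_frame(results: Iterable[ConnectivityResult]) -> pd.DataFrame:
    """Tidy frame: one row per (pair or electrode group) value."""
    rows = []
    for r in results:
        base = dict(subject_id=r.subject_id, group=r.group, session=r.session,
                    condition=r.condition, method=r.method, band=r.band.name,
                    band_lo=r.band.lo, band_hi=r.band.hi)
        for (a, b), v in sorted(r.pair_values.items()):
            rows.append(dict(base, pair=f"{a}-{b}", kind="pair", value=v))
        for name, v in sorted(r.group_values.items()):
            rows.append(dict(base, pair=name, kind="group", value=v))
    return pd.DataFrame(rows)
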