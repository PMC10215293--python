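"""Heart-rate-variability features and longitudinal slope contrasts.

Daily five-minute morning RR-interval scans are cleaned with
physiological gates, reduced to time-domain, frequency-domain and
Poincare features (HRV Task-Force band conventions), and each metric's
per-subject temporal trend is summarised as the slope of an ordinary
least-squares fit against day index. Group trends are contrasted against
control with a Mann-Whitney test on per-subject slopes.

Feature definitions
-------------------
range_nni   max(RR) - min(RR), ms
nni_50      count of successive |dRR| > 50 ms
mean_hr     mean of instantaneous HR = 60000 / RR, bpm
min_hr      minimum of the 10-beat moving-average HR, bpm (robust to
            single ectopics)
vlf/lf/hf   band powers (ms^2) of the Welch spectrum of the cubic-spline
            resampled tachogram (4 Hz) in 0.003-0.04 / 0.04-0.15 /
            0.15-0.4 Hz; total_power is their sum
lfnu/hfnu   100 * lf/(lf+hf) and 100 * hf/(lf+hf)
csi         Poincare ellipse axis ratio SD2/SD1 (cardiac sympathetic
            index)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, signal as sps, stats as spstats

from . import stats as gstats

__all__ = [
    "FREQ_BANDS",
    "RrSeries",
    "HrvFeatures",
    "SlopeEstimate",
    "clean_rr",
    "hrv_features",
    "fit_daily_slope",
    "slopes_table",
    "contrast_slopes",
]

#: HRV Task-Force frequency bands, Hz.
FREQ_BANDS = {"vlf": (0.003, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}

RR_GATE_MS = (300.0, 2000.0)  # physiological RR window
RELATIVE_JUMP = 0.20  # exclusion threshold vs previous kept interval
MIN_USABLE_S = 60.0


@dataclass
class RrSeries:
    """Cleaned inter-beat interval sequence for one scan."""

    rr: np.ndarray  # ms
    date: object = None
    daypart: str = "morning"
    subject_id: str = ""
    group: str = ""
    n_removed_gate: int = 0
    n_removed_jump: int = 0
    usable: bool = True

    @property
    def duration_s(self) -> float:
        return float(self.rr.sum()) / 1000.0


@dataclass
class HrvFeatures:
    total_power: float
    vlf: float
    lf: float
    hf: float
    lfnu: float
    hfnu: float
    csi: float
    range_nni: float
    nni_50: int
    min_hr: float
    mean_hr: float
    vlf_low_confidence: bool = False
    degenerate_spectrum: bool = False

    def to_dict(self) -> dict:
        return {
            "total_power": self.total_power, "vlf": self.vlf, "lf": self.lf,
            "hf": self.hf, "lfnu": self.lfnu, "hfnu": self.hfnu, "csi": self.csi,
            "range_nni": self.range_nni, "nni_50": self.nni_50,
            "min_hr": self.min_hr, "mean_hr": self.mean_hr,
        }


@dataclass
class SlopeEstimate:
    subject_id: str
    metric: str
    slope: float
    intercept: float
    n_days: int
    ci_lo: float
    ci_hi: float


def clean_rr(
    rr_raw: Sequence[float],
    gate_ms: tuple[float, float] = RR_GATE_MS,
    relative_jump: float = RELATIVE_JUMP,
    min_usable_s: float = MIN_USABLE_S,
    **labels,
) -> RrSeries:
    """Gate implausible intervals; exclude (never interpolate) jump outliers.

    Intervals outside ``gate_ms`` are removed; an interval differing from
    the previous *kept* interval by more than ``relative_jump`` is excluded.
    A series with under ``min_usable_s`` of usable data is flagged unusable.
    """
    rr_raw = np.asarray(rr_raw, float)
    if rr_raw.size == 0:
        raise ValueError("empty RR series")
    gated = rr_raw[(rr_raw >= gate_ms[0]) & (rr_raw <= gate_ms[1])]
    n_gate = rr_raw.size - gated.size
    kept: list[float] = []
    n_jump = 0
    for v in gated:
        if kept and abs(v - kept[-1]) / kept[-1] > relative_jump:
            n_jump += 1
            continue
        kept.append(float(v))
    rr = np.asarray(kept)
    usable = rr.sum() / 1000.0 >= min_usable_s
    return RrSeries(
        rr=rr, n_removed_gate=n_gate, n_removed_jump=n_jump, usable=usable, **labels
    )


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    sel = (freqs >= lo) & (freqs < hi)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[sel], freqs[sel]))


def hrv_features(
    series: RrSeries,
    resample_hz: float = 4.0,
    welch_seg_s: float = 300.0,
) -> HrvFeatures:
    """Compute the feature set for one cleaned scan."""
    rr = series.rr
    if rr.size < 3:
        raise ValueError("need at least 3 intervals")
    hr = 60000.0 / rr
    window = min(10, rr.size)
    smoothed_hr = np.convolve(hr, np.ones(window) / window, mode="valid")
    drr = np.diff(rr)

    # Frequency domain on the evenly resampled tachogram.
    t_beats = np.cumsum(rr) / 1000.0
    duration = t_beats[-1] - t_beats[0]
    degenerate = duration <= 0 or np.ptp(rr) == 0
    if degenerate:
        vlf = lf = hf = 0.0
    else:
        t_grid = np.arange(t_beats[0], t_beats[-1], 1.0 / resample_hz)
        kind = "cubic" if rr.size >= 4 else "linear"
        tach = interpolate.interp1d(t_beats, rr, kind=kind)(t_grid)
        tach = tach - tach.mean()
        nperseg = min(len(tach), int(welch_seg_s * resample_hz))
        freqs, psd = sps.welch(tach, fs=resample_hz, nperseg=nperseg)
        vlf = _band_power(freqs, psd, *FREQ_BANDS["vlf"])
        lf = _band_power(freqs, psd, *FREQ_BANDS["lf"])
        hf = _band_power(freqs, psd, *FREQ_BANDS["hf"])
    total = vlf + lf + hf
    if lf + hf > 0:
        lfnu = 100.0 * lf / (lf + hf)
        hfnu = 100.0 * hf / (lf + hf)
    else:
        lfnu = hfnu = np.nan

    # Poincare: SD1 transverse, SD2 longitudinal; CSI = SD2/SD1.
    x, y = rr[:-1], rr[1:]
    sd1 = float(np.std((y - x) / np.sqrt(2), ddof=1)) if rr.size > 2 else 0.0
    sd2 = float(np.std((y + x) / np.sqrt(2), ddof=1)) if rr.size > 2 else 0.0
    csi = sd2 / sd1 if sd1 > 0 else np.nan

    return HrvFeatures(
        total_power=total, vlf=vlf, lf=lf, hf=hf, lfnu=lfnu, hfnu=hfnu, csi=csi,
        range_nni=float(np.ptp(rr)),
        nni_50=int(np.sum(np.abs(drr) > 50.0)),
        min_hr=float(smoothed_hr.min()),
        mean_hr=float(hr.mean()),
        vlf_low_confidence=duration < 1.0 / FREQ_BANDS["vlf"][0],
        degenerate_spectrum=bool(degenerate),
    )


def fit_daily_slope(
    day_values: pd.DataFrame, metric: str, subject_id: str = "", conf: float = 0.95
) -> SlopeEstimate | None:
    """OLS slope of a metric against day index; None with fewer than 3 days.

    ``day_values`` needs columns ``day`` and ``metric``.
    """
    sub = day_values[["day", metric]].dropna()
    if len(sub) < 3:
        return None
    x = sub["day"].to_numpy(float)
    y = sub[metric].to_numpy(float)
    res = spstats.linregress(x, y)
    tcrit = spstats.t.ppf(0.5 + conf / 2, len(sub) - 2)
    half = tcrit * res.stderr if np.isfinite(res.stderr) else 0.0
    return SlopeEstimate(
        subject_id=subject_id, metric=metric,
        slope=float(res.slope), intercept=float(res.intercept),
        n_days=len(sub), ci_lo=float(res.slope - half), ci_hi=float(res.slope + half),
    )


def slopes_table(features_by_scan: pd.DataFrame, metrics: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-subject slopes of each metric from a long table of daily features.

    Input columns: subject_id, group, day, plus one column per metric
    (morning scans only are expected — filter ``daypart`` upstream).
    """
    if metrics is None:
        metrics = [c for c in features_by_scan.columns if c not in ("subject_id", "group", "day", "date", "daypart")]
    rows = []
    for (subject, group), sub in features_by_scan.groupby(["subject_id", "group"], sort=True):
        for metric in metrics:
            est = fit_daily_slope(sub, metric, subject_id=subject)
            if est is None:
                continue
            rows.append(
                dict(subject_id=subject, group=group, metric=metric,
                     slope=est.slope, intercept=est.intercept, n_days=est.n_days,
                     ci_lo=est.ci_lo, ci_hi=est.ci_hi)
            )
    return pd.DataFrame(rows)


def contrast_slopes(
    slopes: pd.DataFrame,
    group: str,
    control: str = "control",
    alpha: float = 0.05,
    es_min: float = 0.75,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mann-Whitney contrast of per-subject slopes, one row per metric.

    Mirrors the reporting schema Parameter / Group / Type of Change /
    p-Value / Effect Size, with Holm-adjusted p over the metric family and
    analytic post-hoc power attached. Direction follows the sign of the
    group-minus-control median slope.
    """
    if metrics is None:
        metrics = sorted(slopes["metric"].unique())
    rows = []
    for metric in metrics:
        a = slopes.query("metric == @metric and group == @group")["slope"].to_numpy()
        b = slopes.query("metric == @metric and group == @control")["slope"].to_numpy()
        if len(a) < 3 or len(b) < 3:
            continue
        p, direction, tie = gstats.mannwhitney_contrast(a, b)
        d, d_flag = gstats.effect_size_d(a, b)
        power = gstats.posthoc_power(d, len(a), len(b), alpha) if np.isfinite(d) else np.nan
        rows.append(
            dict(parameter=metric, group=group, raw_p=p,
                 effect_size=d, power=power,
                 type_of_change={1: "Increase", -1: "Decrease", 0: "None"}[direction],
                 tie_flag=tie, es_flag=d_flag, n_group=len(a), n_control=len(b))
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["adjusted_p"] = gstats.holm_adjust(out["raw_p"].to_numpy())
    out["significant"] = (out["adjusted_p"] <= alpha) & (out["effect_size"] > es_min)
    return out
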