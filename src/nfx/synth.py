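"""Synthetic multimodal data with planted ground truth.

Every analysis module in this package has a matching generator here
whose output carries a known structure the estimators must recover:
EEG with narrowband couplings at a fixed phase lag, fNIRS optical
density forward-modelled through the Beer-Lambert system from known
hemoglobin time courses, RR series with planted LF/HF spectral balance
and per-day drifts, and subject tables with planted pre/post effect
sizes and Spearman structure via a Gaussian copula. A fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eeg import BANDS, CHANNELS_1020, Band, EegRecording, _bandpass_array
from .fnirs import (
    DEFAULT_DISTANCE_CM,
    OpticalDensitySeries,
    TaskSchedule,
    forward_mbll,
)
from .hrv import RrSeries

__all__ = [
    "Coupling",
    "EegGenSpec",
    "FnirsGenSpec",
    "RrGenSpec",
    "TableVariable",
    "TableGenSpec",
    "gen_eeg",
    "gen_fnirs",
    "gen_rr",
    "gen_table",
    "gen_study",
    "StudyData",
]


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-power noise (FFT-shaped white noise)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    spec[0] = 0
    spec[1:] /= np.sqrt(freqs[1:])
    out = np.fft.irfft(spec, n)
    return out / out.std()


# ---------------------------------------------------------------------------
# EEG


@dataclass(frozen=True)
class Coupling:
    """A shared narrowband component between two channels.

    ``phase_lag`` (rad, in (-pi, pi]) is the constant phase by which the
    first channel leads the second; ``strength`` in [0, 1] scales the
    shared component's amplitude relative to ``EegGenSpec.signal_rms``.
    """

    pair: tuple[str, str]
    band: str
    phase_lag: float
    strength: float

    def __post_init__(self) -> None:
        if not (-np.pi < self.phase_lag <= np.pi):
            raise ValueError("phase_lag must lie in (-pi, pi]")
        if not (0 <= self.strength <= 1):
            raise ValueError("strength must lie in [0, 1]")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")


@dataclass
class EegGenSpec:
    fs: float = 125.0
    duration_s: float = 180.0
    couplings: tuple[Coupling, ...] = ()
    noise_sd: float = 10.0  # µV RMS per channel (1/f + white mixture)
    signal_rms: float = 10.0  # µV RMS of a full-strength shared component
    pink_fraction: float = 0.5
    artifact_epochs: tuple[int, ...] = ()
    artifact_amp: float = 150.0  # µV, exceeds the 100 µV rejection threshold
    seed: int = 0
    subject_id: str = "S00"
    group: str = "control"
    session: str = "pre"
    condition: str = "open-eye"


def gen_eeg(spec: EegGenSpec) -> EegRecording:
    """8-channel recording with planted narrowband phase-lagged couplings.

    Each coupling injects the same band-limited Gaussian process into both
    channels of its pair, the second rotated by ``phase_lag`` through the
    analytic signal, on top of independent 1/f + white noise. Artifact
    epochs receive a square excursion above the rejection threshold.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    idx = {ch: i for i, ch in enumerate(CHANNELS_1020)}
    x = np.empty((8, n))
    for ch in range(8):
        pink = _pink_noise(n, rng)
        white = rng.standard_normal(n)
        x[ch] = spec.noise_sd * (
            np.sqrt(spec.pink_fraction) * pink + np.sqrt(1 - spec.pink_fraction) * white
        )
    from scipy.signal import hilbert

    for c in spec.couplings:
        band = BANDS[c.band]
        carrier = _bandpass_array(rng.standard_normal(n), band, spec.fs)
        carrier /= carrier.std()
        analytic = hilbert(carrier)
        amp = c.strength * spec.signal_rms
        a, b = (idx[c.pair[0]], idx[c.pair[1]])
        x[a] += amp * carrier
        x[b] += amp * np.real(analytic * np.exp(-1j * c.phase_lag))
    spe = int(round(spec.fs))  # 1-s epoch grid for artifact placement
    for ep in spec.artifact_epochs:
        lo = ep * spe + spe // 4
        x[0, lo : lo + spe // 2] += spec.artifact_amp
    return EegRecording(
        samples=x, fs=spec.fs, channel_labels=CHANNELS_1020,
        condition=spec.condition, session=spec.session,
        subject_id=spec.subject_id, group=spec.group,
    )


# ---------------------------------------------------------------------------
# fNIRS


@dataclass
class FnirsGenSpec:
    n_channels: int = 8
    fs: float = 10.0
    schedule: TaskSchedule = field(default_factory=TaskSchedule.two_back_default)
    hbo_baseline: float = 0.060  # mmol/L, typical adult-cortex scale
    hb_baseline: float = 0.025
    block_amp_hbo: float = 0.004  # task-evoked HbO rise, mmol/L
    block_amp_hb: float = -0.0015  # task-evoked Hb dip
    response_tau_s: float = 5.0  # smoothing time constant of the response
    drift_amp: float = 0.0005  # slow physiological drift, mmol/L
    noise_sd: float = 0.001  # OD-unit white noise per wavelength
    spike_times_s: tuple[float, ...] = ()
    spike_amp: float = 0.05  # OD units
    distance_cm: float = DEFAULT_DISTANCE_CM
    seed: int = 0
    subject_id: str = "S00"
    session: str = "pre"


def _smooth_response(boxcar: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """Causal exponential smoothing, a minimal hemodynamic-response stand-in."""
    t = np.arange(0, 6 * tau_s, 1.0 / fs)
    kernel = np.exp(-t / tau_s)
    kernel /= kernel.sum()
    return np.convolve(boxcar, kernel)[: boxcar.size]


def gen_fnirs(spec: FnirsGenSpec) -> tuple[OpticalDensitySeries, dict]:
    """Forward-modelled OD series plus the hidden hemoglobin truth.

    The truth time courses are block-modulated boxcars (smoothed with an
    exponential response) plus a slow drift, per channel; OD is the exact
    Beer-Lambert forward model of the *changes* plus optional white noise
    and injected OD spikes. Returns (series, truth) where ``truth`` holds
    the absolute hbo/hb including baselines.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.schedule.total_duration * spec.fs))
    t = np.arange(n) / spec.fs
    boxcar = np.zeros(n)
    for st in spec.schedule.stages:
        if st.kind == "block":
            lo = int(round(st.onset * spec.fs))
            hi = int(round((st.onset + st.duration) * spec.fs))
            boxcar[lo:hi] = 1.0
    response = _smooth_response(boxcar, spec.fs, spec.response_tau_s)
    hbo = np.empty((spec.n_channels, n))
    hb = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        gain = 1.0 + 0.1 * ch / max(spec.n_channels - 1, 1)  # mild channel diversity
        drift = spec.drift_amp * np.sin(2 * np.pi * 0.01 * t + ch)
        hbo[ch] = spec.hbo_baseline + gain * spec.block_amp_hbo * response + drift
        hb[ch] = spec.hb_baseline + gain * spec.block_amp_hb * response - 0.3 * drift
    od = forward_mbll(
        hbo - spec.hbo_baseline, hb - spec.hb_baseline,
        distances_cm=spec.distance_cm, fs=spec.fs,
    )
    for lam in od.wavelengths:
        if spec.noise_sd > 0:
            od.od[lam] += spec.noise_sd * rng.standard_normal(od.od[lam].shape)
        for ts in spec.spike_times_s:
            k = int(round(ts * spec.fs))
            if 0 <= k < n:
                od.od[lam][:, k] += spec.spike_amp
    od.subject_id = spec.subject_id
    od.session = spec.session
    truth = {"hbo": hbo, "hb": hb, "baseline": (spec.hbo_baseline, spec.hb_baseline)}
    return od, truth


# ---------------------------------------------------------------------------
# RR / HRV


@dataclass
class RrGenSpec:
    n_days: int = 28
    scan_duration_s: float = 300.0
    mean_rr: float = 900.0  # ms
    lf_amp: float = 30.0  # ms, 0.1 Hz modulation
    hf_amp: float = 30.0  # ms, 0.25 Hz modulation
    noise_sd: float = 5.0  # ms white beat-to-beat noise
    mean_rr_drift: float = 0.0  # ms/day
    lf_amp_drift: float = 0.0  # ms/day
    hf_amp_drift: float = 0.0  # ms/day
    start_date: _dt.date = _dt.date(2022, 6, 1)
    daypart: str = "morning"
    seed: int = 0
    subject_id: str = "S00"
    group: str = "control"


def gen_rr(spec: RrGenSpec) -> list[RrSeries]:
    """One five-minute RR series per day with planted drifts and LF/HF tones.

    RR_k = mean_rr(day) + lf_amp(day) sin(2 pi 0.1 t_k)
         + hf_amp(day) sin(2 pi 0.25 t_k) + noise, with drifts applied
    linearly per day. Raises if the parameters can produce rr <= 0.
    """
    worst = (
        abs(spec.mean_rr) - abs(spec.lf_amp) - abs(spec.hf_amp)
        - spec.n_days * (abs(spec.mean_rr_drift) + abs(spec.lf_amp_drift) + abs(spec.hf_amp_drift))
        - 6 * spec.noise_sd
    )
    if worst <= 0:
        raise ValueError("spec admits nonpositive RR intervals")
    rng = np.random.default_rng(spec.seed)
    out = []
    for day in range(spec.n_days):
        mean_rr = spec.mean_rr + spec.mean_rr_drift * day
        lf_amp = spec.lf_amp + spec.lf_amp_drift * day
        hf_amp = spec.hf_amp + spec.hf_amp_drift * day
        rr, t = [], 0.0
        while t < spec.scan_duration_s:
            v = (
                mean_rr
                + lf_amp * np.sin(2 * np.pi * 0.1 * t)
                + hf_amp * np.sin(2 * np.pi * 0.25 * t)
                + spec.noise_sd * rng.standard_normal()
            )
            rr.append(v)
            t += v / 1000.0
        out.append(
            RrSeries(
                rr=np.asarray(rr), date=spec.start_date + _dt.timedelta(days=day),
                daypart=spec.daypart, subject_id=spec.subject_id, group=spec.group,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Subject table


@dataclass(frozen=True)
class TableVariable:
    """One pre/post variable with optional planted per-group delta effects.

    ``effects`` maps a group name to the planted post-minus-pre effect in
    Cohen's d units (relative to ``delta_sd``, which defaults to pre_sd);
    unlisted groups (incl. control) get a zero-mean delta.
    """

    name: str
    pre_mean: float
    pre_sd: float
    effects: Mapping[str, float] = field(default_factory=dict)
    delta_sd: float | None = None
    modality: str = "biochemistry"


@dataclass
class TableGenSpec:
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"EMS": 18, "hypoxia": 15, "control": 14}
    )
    variables: tuple[TableVariable, ...] = ()
    spearman: np.ndarray | None = None  # target pre-value Spearman structure
    seed: int = 0


def gen_table(spec: TableGenSpec) -> tuple[pd.DataFrame, dict]:
    """Tidy subject table (pre/post) with planted deltas and rank correlation.

    Pre values are drawn through a Gaussian copula whose latent Pearson
    correlation is 2 sin(pi rho_s / 6), so the requested Spearman structure
    holds in population for any (here normal) marginals. Deltas are
    independent normal with a planted d * delta_sd mean shift per group.
    Returns (tidy frame, truth).
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.variables)
    if k == 0:
        raise ValueError("need at least one variable")
    if spec.spearman is None:
        latent_r = np.eye(k)
    else:
        rho = np.asarray(spec.spearman, float)
        if rho.shape != (k, k):
            raise ValueError("spearman matrix shape must match variables")
        latent_r = 2 * np.sin(np.pi * rho / 6)
        np.fill_diagonal(latent_r, 1.0)
    eig = np.linalg.eigvalsh(latent_r)
    if eig.min() < -1e-10:
        raise ValueError("requested correlation matrix is not positive semi-definite")
    chol = np.linalg.cholesky(latent_r + 1e-12 * np.eye(k))
    rows = []
    truth_d = {v.name: dict(v.effects) for v in spec.variables}
    subj_counter = 0
    for grp in spec.group_sizes:  # insertion order: deterministic
        for _ in range(spec.group_sizes[grp]):
            subj_counter += 1
            sid = f"S{subj_counter:02d}"
            z = chol @ rng.standard_normal(k)
            for vi, var in enumerate(spec.variables):
                pre = var.pre_mean + var.pre_sd * z[vi]
                dsd = var.delta_sd if var.delta_sd is not None else var.pre_sd
                delta = var.effects.get(grp, 0.0) * dsd + dsd * rng.standard_normal()
                for session, value in (("pre", pre), ("post", pre + delta)):
                    rows.append(
                        dict(subject_id=sid, group=grp, session=session,
                             variable=var.name, value=float(value))
                    )
    table = pd.DataFrame(rows)
    truth = {
        "effects_d": truth_d,
        "spearman": None if spec.spearman is None else np.asarray(spec.spearman, float),
        "modality": {v.name: v.modality for v in spec.variables},
    }
    return table, truth


# ---------------------------------------------------------------------------
# Full study


@dataclass
class StudyData:
    """In-memory synthetic study mirroring the full acquisition layout."""

    subjects: pd.DataFrame  # subject_id, group
    eeg: list[EegRecording]
    fnirs: list[tuple[OpticalDensitySeries, dict]]
    schedule: TaskSchedule
    rr: list[RrSeries]
    table: pd.DataFrame
    table_truth: dict
    seed: int


DEFAULT_TABLE_VARIABLES: tuple[TableVariable, ...] = (
    TableVariable("lactate", 1.8, 0.5, {"hypoxia": 1.0}, modality="biochemistry"),
    TableVariable("MCV", 90.0, 4.0, {"hypoxia": 0.9}, modality="biochemistry"),
    TableVariable("lymphocytes", 2.2, 0.5, {"EMS": -0.9}, modality="biochemistry"),
    TableVariable("norepinephrine", 400.0, 90.0, {"EMS": -0.9}, modality="biochemistry"),
    TableVariable("BDNF", 25.0, 6.0, {}, modality="biochemistry"),
    TableVariable("creatinine", 85.0, 10.0, {}, modality="biochemistry"),
    TableVariable("reaction_time", 420.0, 45.0, {"EMS": 1.0}, modality="cognitive"),
    TableVariable("nonverbal_memory", 520.0, 60.0, {"EMS": 0.9}, modality="cognitive"),
    TableVariable("attention", 480.0, 55.0, {"EMS": -0.9}, modality="cognitive"),
    TableVariable("contextual_memory", 460.0, 50.0, {"hypoxia": 0.9}, modality="cognitive"),
    TableVariable("short_term_memory", 500.0, 55.0, {}, modality="cognitive"),
    TableVariable("cognitive_flexibility", 450.0, 50.0, {}, modality="cognitive"),
)


def gen_study(
    seed: int = 0,
    group_sizes: Mapping[str, int] | None = None,
    eeg_duration_s: float = 180.0,
    rr_days: int = 28,
    variables: Sequence[TableVariable] = DEFAULT_TABLE_VARIABLES,
) -> StudyData:
    """A full synthetic cohort with group-dependent planted changes.

    Planted structure (all recoverable by the analysis modules):

    * EEG: a frontal beta1 coupling whose strength *increases* post vs pre
      for the hypoxia group in the closed-eye state and an occipital gamma
      coupling that *decreases* post for the EMS group in the open-eye
      state; control is stationary.
    * fNIRS: the EMS group's task-evoked HbO amplitude grows post.
    * RR: hypoxia drifts toward shorter mean RR (higher min HR) and lower
      modulation amplitudes; EMS shifts the LF/HF balance toward LF.
    * Table: planted biochemistry/cognitive deltas per
      ``DEFAULT_TABLE_VARIABLES``.
    """
    rng = np.random.default_rng(seed)
    group_sizes = dict(group_sizes or {"EMS": 18, "hypoxia": 15, "control": 14})
    table_spec = TableGenSpec(group_sizes=group_sizes, variables=tuple(variables),
                              seed=int(rng.integers(2**31)))
    table, table_truth = gen_table(table_spec)
    subjects = table[["subject_id", "group"]].drop_duplicates().reset_index(drop=True)

    schedule = TaskSchedule.two_back_default()
    eeg_list: list[EegRecording] = []
    fnirs_list: list[tuple[OpticalDensitySeries, dict]] = []
    rr_list: list[RrSeries] = []
    for _, row in subjects.iterrows():
        sid, grp = row["subject_id"], row["group"]
        base_couplings = {
            "closed-eye": Coupling(("F3", "F4"), "beta1", np.pi / 3, 0.45),
            "open-eye": Coupling(("O1", "O2"), "gamma", np.pi / 4, 0.55),
        }
        for session in ("pre", "post"):
            for condition, coup in base_couplings.items():
                strength = coup.strength
                if session == "post":
                    if grp == "hypoxia" and condition == "closed-eye":
                        strength = min(1.0, strength + 0.35)
                    if grp == "EMS" and condition == "open-eye":
                        strength = max(0.0, strength - 0.35)
                eeg_list.append(
                    gen_eeg(
                        EegGenSpec(
                            duration_s=eeg_duration_s,
                            couplings=(replace(coup, strength=strength),),
                            seed=int(rng.integers(2**31)),
                            subject_id=sid, group=grp, session=session, condition=condition,
                        )
                    )
                )
            amp = 0.004
            if session == "post" and grp == "EMS":
                amp = 0.006
            od, truth = gen_fnirs(
                FnirsGenSpec(
                    schedule=schedule, block_amp_hbo=amp, noise_sd=0.001,
                    seed=int(rng.integers(2**31)), subject_id=sid, session=session,
                )
            )
            fnirs_list.append((od, truth))
        drifts = dict(mean_rr_drift=0.0, lf_amp_drift=0.0, hf_amp_drift=0.0)
        if grp == "hypoxia":
            drifts.update(mean_rr_drift=-2.0, lf_amp_drift=-0.4, hf_amp_drift=-0.4)
        elif grp == "EMS":
            drifts.update(lf_amp_drift=0.5, hf_amp_drift=-0.5)
        rr_list.extend(
            gen_rr(
                RrGenSpec(
                    n_days=rr_days, seed=int(rng.integers(2**31)),
                    subject_id=sid, group=grp, **drifts,
                )
            )
        )
    return StudyData(
        subjects=subjects, eeg=eeg_list, fnirs=fnirs_list, schedule=schedule,
        rr=rr_list, table=table, table_truth=table_truth, seed=seed,
    )
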