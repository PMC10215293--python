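"""EEG functional connectivity: coherence and phase lag index.

Raw 8-channel EEG (10–20 montage subset F3, F4, C3, C4, P3, P4, O1, O2,
recorded at 125 Hz against an A2 reference) is segmented into 1-s epochs,
amplitude-thresholded, band-filtered, and reduced to two pairwise
functional-connectivity measures:

* magnitude-squared coherence (COH), a Welch estimate
  ``|<S_xy>|^2 / (<S_xx> <S_yy>)`` averaged over the frequency bins of a
  band, computed in 10-s Hann windows with 50 % overlap;
* phase lag index (PLI), ``|<sign(dphi(t_k))>|`` over instantaneous
  analytic-signal phase differences of the band-filtered pair, which is 0
  for zero-lag (or pi-lag) coupling and 1 for a consistent nonzero lag.

Pairwise values are aggregated into the electrode groups used for
reporting: frontal (all pairs among F3, F4, C3, C4), interhemispheric
(C3-C4, P3-P4, C3-P4, C4-P3), sagittal/fronto-occipital (F3-O1, F4-O2,
F3-O2, F4-O1) and the grand average over all 28 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "CHANNELS_1020",
    "BANDS",
    "ELECTRODE_GROUPS",
    "Band",
    "EegRecording",
    "EpochSet",
    "ConnectivityResult",
    "NoUsableDataError",
    "segment_and_reject",
    "bandpass",
    "compute_coherence",
    "compute_pli",
    "pli_from_phase_diffs",
    "aggregate_groups",
    "connectivity_pipeline",
]

#: Canonical channel order for the 8-electrode montage.
CHANNELS_1020: tuple[str, ...] = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")


@dataclass(frozen=True)
class Band:
    """A frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: need 0 < lo < hi, got {self.lo}, {self.hi}")


#: Canonical band table (broadband included for whole-spectrum reporting).
BANDS: dict[str, Band] = {
    b.name: b
    for b in (
        Band("delta", 0.5, 4.0),
        Band("theta", 4.0, 8.0),
        Band("alpha", 8.0, 12.0),
        Band("beta1", 12.0, 18.0),
        Band("beta2", 18.0, 30.0),
        Band("gamma", 30.0, 48.0),
        Band("broadband", 0.5, 48.0),
    )
}


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered-pair key, ordered by montage position."""
    order = {ch: i for i, ch in enumerate(CHANNELS_1020)}
    return (a, b) if order.get(a, 99) <= order.get(b, 99) else (b, a)


#: Reporting pair sets. ``frontal`` is every unordered pair among the four
#: fronto-central electrodes; ``AVG`` (all 28 pairs) is handled separately.
ELECTRODE_GROUPS: dict[str, tuple[tuple[str, str], ...]] = {
    "frontal": tuple(combinations(("F3", "F4", "C3", "C4"), 2)),
    "interhemispheric": (("C3", "C4"), ("P3", "P4"), ("C3", "P4"), ("C4", "P3")),
    "sagittal": (("F3", "O1"), ("F4", "O2"), ("F3", "O2"), ("F4", "O1")),
}


class NoUsableDataError(ValueError):
    """All epochs of a recording were rejected."""

    def __init__(self, rejected_count: int):
        self.rejected_count = rejected_count
        super().__init__(f"no usable data: all {rejected_count} epochs exceeded the amplitude threshold")


@dataclass
class EegRecording:
    """Multichannel EEG voltage trace with acquisition labels.

    ``samples`` is (n_channels, n_samples) in microvolts.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    condition: str = "open-eye"
    session: str = "pre"
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels must match the number of rows in samples")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        unknown = set(self.channel_labels) - set(CHANNELS_1020)
        if unknown:
            raise ValueError(f"unknown channel labels: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length epochs surviving amplitude-based artifact rejection."""

    epochs: np.ndarray  # (n_kept, n_channels, samples_per_epoch)
    epoch_len: float
    kept_indices: np.ndarray
    rejected_count: int
    fs: float

    @property
    def n_kept(self) -> int:
        return self.epochs.shape[0]

    def contiguous_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive kept epochs as (first, last) epoch indices."""
        runs: list[tuple[int, int]] = []
        kept = self.kept_indices
        if kept.size == 0:
            return runs
        start = prev = int(kept[0])
        for idx in kept[1:]:
            idx = int(idx)
            if idx == prev + 1:
                prev = idx
            else:
                runs.append((start, prev))
                start = prev = idx
        runs.append((start, prev))
        return runs


@dataclass
class ConnectivityResult:
    """Band-resolved pairwise connectivity with electrode-group aggregates."""

    method: str  # "COH" | "PLI"
    band: Band
    pair_values: dict[tuple[str, str], float]
    group_values: dict[str, float]
    condition: str = "open-eye"
    session: str = "pre"
    subject_id: str = ""
    group: str = ""
    n_epochs_kept: int = 0
    n_epochs_rejected: int = 0


def segment_and_reject(
    rec: EegRecording, epoch_len: float = 1.0, amp_threshold: float = 100.0
) -> EpochSet:
    """Cut a recording into consecutive epochs and drop high-amplitude ones.

    Any epoch whose maximum absolute amplitude on *any* channel exceeds
    ``amp_threshold`` (µV) is dropped whole. A trailing partial window is
    discarded. Raises :class:`NoUsableDataError` if nothing survives.
    """
    spe = epoch_len * rec.fs
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError("epoch_len * fs must be an integer number of samples")
    spe = int(round(spe))
    n_epochs = rec.n_samples // spe
    if n_epochs == 0:
        raise NoUsableDataError(0)
    cut = rec.samples[:, : n_epochs * spe]
    epochs = cut.reshape(rec.samples.shape[0], n_epochs, spe).swapaxes(0, 1)
    peak = np.abs(epochs).max(axis=(1, 2))
    keep = peak <= amp_threshold
    kept_indices = np.flatnonzero(keep)
    rejected = int(n_epochs - kept_indices.size)
    if kept_indices.size == 0:
        raise NoUsableDataError(rejected)
    return EpochSet(
        epochs=epochs[keep],
        epoch_len=epoch_len,
        kept_indices=kept_indices,
        rejected_count=rejected,
        fs=rec.fs,
    )


def _band_sos(band: Band, fs: float, order: int = 4):
    if band.hi >= fs / 2:
        raise ValueError(f"band {band.name} upper edge {band.hi} Hz >= Nyquist {fs / 2} Hz")
    return sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def _bandpass_array(x: np.ndarray, band: Band, fs: float) -> np.ndarray:
    """Zero-phase (forward-backward) order-4 Butterworth band-pass."""
    return sps.sosfiltfilt(_band_sos(band, fs), x, axis=-1)


def bandpass(rec: EegRecording, band: Band) -> EegRecording:
    """Band-filter every channel with a zero-phase Butterworth filter.

    Zero-phase filtering matters here: phase distortion would corrupt the
    phase-difference statistics the PLI is built on.
    """
    return EegRecording(
        samples=_bandpass_array(rec.samples, band, rec.fs),
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        condition=rec.condition,
        session=rec.session,
        subject_id=rec.subject_id,
        group=rec.group,
    )


class _SpectralAccumulator:
    """Accumulates Welch cross/auto spectra over windows drawn from data runs.

    Windows are Hann-tapered segments of ``nperseg`` samples advancing by
    ``nperseg - noverlap``; runs shorter than one window contribute nothing.
    No detrending is applied (the EEG pipeline band-filters separately and
    coherence is a ratio, so per-window means only affect the 0 Hz bin).
    """

    def __init__(self, n_series: int, fs: float, nperseg: int, noverlap: int):
        if not 0 <= noverlap < nperseg:
            raise ValueError("need 0 <= noverlap < nperseg")
        self.fs = fs
        self.nperseg = nperseg
        self.step = nperseg - noverlap
        self.window = sps.get_window("hann", nperseg, fftbins=True)
        self.freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
        self.n_windows = 0
        self._spec_sum = np.zeros((n_series, n_series, self.freqs.size), dtype=complex)

    def add_run(self, data: np.ndarray) -> None:
        """``data``: (n_series, n_samples) synchronous segment."""
        n = data.shape[1]
        for start in range(0, n - self.nperseg + 1, self.step):
            seg = data[:, start : start + self.nperseg] * self.window
            fx = np.fft.rfft(seg, axis=1)
            self._spec_sum += fx[:, None, :] * np.conj(fx[None, :, :])
            self.n_windows += 1

    def coherence(self) -> np.ndarray:
        """(n_series, n_series, n_freqs) magnitude-squared coherence."""
        if self.n_windows < 2:
            raise ValueError(
                "coherence needs at least 2 windows "
                f"(got {self.n_windows}; a single window always yields 1)"
            )
        s = self._spec_sum / self.n_windows
        auto = np.real(np.einsum("iif->if", s))
        denom = auto[:, None, :] * auto[None, :, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(s) ** 2 / denom
        return coh

    def band_mean(self, coh: np.ndarray, band: Band) -> np.ndarray:
        sel = (self.freqs >= band.lo) & (self.freqs <= band.hi)
        if not sel.any():
            raise ValueError(f"no frequency bins inside band {band.name}")
        return coh[..., sel].mean(axis=-1)


def compute_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: Band,
    window_len: float = 10.0,
    overlap: float = 0.5,
) -> float:
    """Band-averaged Welch magnitude-squared coherence of two signals.

    ``|<S_xy>|^2 / (<S_xx> <S_yy>)`` with Hann windows of ``window_len``
    seconds and fractional ``overlap``, averaged over the frequency bins in
    ``band``. Raises if fewer than two windows fit.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    nperseg = int(round(window_len * fs))
    acc = _SpectralAccumulator(2, fs, nperseg, int(round(nperseg * overlap)))
    acc.add_run(np.vstack([x, y]))
    value = float(acc.band_mean(acc.coherence(), band)[0, 1])
    # Clip round-off excursions just above 1 from the ratio of averaged spectra.
    return min(max(value, 0.0), 1.0)


def pli_from_phase_diffs(dphi: np.ndarray) -> float:
    """PLI of a series of phase differences: ``|<sign(wrap(dphi))>|``.

    ``dphi`` is wrapped to (-pi, pi]; exact zeros contribute 0 to the mean.
    """
    dphi = np.asarray(dphi, float)
    if dphi.size == 0:
        raise ValueError("empty phase-difference series")
    wrapped = np.angle(np.exp(1j * dphi))
    return abs(float(np.mean(np.sign(wrapped))))


def compute_pli(x: np.ndarray, y: np.ndarray) -> float:
    """Phase lag index of two band-limited signals.

    Instantaneous phases come from the analytic (Hilbert) signal; the PLI is
    the absolute mean sign of the wrapped phase differences. 0 means no
    coupling or a lag centred on multiples of pi; 1 means a consistent
    nonzero lag.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size == 0:
        raise ValueError("empty signal")
    dphi = np.angle(sps.hilbert(x)) - np.angle(sps.hilbert(y))
    return pli_from_phase_diffs(dphi)


def aggregate_groups(
    pair_values: Mapping[tuple[str, str], float],
    extra_groups: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> dict[str, float]:
    """Mean connectivity over the reporting electrode groups.

    Returns frontal / interhemispheric / sagittal means plus ``AVG`` (all 28
    unordered pairs). ``extra_groups`` lets callers define additional
    user-supplied pair sets (e.g. per-hemisphere labels). A missing pair is
    an error naming the pair.
    """
    values = {_norm_pair(*k): float(v) for k, v in pair_values.items()}

    def mean_over(pairs: Iterable[tuple[str, str]], label: str) -> float:
        out = []
        for a, b in pairs:
            key = _norm_pair(a, b)
            if key not in values:
                raise KeyError(f"group '{label}' needs pair {key} but it is missing")
            out.append(values[key])
        return float(np.mean(out))

    groups = dict(ELECTRODE_GROUPS)
    if extra_groups:
        groups.update({k: tuple(v) for k, v in extra_groups.items()})
    result = {name: mean_over(pairs, name) for name, pairs in groups.items()}
    result["AVG"] = mean_over(combinations(CHANNELS_1020, 2), "AVG")
    return result


def _run_slices(epoch_set: EpochSet) -> list[tuple[int, int]]:
    """Sample ranges of the original recording covered by contiguous kept runs."""
    spe = int(round(epoch_set.epoch_len * epoch_set.fs))
    return [(first * spe, (last + 1) * spe) for first, last in epoch_set.contiguous_runs()]


def connectivity_pipeline(
    rec: EegRecording,
    methods: Sequence[str] = ("COH", "PLI"),
    bands: Mapping[str, Band] = BANDS,
    epoch_len: float = 1.0,
    amp_threshold: float = 100.0,
    coh_window_s: float = 10.0,
    coh_overlap: float = 0.5,
    boundary_trim_s: float = 0.5,
    extra_groups: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> list[ConnectivityResult]:
    """Full per-recording connectivity analysis.

    1-s segmentation and 100 µV rejection come first; estimation then uses
    only maximal contiguous runs of kept epochs. Coherence windows (10 s,
    50 % overlap) are drawn within runs, so runs shorter than one window
    contribute none. For PLI each run is band-filtered and Hilbert-
    transformed separately, ``boundary_trim_s`` is discarded at each run
    edge to suppress filter/analytic-signal edge effects, and the signed
    phase differences are pooled over runs.
    """
    for m in methods:
        if m not in ("COH", "PLI"):
            raise ValueError(f"unknown method {m!r}")
    try:
        epoch_set = segment_and_reject(rec, epoch_len, amp_threshold)
    except NoUsableDataError as err:
        raise NoUsableDataError(err.rejected_count) from err
    slices = _run_slices(epoch_set)
    n_ch = len(rec.channel_labels)
    labels = rec.channel_labels
    meta = dict(
        condition=rec.condition,
        session=rec.session,
        subject_id=rec.subject_id,
        group=rec.group,
        n_epochs_kept=epoch_set.n_kept,
        n_epochs_rejected=epoch_set.rejected_count,
    )
    results: list[ConnectivityResult] = []

    if "COH" in methods:
        nperseg = int(round(coh_window_s * rec.fs))
        acc = _SpectralAccumulator(n_ch, rec.fs, nperseg, int(round(nperseg * coh_overlap)))
        for lo, hi in slices:
            acc.add_run(rec.samples[:, lo:hi])
        try:
            coh = acc.coherence()
        except ValueError as err:
            raise ValueError(f"COH stage failed: {err}") from err
        for band in bands.values():
            band_coh = np.clip(acc.band_mean(coh, band), 0.0, 1.0)
            pair_values = {
                _norm_pair(labels[i], labels[j]): float(band_coh[i, j])
                for i, j in combinations(range(n_ch), 2)
            }
            results.append(
                ConnectivityResult(
                    method="COH",
                    band=band,
                    pair_values=pair_values,
                    group_values=aggregate_groups(pair_values, extra_groups),
                    **meta,
                )
            )

    if "PLI" in methods:
        trim = int(round(boundary_trim_s * rec.fs))
        for band in bands.values():
            phases_per_run: list[np.ndarray] = []
            for lo, hi in slices:
                seg = rec.samples[:, lo:hi]
                if seg.shape[1] <= 2 * trim + 1:
                    continue
                filt = _bandpass_array(seg, band, rec.fs)
                ph = np.angle(sps.hilbert(filt, axis=-1))
                phases_per_run.append(ph[:, trim : ph.shape[1] - trim or None])
            if not phases_per_run:
                raise ValueError(f"PLI stage failed: no run long enough after boundary trimming ({band.name})")
            pair_values = {}
            for i, j in combinations(range(n_ch), 2):
                dphi = np.concatenate([ph[i] - ph[j] for ph in phases_per_run])
                pair_values[_norm_pair(labels[i], labels[j])] = pli_from_phase_diffs(dphi)
            results.append(
                ConnectivityResult(
                    method="PLI",
                    band=band,
                    pair_values=pair_values,
                    group_values=aggregate_groups(pair_values, extra_groups),
                    **meta,
                )
            )
    return results
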