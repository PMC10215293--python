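# Methods

`nfx` re-implements, as a reusable and tested pipeline, a multimodal
pre/post intervention-assessment analysis: resting-state EEG functional
connectivity, task fNIRS hemodynamics, longitudinal heart-rate-variability
trends, and a group-delta statistical framework comparing two training
interventions (interval normobaric hypoxic training and electrical muscle
stimulation) against a control group. Because studies of this design
typically leave their human data undeposited, the package ships synthetic
generators that plant known structure in every modality; validation rests
on recovering that structure, on analytic fixed points, and on
independently coded estimator oracles.

## EEG functional connectivity

Recordings are 8-channel (F3, F4, C3, C4, P3, P4, O1, O2; 10–20 system,
A2 reference, consumed as recorded) at 125 Hz, 3 min per condition
(open/closed eyes), pre and post.

**Preprocessing.** The trace is cut into consecutive non-overlapping 1-s
epochs starting at sample 0; any epoch whose absolute amplitude exceeds
100 µV on any channel is dropped whole; a trailing partial window is
discarded. If nothing survives, a "no usable data" error carries the
rejected count. Band filtering uses an order-4 Butterworth applied
forward–backward (zero phase): phase distortion would corrupt the
phase-difference statistics below. Bands: delta 0.5–4, theta 4–8, alpha
8–12, beta-1 12–18, beta-2 18–30, gamma 30–48 Hz, plus a broadband
0.5–48 Hz channel through the same machinery.

**Coherence.** Magnitude-squared coherence per pair,
`|<S_xy>|^2 / (<S_xx><S_yy>)`, estimated Welch-style in 10-s Hann windows
with 50 % overlap and averaged over the frequency bins inside each band
(window edges inclusive). No per-window detrending is applied; coherence
is a spectral ratio and the bands start above DC. Fewer than two windows
is an error — a single window always yields 1. Windows are drawn only
from maximal contiguous runs of artifact-free epochs, so a run shorter
than 10 s contributes nothing; this resolves the tension between 1-s
rejection resolution and 10-s spectral windows.

**Phase lag index.** `PLI = |<sign(Δφ(t_k))>|` over instantaneous phase
differences of the band-filtered pair, with phases from the
analytic-signal (Hilbert) representation and Δφ wrapped to (−π, π].
`sign(0)` contributes 0. PLI is 0 for no coupling or coupling centred on
multiples of π (hence insensitive to zero-lag, volume-conduction-like
dependence) and 1 for a consistent nonzero lag. In the pipeline, phases
are computed per contiguous run and 0.5 s is trimmed at each run boundary
to suppress filter/Hilbert edge effects; signed differences are pooled
across runs (pooled-samples rather than per-epoch averaging — the
estimator variance is lower and the two coincide for clean data).

**Aggregation.** Reported electrode groups are means of pair values:
interhemispheric = {C3-C4, P3-P4, C3-P4, C4-P3}; sagittal
(fronto-occipital, "FO") = {F3-O1, F4-O2, F3-O2, F4-O1}; frontal = all 6
unordered pairs among {F3, F4, C3, C4} (the symmetric, parameter-free
reading of a group defined only by its electrodes); AVG = all 28 pairs.
Additional labels (e.g. per-hemisphere "Left"/"Right") can be supplied as
user-defined pair sets.

## fNIRS hemodynamics

Two-wavelength (770/850 nm) optical-density change series from an
8-channel prefrontal array at 10 Hz are inverted per sample through the
modified Beer–Lambert system

    ΔOD(λ) = d · DPF(λ) · [ε_HbO(λ) ΔHbO + ε_Hb(λ) ΔHb]

using decadic molar extinction coefficients from the standard compiled
hemoglobin spectra (770 nm: 0.650 / 1.3119; 850 nm: 1.058 / 0.6913, in
1/(mmol/L·cm)), DPF 6.0 at both wavelengths, and a 2.5 cm source–detector
separation (source at the centre of a 5-cm-diagonal square array,
detectors at the vertices). All three are overridable — only the
wavelengths are fixed by the acquisition. The module computes
concentration *changes*; an optional (HbO₀, Hb₀) baseline offset supports
TSI on absolute-like values. HbT = HbO + Hb and TSI = 100·HbO/HbT are
formed per sample, TSI being undefined (and masked) where HbT ≤ 0.

Motion/muscle artifacts are spike-like: a sample is masked when the
robust z-score (median/MAD) of the first difference of HbO or Hb exceeds
5; both samples adjoining a flagged difference are masked, and a channel
more than half masked is excluded outright. Stage means are unweighted
arithmetic means of unmasked samples over the working-memory (2-back)
timeline: a leading rest, then 5 blocks of 25 stimuli (1 s stimulus +
2 s pause) separated by 17 s pauses. The per-stimulus arithmetic gives
443 s of task, which contradicts the separately stated 5 min 20 s total;
the schedule is fully configurable, the default encodes the per-stimulus
timings, and the inconsistency is surfaced in provenance output rather
than silently resolved.

## HRV trends

Daily five-minute morning RR scans are cleaned with physiological gates
(intervals outside 300–2000 ms removed; an interval differing from the
previous kept interval by more than 20 % excluded, never interpolated;
under 60 s of usable data flags the scan unusable). Features follow
Task-Force conventions: range NNI (max − min), NNI50 (successive
differences > 50 ms), mean HR, min HR (minimum of the 10-beat
moving-average HR, robust to single ectopics), band powers of the Welch
spectrum of the cubic-spline tachogram resampled at 4 Hz (VLF
0.003–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz; total power their sum; a scan
shorter than one VLF cycle flags VLF low-confidence), normalized powers
LFnu/HFnu (summing to 100 by construction), and CSI — the Poincaré
ellipse axis ratio SD2/SD1, the conventional cardiac sympathetic index.

Each metric's trend is the OLS slope against day index per subject
(≥3 days required; 95 % CI from the t distribution). Group trends are
contrasted against control by Mann–Whitney on per-subject slopes, with
Cohen's d, analytic power, direction (sign of the group-minus-control
median slope), and Holm adjustment over the metric family. Per-subject
fitting with group-level comparison is the primary path; a pooled
group×day interaction regression is the documented alternative reading
and can be assembled from `slopes_table` inputs.

## Group-delta statistics

Per-subject deltas are post − pre (the direction consistent with the
reported signs of change). Shapiro–Wilk normality is evaluated and
reported per variable, but contrasts always use the two-sided
Mann–Whitney U (exact for small tie-free samples, tie-corrected normal
approximation otherwise) — matching a workflow in which some variables
fail normality. Holm step-down adjustment runs within one family per
modality × contrast pair (biochemistry, cognitive, HRV metrics, fNIRS
channels, FC variables), a granularity matching per-table reporting;
families are configurable. A contrast is *significant* only when the
adjusted p ≤ α (0.05) and Cohen's d on the deltas (pooled-SD, n−1
weights) exceeds the large-effect filter 0.75. Analytic post-hoc power
accompanies each contrast: two-sided two-sample t power via the
noncentral t with ncp = d√(n₁n₂/(n₁+n₂)) — the conventional power model
even though the test is Mann–Whitney; the mismatch costs MW a few
percent of power (asymptotic relative efficiency 3/π under normality)
and is accounted for in the calibration study below.

Baseline homogeneity of the three groups' pre-session values is screened
with pairwise two-sample Kolmogorov–Smirnov tests (Bonferroni over the 3
pairs) plus Tukey HSD; a variable failing either is excluded from
contrasts, mirroring the exclusion of variables that differ before the
intervention. Associations use Spearman ρ and Kendall τ on pre-session
values (pairwise complete, n ≥ 5), with an FC variant that counts, per
band and condition, the channel pairs whose connectivity correlates with
a score at α — the heatmap-shade quantity. Connectivity deltas
additionally get a one-way ANOVA across the three groups per
(pair, band, method, condition).

## Synthetic generators

The generators define the study conditions and return their ground truth
for recovery testing. Fixed seeds give bit-identical output.

* **EEG** — independent 1/f + white noise per channel (equal-power mix,
  10 µV RMS: 1/f gives realistic low-band PLI/COH floors), plus shared
  narrowband components: band-limited Gaussian carriers injected into
  both channels of a pair, the second rotated by a constant phase lag
  through the analytic signal. A full-strength component is 10 µV RMS.
  Artifact epochs receive a 150 µV square excursion. A consequence worth
  knowing: in 180 s the delta band holds few phase-decorrelation times,
  so its null PLI max over 28 pairs sits near 0.1 even with no coupling;
  faster bands sit well below.
* **fNIRS** — hemoglobin truth = baseline (0.060 / 0.025 mmol/L HbO/Hb,
  ≈ 70 % TSI) + block-modulated boxcar smoothed by a 5-s exponential
  response (HbO +0.004, Hb −0.0015 mmol/L at task) + slow 0.01 Hz drift;
  OD is the exact forward Beer–Lambert model of the changes plus 0.001
  OD white noise and optional injected spikes.
* **RR** — beat-by-beat construction RRₖ = mean RR + LF·sin(2π·0.1t) +
  HF·sin(2π·0.25t) + noise (defaults 900 ± 30/30 ms, 5 ms noise), with
  per-day linear drifts on the mean and the amplitudes.
* **Table** — pre values through a Gaussian copula (latent Pearson
  2·sin(πρ_s/6), so planted Spearman structure is exact in population);
  deltas independent normal with a planted d·σ_Δ mean shift per group.
  Default cohort: 18 / 15 / 14 subjects (EMS / hypoxia / control).

What the generators do *not* emulate: volume conduction and common
reference effects, non-stationary EEG rhythms, physiological fNIRS
confounds (Mayer waves, scalp blood flow), ectopic beats, and non-normal
score marginals. Passing the recovery suites therefore demonstrates
estimator and pipeline correctness under the assumed statistical
structure, not robustness to every property of real recordings.

## Calibration of the planted-effect study

The end-to-end check generates 1000 cohorts of 18 + 14 subjects with 20
variables, one carrying a planted delta of d = 1.2. Detection of the
planted variable is judged by the per-comparison Mann–Whitney test at
α = 0.05, and compared to the analytic noncentral-t power at the same α
(0.903 at n = 18/14): that is the pairing the power model describes, and
the observed rate (≈ 0.86–0.87) sits within the expected Mann–Whitney
efficiency loss. Family-wise error over the 19 null variables is judged
by the pipeline's full flag (Holm-adjusted p ≤ α and d > 0.75) and stays
below α. Judging detection by the Holm-adjusted flag against unadjusted
analytic power would compare two different tests and is structurally
uninformative (≈ 0.44 vs 0.90).

## Numerical and implementation choices

* Coherence values are clipped to [0, 1] against round-off excursions of
  the spectral ratio; the estimators otherwise guarantee the bounds.
* `scipy.stats.nct` can return NaN in the far lower tail at large
  noncentrality; that term (< 1e-28 where it matters) is set to 0.
* Constant inputs are reported as degenerate rather than erroring:
  Shapiro–Wilk on constants, all-tied Mann–Whitney (p = 1, tie flag),
  zero pooled SD (d undefined), zero within-group variance ANOVA
  (F = ∞ flag), zero-power spectra (LFnu/HFnu undefined).
* All result CSVs are written with a fixed float format and sorted
  iteration orders; provenance excludes paths and timestamps, so re-runs
  on identical inputs are byte-identical.
* Problem sizes in the test and acceptance runs are scaled to keep the
  suites fast (e.g. 30–60 s EEG records, 3–6 subjects per group for the
  orchestration and determinism checks, 200–1000 Monte-Carlo replicates)
  while the generator defaults remain the full study conditions
  (180-s recordings, 18/15/14 subjects, 28 days of scans).

## Known limitations

* The two-wavelength inversion is exact only up to the assumed extinction
  coefficients, DPF and path length; no partial-volume correction.
* Coherence windows use fixed 50 % overlap and Hann tapers; multitaper
  estimation is out of scope.
* Exact Mann–Whitney enumeration is used only where scipy's exact method
  applies (small, tie-free samples); otherwise the tie-corrected normal
  approximation.
* The EDF reader requires the optional `mne` dependency; CSV input is
  first-class.
* Causal discovery, source localization, re-referencing schemes and
  figure styling are out of scope.
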