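"""EEG segmentation, filtering, and connectivity estimators."""

import numpy as np
import pytest
from scipy import signal as sps

from nfx.eeg import (
    BANDS,
    CHANNELS_1020,
    EegRecording,
    NoUsableDataError,
    aggregate_groups,
    bandpass,
    compute_coherence,
    compute_pli,
    connectivity_pipeline,
    pli_from_phase_diffs,
    segment_and_reject,
)
from conftest import direct_dft_coherence


def _rec(samples, fs=125.0, labels=None):
    labels = labels or CHANNELS_1020[: samples.shape[0]]
    return EegRecording(samples=samples, fs=fs, channel_labels=labels)


class TestSegmentAndReject:
    def test_clean_recording_keeps_every_epoch(self, rng):
        rec = _rec(rng.normal(0, 10, (2, 180 * 125)))
        es = segment_and_reject(rec, epoch_len=1.0, amp_threshold=100.0)
        assert es.n_kept == 180
        assert es.rejected_count == 0

    def test_single_excursion_drops_exactly_that_epoch(self, rng):
        x = rng.normal(0, 10, (2, 180 * 125))
        x[1, 5 * 125 + 60] = 150.0  # one 150 µV sample inside epoch 5
        es = segment_and_reject(_rec(x))
        assert es.n_kept == 179
        assert 5 not in es.kept_indices
        assert es.rejected_count == 1

    def test_saturated_recording_raises_no_usable_data(self):
        rec = _rec(np.full((2, 180 * 125), 200.0))
        with pytest.raises(NoUsableDataError) as err:
            segment_and_reject(rec)
        assert err.value.rejected_count == 180

    def test_trailing_partial_window_is_discarded(self, rng):
        rec = _rec(rng.normal(0, 10, (2, 10 * 125 + 60)))
        assert segment_and_reject(rec).n_kept == 10

    def test_contiguous_runs(self, rng):
        x = rng.normal(0, 10, (1, 20 * 125))
        x[0, 5 * 125 + 3] = 500.0
        runs = segment_and_reject(_rec(x)).contiguous_runs()
        assert runs == [(0, 4), (6, 19)]


class TestBandpass:
    def test_in_band_tone_amplitude_preserved(self):
        t = np.arange(0, 20, 1 / 125)
        rec = _rec(np.sin(2 * np.pi * 10 * t)[None, :])
        out = bandpass(rec, BANDS["alpha"]).samples[0][500:-500]
        assert abs(out.std() / rec.samples[0][500:-500].std() - 1) < 0.05

    def test_out_of_band_tone_attenuation_matches_design_response(self):
        # Oracle: the squared magnitude response of the designed filter at
        # 10 Hz bounds the tone's power gain through the gamma band.
        t = np.arange(0, 20, 1 / 125)
        rec = _rec(np.sin(2 * np.pi * 10 * t)[None, :])
        out = bandpass(rec, BANDS["gamma"]).samples[0][500:-500]
        measured_db = 20 * np.log10(out.std() / rec.samples[0][500:-500].std())
        sos = sps.butter(4, [30, 48], btype="bandpass", fs=125, output="sos")
        _, h = sps.sosfreqz(sos, worN=[10.0], fs=125)
        expected_db = 2 * 20 * np.log10(np.abs(h[0]))  # forward-backward: doubled
        assert measured_db <= -20
        assert measured_db == pytest.approx(expected_db, abs=3.0)

    def test_zero_signal_stays_zero(self):
        rec = _rec(np.zeros((2, 1000)))
        assert np.allclose(bandpass(rec, BANDS["alpha"]).samples, 0.0)

    def test_band_above_nyquist_rejected(self):
        from nfx.eeg import Band

        rec = _rec(np.zeros((1, 1000)), fs=60.0)
        with pytest.raises(ValueError):
            bandpass(rec, Band("too-high", 20.0, 35.0))


class TestCoherence:
    def test_scaled_copy_is_fully_coherent(self, rng):
        x = rng.standard_normal(120 * 125)
        for band in BANDS.values():
            assert compute_coherence(x, 3 * x, 125, band) == pytest.approx(1.0, abs=1e-9)

    def test_affine_copy_is_fully_coherent_off_dc(self, rng):
        x = rng.standard_normal(120 * 125)
        assert compute_coherence(x, 2 * x + 5, 125, BANDS["alpha"]) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_dft_oracle_on_independent_noise(self, rng):
        x = rng.standard_normal(120 * 125)
        y = rng.standard_normal(120 * 125)
        for band in (BANDS["delta"], BANDS["alpha"], BANDS["gamma"]):
            mine = compute_coherence(x, y, 125, band)
            assert mine < 0.3  # independent signals: low band coherence
            assert mine == pytest.approx(direct_dft_coherence(x, y, 125, band), abs=1e-10)

    def test_identical_tone_alpha_coherence_is_one(self):
        t = np.arange(0, 120, 1 / 125)
        x = np.sin(2 * np.pi * 10 * t)
        assert compute_coherence(x, x, 125, BANDS["alpha"]) == pytest.approx(1.0, abs=1e-9)

    def test_single_window_is_degenerate(self, rng):
        x = rng.standard_normal(10 * 125)
        with pytest.raises(ValueError, match="2 windows"):
            compute_coherence(x, x.copy(), 125, BANDS["alpha"])


class TestPli:
    def test_constant_quarter_cycle_lag_gives_one(self):
        t = np.arange(0, 10, 1 / 125)
        x = np.cos(2 * np.pi * 10 * t)
        y = np.cos(2 * np.pi * 10 * t - np.pi / 2)
        assert compute_pli(x, y) == pytest.approx(1.0, abs=1e-6)

    def test_identical_signals_give_zero_exactly(self, rng):
        x = rng.standard_normal(2000)
        assert compute_pli(x, x) == 0.0

    def test_balanced_alternating_lags_cancel(self):
        dphi = np.tile([0.3, -0.3], 500)
        assert pli_from_phase_diffs(dphi) == 0.0

    def test_uniform_phase_noise_is_near_zero(self, rng):
        dphi = rng.uniform(-np.pi, np.pi, 100_000)
        # Binomial bound: sd of the mean sign is 1/sqrt(n) ~ 0.0032.
        assert pli_from_phase_diffs(dphi) < 0.02

    def test_pi_lag_gives_zero(self):
        # A lag centred on pi means signs split evenly across the wrap.
        dphi = np.pi + 0.01 * np.tile([1.0, -1.0], 500)
        assert pli_from_phase_diffs(dphi) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pli_from_phase_diffs(np.array([]))

    def test_swap_invariance(self, rng):
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        assert compute_pli(x, y) == pytest.approx(compute_pli(y, x), abs=1e-12)


class TestAggregateGroups:
    @staticmethod
    def _full_pairs(value_fn):
        from itertools import combinations

        return {pair: value_fn(pair) for pair in combinations(CHANNELS_1020, 2)}

    def test_constant_pairs_give_constant_groups(self):
        out = aggregate_groups(self._full_pairs(lambda p: 0.5))
        assert all(v == pytest.approx(0.5) for v in out.values())
        assert set(out) == {"frontal", "interhemispheric", "sagittal", "AVG"}

    def test_interhemispheric_is_mean_of_its_four_pairs(self):
        ih = {("C3", "C4"): 0.2, ("P3", "P4"): 0.4, ("C3", "P4"): 0.6, ("C4", "P3"): 0.8}
        vals = self._full_pairs(lambda p: ih.get(p, 0.0))
        assert aggregate_groups(vals)["interhemispheric"] == pytest.approx(0.5)

    def test_avg_matches_direct_enumeration(self, rng):
        vals = self._full_pairs(lambda p: float(rng.uniform()))
        assert aggregate_groups(vals)["AVG"] == pytest.approx(np.mean(list(vals.values())), abs=1e-12)

    def test_missing_pair_error_names_the_pair(self):
        vals = self._full_pairs(lambda p: 0.5)
        del vals[("C3", "C4")]
        with pytest.raises(KeyError, match="C3.*C4"):
            aggregate_groups(vals)

    def test_scaling_pairs_scales_every_aggregate(self, rng):
        vals = self._full_pairs(lambda p: float(rng.uniform()))
        base = aggregate_groups(vals)
        scaled = aggregate_groups({k: 3.0 * v for k, v in vals.items()})
        for k in base:
            assert scaled[k] == pytest.approx(3.0 * base[k], rel=1e-12)

    def test_user_supplied_pair_set(self):
        vals = self._full_pairs(lambda p: 0.25)
        out = aggregate_groups(vals, extra_groups={"right": [("F4", "C4"), ("C4", "P4")]})
        assert out["right"] == pytest.approx(0.25)


class TestConnectivityPipeline:
    def test_planted_gamma_lag_detected_only_on_coupled_pair(self):
        from nfx.synth import Coupling, EegGenSpec, gen_eeg

        rec = gen_eeg(
            EegGenSpec(
                duration_s=60, noise_sd=2.0,
                couplings=(Coupling(("O1", "O2"), "gamma", np.pi / 3, 0.9),), seed=11,
            )
        )
        results = {(r.method, r.band.name): r for r in connectivity_pipeline(rec)}
        pli = results[("PLI", "gamma")]
        assert pli.pair_values[("O1", "O2")] > 0.8
        assert pli.pair_values[("F3", "P4")] < 0.2

    def test_identical_channels_give_coh_one_pli_zero(self, rng):
        x = rng.normal(0, 10, 60 * 125)
        rec = _rec(np.tile(x, (8, 1)))
        for r in connectivity_pipeline(rec):
            for v in r.pair_values.values():
                if r.method == "COH":
                    assert v == pytest.approx(1.0, abs=1e-9)
                else:
                    assert v == 0.0

    def test_result_carries_epoch_provenance(self, rng):
        rec = _rec(rng.normal(0, 10, (8, 180 * 125)))
        r = connectivity_pipeline(rec, methods=("COH",), bands={"alpha": BANDS["alpha"]})[0]
        assert r.n_epochs_kept == 180
        assert r.n_epochs_rejected == 0

    def test_rejection_excludes_artifact_from_estimates(self, rng):
        x = rng.normal(0, 5, (8, 60 * 125))
        x[0, 10 * 125 : 11 * 125] += 500.0
        res = connectivity_pipeline(_rec(x), methods=("PLI",), bands={"alpha": BANDS["alpha"]})
        assert res[0].n_epochs_rejected == 1

    def test_bounds_on_random_recordings(self, rng):
        rec = _rec(rng.normal(0, 20, (8, 40 * 125)))
        for r in connectivity_pipeline(rec):
            assert all(0.0 <= v <= 1.0 for v in r.pair_values.values())
            assert all(0.0 <= v <= 1.0 for v in r.group_values.values())
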