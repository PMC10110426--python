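"""Wavelet bank calibration, ITC, Rayleigh statistics and the CKC metric."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ckcnet as ck
from ckcnet.containers import EpochArray
from ckcnet.detection import ckc_metric, wavelet_phase
from ckcnet.errors import InsufficientTrialsError, InvalidParameterError


def _epochs(data, fs=250.0):
    n = data.shape[-1]
    return EpochArray(
        data=data,
        fs=fs,
        time_axis_ms=np.arange(n) / fs * 1000.0 - 200.0,
        channel_labels=[f"ch{i}" for i in range(data.shape[1])],
        kept_trigger_indices=np.arange(data.shape[0]),
        rejection_log=pd.DataFrame(),
    )


class TestWaveletBank:
    def test_pinned_bin_is_exact(self):
        bank = ck.build_wavelet_bank(250.0)
        assert bank.pinned_freq == 3.56
        assert np.sum(bank.frequencies == 3.56) == 1
        assert np.all(np.diff(bank.frequencies) > 0)

    def test_pinned_kernel_fwhms_match_printed_calibration(self):
        # spectral-resolution-first design: 740 ms and 1.18 Hz at the
        # response bin, each within 2%
        bank = ck.build_wavelet_bank(250.0)
        assert bank.fwhm_time() * 1000.0 == pytest.approx(740.0, rel=0.02)
        assert bank.fwhm_freq() == pytest.approx(1.18, rel=0.02)

    def test_time_frequency_product_is_near_gaussian_bound(self):
        bank = ck.build_wavelet_bank(250.0)
        for i in range(0, 40, 8):
            prod = bank.fwhm_time(i) * bank.fwhm_freq(i)
            assert 0.85 <= prod <= 0.95

    def test_pinned_frequency_outside_range_raises(self):
        with pytest.raises(InvalidParameterError):
            ck.build_wavelet_bank(250.0, fmin=4.0, fmax=12.0)


class TestWaveletPhase:
    def test_tone_phase_advances_at_carrier_rate(self):
        # long segment so the kernel is fully supported away from edges
        fs = 250.0
        t = np.arange(2500) / fs
        data = np.tile(np.cos(2 * np.pi * 3.56 * t)[None, None, :], (2, 1, 1))
        bank = ck.build_wavelet_bank(fs)
        ph = wavelet_phase(_epochs(data), bank,
                           freq_indices=[bank.pinned_index])
        mid = slice(800, 1700)
        slope = np.polyfit(t[mid], np.unwrap(ph.phases[0, 0, 0, mid]), 1)[0]
        assert slope == pytest.approx(2 * np.pi * 3.56, rel=1e-3)

    def test_zero_epoch_flags_undefined_phase(self):
        bank = ck.build_wavelet_bank(250.0)
        ph = wavelet_phase(_epochs(np.zeros((2, 1, 275))), bank,
                           freq_indices=[bank.pinned_index])
        assert np.isnan(ph.phases).all()

    def test_pinned_bin_selective_for_response_tone(self):
        # amplitude at the pinned bin >= 10x the 0.5 Hz bin for a 3.56 Hz tone
        bank = ck.build_wavelet_bank(250.0)
        spec_pinned = np.abs(
            np.fft.fft(bank.kernels[bank.pinned_index], 1 << 16)
        )
        spec_lowest = np.abs(np.fft.fft(bank.kernels[0], 1 << 16))
        f = np.fft.fftfreq(1 << 16, 1 / 250.0)
        b = np.argmin(np.abs(f - 3.56))
        assert spec_pinned[b] >= 10 * spec_lowest[b]


class TestITC:
    def test_identical_phases_give_unit_itc(self):
        theta = np.full((10, 3), 0.7)
        assert np.allclose(ck.itc(theta), 1.0)

    def test_balanced_phasors_cancel(self):
        theta = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])[:, None]
        assert ck.itc(theta)[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_trials_quarter_turn(self):
        theta = np.array([0.0, np.pi / 2])[:, None]
        assert ck.itc(theta)[0] == pytest.approx(np.sqrt(2) / 2)

    def test_single_trial_raises(self):
        with pytest.raises(InsufficientTrialsError):
            ck.itc(np.zeros((1, 3)))


class TestRayleighP:
    def test_zero_itc_gives_unity(self):
        for n in (2, 10, 1000):
            assert ck.rayleigh_p(0.0, n) == 1.0

    def test_printed_example_value(self):
        assert ck.rayleigh_p(0.2, 100) == pytest.approx(0.0179, abs=0.0005)

    def test_perfect_locking_is_astronomically_significant(self):
        assert ck.rayleigh_p(1.0, 100) < 1e-70

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_monotone_decreasing_in_itc(self, a, b):
        lo, hi = sorted((a, b))
        assert ck.rayleigh_p(hi, 100) <= ck.rayleigh_p(lo, 100)

    @given(st.integers(2, 400), st.integers(2, 400))
    def test_monotone_decreasing_in_n(self, n1, n2):
        lo, hi = sorted((n1, n2))
        assert ck.rayleigh_p(0.3, hi) <= ck.rayleigh_p(0.3, lo)

    # (0.3, 200) is omitted: its tail P (~1e-8) is far below the
    # resolution of a 10^6-draw Monte-Carlo
    @pytest.mark.parametrize("itc_val,n", [(0.1, 50), (0.2, 50), (0.3, 50),
                                           (0.1, 200), (0.2, 200)])
    def test_against_uniform_phase_monte_carlo(self, itc_val, n):
        # null distribution of the resultant length from 10^6 draws
        rng = np.random.default_rng(12345)
        n_mc = 1_000_000
        exceed = 0
        for _ in range(50):
            theta = rng.uniform(-np.pi, np.pi, (n_mc // 50, n))
            r = np.abs(np.mean(np.exp(1j * theta), axis=1))
            exceed += int(np.sum(r >= itc_val))
        p_mc = exceed / n_mc
        p_formula = float(ck.rayleigh_p(itc_val, n))
        assert p_formula == pytest.approx(p_mc, rel=0.15)


class TestCKCMetric:
    def _metric_from_itc_map(self, itc_map, n):
        t = np.arange(itc_map.shape[-1]) / 250.0 * 1000.0 - 200.0
        return ckc_metric(itc_map, n, np.array([3.56]), t,
                          [f"ch{i}" for i in range(itc_map.shape[0])])

    def test_saturated_map_detected(self):
        res = self._metric_from_itc_map(np.ones((4, 1, 275)), 200)
        assert np.allclose(res.ckc, 1.0)
        assert res.p.max() < 1e-100
        assert res.significant.all()

    def test_averaging_window_excludes_edges(self):
        itc_map = np.zeros((1, 1, 275))
        t = np.arange(275) / 250.0 * 1000.0 - 200.0
        itc_map[0, 0, (t >= 0) & (t < 700)] = 1.0  # response only inside
        res = self._metric_from_itc_map(itc_map, 100)
        assert res.ckc[0] == pytest.approx(1.0)

    def test_missing_response_bin_raises(self):
        itc_map = np.ones((2, 1, 275))
        t = np.arange(275) / 250.0 * 1000.0 - 200.0
        with pytest.raises(InvalidParameterError):
            ckc_metric(itc_map, 50, np.array([3.0]), t, ["a", "b"])

    def test_null_type_one_error_is_calibrated(self):
        # steady-state null: per-trial uniform phases, constant over the
        # epoch; the aggregated channel P then reduces to the exact
        # Rayleigh test, whose alpha=0.01 rate must be near nominal
        rng = np.random.default_rng(77)
        n_trials, n_tests = 200, 2100
        theta = rng.uniform(-np.pi, np.pi, (n_trials, n_tests))
        itc_vals = np.abs(np.mean(np.exp(1j * theta), axis=0))
        p = ck.rayleigh_p(itc_vals, n_trials)
        rate = float(np.mean(p < 0.01))
        assert 0.002 <= rate <= 0.025

    def test_fdr_controls_all_null_channels(self):
        rng = np.random.default_rng(8)
        flagged = 0
        n_rep, n_trials = 30, 60
        for _ in range(n_rep):
            theta = rng.uniform(-np.pi, np.pi, (n_trials, 21, 1, 138))
            res = ckc_metric(
                ck.itc(theta), n_trials, np.array([3.56]),
                np.arange(138) / 125.0 * 1000.0 - 200.0,
                [f"ch{i}" for i in range(21)],
            )
            flagged += int(res.significant.sum())
        assert flagged / (n_rep * 21) <= 0.01


class TestEndToEndDetection:
    def test_detects_planted_response_channels(self, csd_epochs):
        res = ck.detect_ckc(csd_epochs)
        labels = res.channel_labels
        assert res.significant[labels.index("C3")] or res.significant[
            labels.index("C4")
        ]
        others = [i for i, c in enumerate(labels) if c not in ("C3", "C4", "Cz")]
        assert np.mean(res.significant[others]) <= 0.1

    def test_fft_variant_agrees_on_locked_synthetic(self):
        rec = ck.generate_scalp_recording(
            ck.SynthScalpConfig(duration=60.0, seed=2, phase_jitter_sd=0.0,
                                noise_amplitude=0.0, response_amplitude=1.0)
        )
        ep = ck.csd(ck.epoch(ck.filter_and_resample(rec)))
        res = ck.ckc_fft(ep)
        assert res.ckc[res.channel_labels.index("C3")] > 0.999
        assert res.method == "fft"

    def test_epoch_sweep_locked_synthetic_significant_from_start(self):
        rec = ck.generate_scalp_recording(
            ck.SynthScalpConfig(duration=60.0, seed=2, phase_jitter_sd=0.0,
                                noise_amplitude=0.0, response_amplitude=1.0)
        )
        ep = ck.csd(ck.epoch(ck.filter_and_resample(rec)))
        table = ck.epoch_count_sweep(ep, step=10)
        assert table.any_significant.all()
        assert list(table.n_epochs) == list(range(10, ep.n_epochs + 1, 10))

    def test_null_recording_rarely_detected(self):
        hits = 0
        for seed in range(10):
            rec = ck.generate_scalp_recording(
                ck.SynthScalpConfig(duration=60.0, seed=900 + seed,
                                    response_amplitude=0.0)
            )
            res = ck.run_detection_pipeline(rec)
            hits += int(res.any_significant)
        assert hits <= 1
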