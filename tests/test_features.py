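import numpy as np
import pytest
from scipy import signal as sps

from qeegprog import (
    CANONICAL_BANDS,
    EegRecording,
    alpha_delta_ratio,
    band_power,
    band_variability,
    brain_symmetry_index,
    epoch_windows,
    mean_amplitude,
    regularity,
    resolve_montage,
    subject_features,
    total_and_relative_power,
    welch_psd,
    window_features,
)
from qeegprog.features import (
    MODEL_QEEG_FEATURES,
    QEEG_FEATURES,
    SpectralEstimate,
    epoch_band_power,
    regularity_epoch,
)
from conftest import FS, sine_recording

BAND = {b.name: b for b in CANONICAL_BANDS}


def _spectrum(rec):
    ep = epoch_windows(rec)
    return ep, welch_psd(ep)


class TestWelchPsd:
    def test_parseval_white_noise(self, rng):
        x = 2.0 * rng.standard_normal(int(600 * FS))  # sigma^2 = 4
        _, sp = _spectrum(EegRecording(["C3"], FS, x[None, :]))
        integral = np.trapezoid(sp.psd[0, 0], sp.freqs_hz)
        assert integral == pytest.approx(4.0, rel=0.05)

    def test_sine_power_concentrated(self, sine10_spectrum):
        _, sp = sine10_spectrum
        total = np.trapezoid(sp.psd[0, 0], sp.freqs_hz)
        assert total == pytest.approx(0.5, rel=0.02)
        peak = sp.freqs_hz[np.argmax(sp.psd[0, 0])]
        assert peak == pytest.approx(10.0, abs=0.5)

    def test_identical_epochs_average_is_identity(self):
        # every 10-s epoch holds exactly 100 cycles, so all epochs carry
        # the same spectrum up to float rounding of the long time axis
        rec = sine_recording([(10.0, 1.0)], duration_s=600.0, labels=("C3",))
        ep, sp = _spectrum(rec)
        np.testing.assert_allclose(
            sp.psd[0], sp.psd_epochs[0, 0], atol=1e-12 * sp.psd[0].max()
        )

    def test_resolution_half_hz(self, sine10_spectrum):
        _, sp = sine10_spectrum
        assert sp.df == pytest.approx(0.5)


class TestBandPowers:
    def test_pure_alpha_sine(self, sine10_spectrum):
        _, sp = sine10_spectrum
        assert band_power(sp, BAND["alpha"]).mean() == pytest.approx(0.5, rel=0.02)
        for other in ("delta", "theta", "beta"):
            assert band_power(sp, BAND[other]).mean() < 0.005

    def test_equal_sines_give_equal_band_powers(self):
        rec = sine_recording(
            [(2.0, 1.0), (6.0, 1.0), (10.0, 1.0), (16.0, 1.0)], labels=("C3",)
        )
        _, sp = _spectrum(rec)
        powers = [band_power(sp, b).mean() for b in CANONICAL_BANDS]
        assert max(powers) / min(powers) < 1.02
        assert powers[0] == pytest.approx(0.5, rel=0.02)

    def test_zero_signal_zero_power(self):
        x = np.zeros((1, int(600 * FS)))
        _, sp = _spectrum(EegRecording(["C3"], FS, x + 0.0))
        for b in CANONICAL_BANDS:
            assert band_power(sp, b).mean() == 0.0

    def test_band_outside_support_rejected(self, sine10_spectrum):
        from qeegprog import FrequencyBand

        _, sp = sine10_spectrum
        with pytest.raises(ValueError, match="outside"):
            band_power(sp, FrequencyBand("hf", 100.0, 200.0))

    def test_welch_matches_periodogram_oracle(self):
        # brute-force oracle: plain periodogram, no segmenting, integrated
        # over the same half-open band support as the Welch bins
        rng = np.random.default_rng(77)
        x = rng.standard_normal(int(600 * FS))
        _, sp = _spectrum(EegRecording(["C3"], FS, x[None, :]))
        f, pxx = sps.periodogram(x, fs=FS, detrend="constant")
        for band in CANONICAL_BANDS:
            hi_eff = sp.freqs_hz[sp.freqs_hz < band.hi_hz - 1e-9][-1]
            sel = (f >= band.lo_hz) & (f <= hi_eff)
            oracle = np.trapezoid(pxx[sel], f[sel])
            ours = band_power(sp, band).mean()
            assert ours == pytest.approx(oracle, rel=0.05)


class TestRelativePowerAndAdr:
    def test_pure_sine_rel_alpha_one(self, sine10_spectrum):
        _, sp = sine10_spectrum
        total, rel = total_and_relative_power(sp)
        assert rel["alpha"][0] == pytest.approx(1.0, abs=0.01)

    def test_relative_powers_sum_to_one(self, rng):
        x = rng.standard_normal((2, int(600 * FS)))
        _, sp = _spectrum(EegRecording(["C3", "C4"], FS, x))
        _, rel = total_and_relative_power(sp)
        s = sum(rel[b.name] for b in CANONICAL_BANDS)
        np.testing.assert_allclose(s, 1.0, atol=1e-9)

    def test_equal_mixture_quarters(self):
        rec = sine_recording(
            [(2.0, 1.0), (6.0, 1.0), (10.0, 1.0), (16.0, 1.0)], labels=("C3",)
        )
        _, sp = _spectrum(rec)
        _, rel = total_and_relative_power(sp)
        for b in CANONICAL_BANDS:
            assert rel[b.name][0] == pytest.approx(0.25, abs=0.01)

    def test_flat_window_missing(self):
        x = np.zeros((1, int(600 * FS)))
        _, sp = _spectrum(EegRecording(["C3"], FS, x))
        total, rel = total_and_relative_power(sp)
        assert np.isnan(total[0])
        assert np.isnan(rel["alpha"][0])

    @pytest.mark.parametrize("powers,expected", [
        ({"alpha": 2.0, "delta": 1.0}, 2.0),
        ({"alpha": 0.5, "delta": 2.0}, 0.25),  # 10 Hz amp 1 + 2 Hz amp 2
    ])
    def test_adr_ratios(self, powers, expected):
        ap = {k: np.array([v]) for k, v in powers.items()}
        assert alpha_delta_ratio(ap)[0] == pytest.approx(expected)

    def test_adr_two_sine_mixture_pipeline(self):
        rec = sine_recording([(10.0, 1.0), (2.0, 2.0)], labels=("C3",))
        _, sp = _spectrum(rec)
        ap = {b.name: band_power(sp, b).mean(-1) for b in CANONICAL_BANDS}
        assert alpha_delta_ratio(ap)[0] == pytest.approx(0.25, rel=0.02)

    def test_pure_delta_adr_near_zero(self):
        rec = sine_recording([(2.0, 1.0)], labels=("C3",))
        _, sp = _spectrum(rec)
        ap = {b.name: band_power(sp, b).mean(-1) for b in CANONICAL_BANDS}
        assert alpha_delta_ratio(ap)[0] < 0.01


class TestVariability:
    @pytest.mark.parametrize("powers,expected", [
        ([1.0, 1.0, 1.0, 1.0], 0.0),
        ([1.0, 1.0, 1.0, 3.0], 0.0),      # MAD 0, median 1
        ([1.0, 2.0, 3.0, 4.0, 5.0], 1.0 / 3.0),
    ])
    def test_hand_computed(self, powers, expected):
        v = band_variability(np.array([powers]))
        assert v[0] == pytest.approx(expected)

    def test_zero_median_missing(self):
        assert np.isnan(band_variability(np.array([[0.0, 0.0, 0.0]]))[0])

    def test_single_epoch_missing(self):
        arr = np.array([[2.0, np.nan, np.nan]])
        assert np.isnan(band_variability(arr)[0])

    def test_clipped_to_unit_interval(self):
        v = band_variability(np.array([[0.01, 100.0, 0.01, 100.0, 0.01]]))
        assert 0.0 <= v[0] <= 1.0


class TestBrainSymmetryIndex:
    def _sp_from(self, left, right, fs=FS):
        rec = EegRecording(["C3", "C4"], fs, np.vstack([left, right]))
        ep = epoch_windows(rec)
        return welch_psd(ep), resolve_montage(rec)

    def test_identical_hemispheres_zero(self, sine10_spectrum):
        ep, sp = sine10_spectrum
        rec_labels = ["C3", "C4"]
        m = resolve_montage(EegRecording(rec_labels, FS, np.zeros((2, 100)) + 1))
        assert brain_symmetry_index(sp, m)[0] == pytest.approx(0.0, abs=1e-12)

    def test_silent_right_hemisphere_one(self, rng):
        left = rng.standard_normal(int(600 * FS))
        sp, m = self._sp_from(left, np.zeros_like(left))
        assert brain_symmetry_index(sp, m)[0] == pytest.approx(1.0)

    def test_constant_ratio_closed_form(self, rng):
        # right PSD = 3x left PSD bin-by-bin -> |3-1|/(3+1) = 0.5
        left = rng.standard_normal(int(600 * FS))
        sp, m = self._sp_from(left, np.sqrt(3.0) * left)
        assert brain_symmetry_index(sp, m)[0] == pytest.approx(0.5, abs=1e-9)

    def test_left_right_swap_invariant(self, rng):
        left = rng.standard_normal(int(600 * FS))
        right = rng.standard_normal(int(600 * FS)) * 1.5
        sp1, m1 = self._sp_from(left, right)
        sp2, m2 = self._sp_from(right, left)
        assert brain_symmetry_index(sp1, m1)[0] == pytest.approx(
            brain_symmetry_index(sp2, m2)[0]
        )

    def test_delta_band_variant(self, rng):
        left = rng.standard_normal(int(600 * FS))
        sp, m = self._sp_from(left, np.sqrt(3.0) * left)
        assert brain_symmetry_index(sp, m, 0.5, 4.0)[0] == pytest.approx(
            0.5, abs=1e-9
        )


class TestAmplitudeAndRegularity:
    def test_sine_amplitude(self, sine10_spectrum):
        ep, _ = sine10_spectrum
        assert mean_amplitude(ep)[0] == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_constant_signal_zero_amplitude(self):
        x = np.full((1, int(600 * FS)), 5.0)
        ep = epoch_windows(EegRecording(["C3"], FS, x))
        assert mean_amplitude(ep)[0] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_amplitude(self, rng):
        x = 10.0 * rng.standard_normal((1, int(600 * FS)))
        ep = epoch_windows(EegRecording(["C3"], FS, x))
        assert mean_amplitude(ep)[0] == pytest.approx(10.0, rel=0.02)

    def test_constant_envelope_sine_reg_near_one(self, sine10_spectrum):
        ep, _ = sine10_spectrum
        assert regularity(ep)[0] == pytest.approx(1.0, rel=0.02)

    def test_single_spike_closed_form(self):
        n = 10_000
        x = np.zeros(n)
        x[1234] = 1.0
        assert regularity_epoch(x, smooth_s=0) == pytest.approx(
            np.sqrt(3) / n, rel=1e-9
        )

    def test_burst_suppression_lower_than_continuous(self, rng):
        n = int(600 * FS)
        base = rng.standard_normal(n)
        t = np.arange(n) / FS
        env = np.where((t % 10.0) / 10.0 < 0.1, 1.0, 0.0)
        ep_c = epoch_windows(EegRecording(["C3"], FS, base[None, :]))
        ep_b = epoch_windows(EegRecording(["C3"], FS, (base * env)[None, :]))
        assert regularity(ep_b)[0] < regularity(ep_c)[0]

    def test_zero_energy_epoch_excluded(self):
        assert np.isnan(regularity_epoch(np.zeros(1000), fs=FS))


class TestSubjectAggregation:
    def test_median_across_windows(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            {f: [1.0, 2.0, 3.0] for f in QEEG_FEATURES}
            | {"rel_power_delta": [0.5, 0.6, 0.9], "n_epochs_used": [60] * 3}
        )
        out = subject_features(df)
        assert out["rel_power_delta"] == pytest.approx(0.6)
        assert out["n_windows_used"] == 3

    def test_single_window_identity(self):
        import pandas as pd

        df = pd.DataFrame({f: [0.7] for f in QEEG_FEATURES} | {"n_epochs_used": [60]})
        out = subject_features(df)
        assert out["adr"] == pytest.approx(0.7)

    def test_missing_feature_uses_remaining_windows(self):
        import pandas as pd

        df = pd.DataFrame({f: [1.0, 2.0, 4.0] for f in QEEG_FEATURES}
                          | {"n_epochs_used": [60] * 3})
        df.loc[1, "adr"] = np.nan
        out = subject_features(df)
        assert out["adr"] == pytest.approx(2.5)

    def test_no_usable_window_is_error(self):
        import pandas as pd

        with pytest.raises(ValueError, match="no usable"):
            subject_features(pd.DataFrame(columns=QEEG_FEATURES + ["n_epochs_used"]))


class TestScaleEquivariance:
    def test_rescaling_signal(self, rng):
        a = 3.7
        x = rng.standard_normal((2, int(600 * FS)))
        rec1 = EegRecording(["C3", "C4"], FS, x)
        rec2 = EegRecording(["C3", "C4"], FS, a * x)
        m = resolve_montage(rec1)
        f1 = window_features(epoch_windows(rec1), m).iloc[0]
        f2 = window_features(epoch_windows(rec2), m).iloc[0]
        assert f2["abs_power_alpha"] == pytest.approx(
            a**2 * f1["abs_power_alpha"], rel=1e-9
        )
        assert f2["total_power"] == pytest.approx(a**2 * f1["total_power"], rel=1e-9)
        assert f2["mean_amp"] == pytest.approx(a * f1["mean_amp"], rel=1e-9)
        for name in MODEL_QEEG_FEATURES:
            if name == "mean_amp":
                continue
            assert f2[name] == pytest.approx(f1[name], rel=1e-6), name

    def test_feature_vector_invariants(self, rng):
        x = rng.standard_normal((2, int(600 * FS))) * 20
        rec = EegRecording(["C3", "C4"], FS, x)
        f = window_features(epoch_windows(rec), resolve_montage(rec)).iloc[0]
        rels = [f[f"rel_power_{b.name}"] for b in CANONICAL_BANDS]
        assert all(0 <= r <= 1 for r in rels)
        assert sum(rels) == pytest.approx(1.0, abs=1e-9)
        for name in ("variability_delta", "variability_all"):
            assert 0 <= f[name] <= 1
        assert 0 <= f["bsi_all"] <= 1
        assert 0 <= f["bsi_delta"] <= 1
        assert 0 <= f["reg"] <= 1
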