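"""Spectral band algebra and cavitation dose metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fuslbx.biomarkers import DegenerateVarianceError
from fuslbx.cavitation import (
    PCDRecording,
    Spectrum,
    band_rms,
    build_band_set,
    compare_pre_post,
    compute_cavitation_doses,
    pulse_spectrum,
    read_pcd_recording,
)
from fuslbx.errors import AnalysisError, ConfigurationError, InputError
from fuslbx.synthetic import PCDSimConfig, simulate_pcd, write_pcd_recording

F0 = 0.65
FS = 10.0
N = 20000  # 2 ms at 10 MHz: all band tones (f0/2, f0, 2f0, 3f0) are bin-aligned


def tone(freq_mhz, amp=1.0, n=N, fs=FS):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq_mhz * t)


def make_recording(baseline_pulses, post_pulses, fs=FS, f0=F0):
    pulses = np.asarray(baseline_pulses + post_pulses)
    times = np.arange(len(pulses), dtype=float)
    mb = len(baseline_pulses) - 0.5
    return PCDRecording(fs=fs, f0=f0, pulses=pulses, pulse_times=times, mb_injection_time=mb)


# ---------------------------------------------------------------------------
# band algebra
# ---------------------------------------------------------------------------


class TestBandSet:
    def test_printed_geometry_at_650khz(self):
        bands = build_band_set(0.65)
        assert bands.subharmonic == pytest.approx((0.175, 0.475))
        assert np.allclose(bands.harmonic_exclusions, [(0.5, 0.8), (1.15, 1.45), (1.8, 2.1)])
        assert np.allclose(bands.broadband_kept, [(0.475, 0.5), (0.8, 1.15), (1.45, 1.8)])

    @given(
        f0=st.floats(0.4, 1.0),
        hw=st.floats(0.02, 0.18),
    )
    def test_kept_bands_match_pointwise_membership_oracle(self, f0, hw):
        """broadband_kept must equal [0.3, 2] minus subharmonic minus harmonics,
        checked point-by-point on a dense frequency grid."""
        if hw >= f0 / 2:
            return
        try:
            bands = build_band_set(f0, half_width=hw)
        except ConfigurationError:
            return
        grid = np.linspace(0.3, 2.0, 4001)
        removed = [(f0 / 2 - hw, f0 / 2 + hw)] + [
            (n * f0 - hw, n * f0 + hw) for n in (1, 2, 3)
        ]
        oracle = np.ones_like(grid, dtype=bool)
        for lo, hi in removed:
            oracle &= ~((grid > lo) & (grid < hi))  # open: edges are boundary points
        kept = np.zeros_like(grid, dtype=bool)
        for lo, hi in bands.broadband_kept:
            kept |= (grid >= lo) & (grid <= hi)
        # away from interval edges the memberships must agree exactly
        edges = np.concatenate([np.asarray(removed).ravel(), [0.3, 2.0]])
        interior = np.min(np.abs(grid[:, None] - edges[None, :]), axis=1) > 1e-6
        assert np.array_equal(kept[interior], oracle[interior])

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            build_band_set(0.65, broad_lo=0.5, broad_hi=0.8)  # fully inside the 1st harmonic notch
        with pytest.raises(ConfigurationError):
            build_band_set(-1.0)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


class TestPulseSpectrum:
    def test_zero_waveform_gives_zero_spectrum(self):
        spec = pulse_spectrum(np.zeros(N), FS)
        assert np.all(spec.mags == 0)

    def test_pure_tone_single_bin_amplitude(self):
        amp = 2.5
        spec = pulse_spectrum(tone(0.325, amp), FS)
        k = np.argmin(np.abs(spec.freqs - 0.325))
        assert spec.mags[k] == pytest.approx(amp, rel=1e-9)
        others = np.delete(spec.mags, k)
        assert np.max(others) < 1e-9

    def test_two_tone_superposition(self):
        spec = pulse_spectrum(tone(0.325, 1.5) + tone(0.9, 0.7), FS)
        k1 = np.argmin(np.abs(spec.freqs - 0.325))
        k2 = np.argmin(np.abs(spec.freqs - 0.9))
        assert spec.mags[k1] == pytest.approx(1.5, rel=1e-9)
        assert spec.mags[k2] == pytest.approx(0.7, rel=1e-9)

    def test_rejects_short_or_nonfinite_pulses(self):
        with pytest.raises(InputError):
            pulse_spectrum(np.zeros(32), FS)
        bad = np.zeros(128)
        bad[3] = np.nan
        with pytest.raises(InputError):
            pulse_spectrum(bad, FS)

    def test_parseval_crosscheck_tones_and_noise(self, rng):
        """Band energy over the full one-sided spectrum reproduces the
        time-domain RMS (exact for integer-cycle tones, ~2% for noise)."""
        x = tone(0.325, 1.0) + tone(1.3, 0.5)
        spec = pulse_spectrum(x, FS)
        nbins = len(spec.mags)
        brms = band_rms(spec, [(0.0, spec.freqs[-1])])
        time_rms = np.sqrt(np.mean(x**2))
        assert brms * np.sqrt(nbins / 2.0) == pytest.approx(time_rms, rel=1e-9)

        noise = rng.normal(0, 1.0, N)
        noise -= noise.mean()
        spec = pulse_spectrum(noise, FS)
        brms = band_rms(spec, [(0.0, spec.freqs[-1])])
        assert brms * np.sqrt(len(spec.mags) / 2.0) == pytest.approx(
            np.sqrt(np.mean(noise**2)), rel=0.02
        )


class TestBandRMS:
    def test_constant_bins(self):
        spec = Spectrum(freqs=np.linspace(0, 5, 101), mags=np.full(101, 0.7))
        assert band_rms(spec, [(1.0, 2.0), (3.0, 4.0)]) == pytest.approx(0.7)

    def test_hand_computed_two_bin_rms(self):
        freqs = np.array([0.0, 1.0, 2.0, 3.0])
        mags = np.array([0.0, 3.0, 4.0, 0.0])
        spec = Spectrum(freqs=freqs, mags=mags)
        assert band_rms(spec, [(0.9, 2.1)]) == pytest.approx(np.sqrt(12.5))

    def test_single_tone_among_k_bins(self):
        amp = 2.0
        spec = pulse_spectrum(tone(0.325, amp), FS)
        lo, hi = 0.175, 0.475
        k = np.sum((spec.freqs >= lo) & (spec.freqs <= hi))
        assert band_rms(spec, [(lo, hi)]) == pytest.approx(amp / np.sqrt(k), rel=1e-9)

    def test_empty_interval_list_rejected(self):
        spec = pulse_spectrum(np.zeros(128), FS)
        with pytest.raises(InputError):
            band_rms(spec, [])

    def test_no_bins_in_band_is_zero(self):
        spec = Spectrum(freqs=np.array([0.0, 1.0, 2.0]), mags=np.ones(3))
        assert band_rms(spec, [(1.4, 1.6)]) == 0.0


# ---------------------------------------------------------------------------
# doses
# ---------------------------------------------------------------------------


class TestCavitationDoses:
    bands = build_band_set(F0)

    def test_identical_pre_post_pulses_self_normalize_to_zero_db(self, rng):
        pulse = rng.normal(0, 1, N)
        rec = make_recording([pulse] * 3, [pulse] * 3)
        dose = compute_cavitation_doses(rec, self.bands)
        assert np.allclose(dose.sc_db, 0.0, atol=1e-9)
        assert np.allclose(dose.ic_db, 0.0, atol=1e-9)

    def test_subharmonic_only_elevates_sc_not_ic(self):
        cfg = PCDSimConfig(
            pulse_duration=2.0,
            n_baseline_pulses=5,
            n_post_pulses=10,
            subharmonic_amp=0.5,
            broadband_sd=0.02,
            seed=7,
        )
        dose = compute_cavitation_doses(simulate_pcd(cfg), self.bands)
        post = dose.is_post_mb
        assert dose.sc_db[post].mean() > 6.0
        assert abs(dose.ic_db[post].mean()) < 1.0

    def test_doubling_subharmonic_amplitude_adds_6db(self):
        base = [tone(0.325, 1.0)] * 3
        rec_a = make_recording(base, [tone(0.325, 2.0)] * 3)
        rec_2a = make_recording(base, [tone(0.325, 4.0)] * 3)
        dose_a = compute_cavitation_doses(rec_a, self.bands)
        dose_2a = compute_cavitation_doses(rec_2a, self.bands)
        delta = dose_2a.sc_db[dose_2a.is_post_mb] - dose_a.sc_db[dose_a.is_post_mb]
        assert np.allclose(delta, 20 * np.log10(2), atol=1e-9)

    def test_ic_invariant_to_tones_in_excluded_bands(self, rng):
        noise = rng.normal(0, 0.1, N)
        rec_plain = make_recording([noise] * 2, [noise] * 2)
        excl_tones = sum(tone(f, 3.0) for f in (0.325, 0.65, 1.3, 1.95))
        rec_spiked = make_recording([noise] * 2, [noise + excl_tones] * 2)
        ic_plain = compute_cavitation_doses(rec_plain, self.bands).ic_linear
        ic_spiked = compute_cavitation_doses(rec_spiked, self.bands).ic_linear
        assert np.max(np.abs(ic_plain - ic_spiked)) < 1e-9

    def test_sc_invariant_to_out_of_band_energy(self, rng):
        noise = rng.normal(0, 0.1, N)
        rec_plain = make_recording([noise] * 2, [noise] * 2)
        rec_spiked = make_recording([noise] * 2, [noise + tone(0.9, 5.0) + tone(1.6, 2.0)] * 2)
        sc_plain = compute_cavitation_doses(rec_plain, self.bands).sc_linear
        sc_spiked = compute_cavitation_doses(rec_spiked, self.bands).sc_linear
        assert np.max(np.abs(sc_plain - sc_spiked)) < 1e-9

    @given(alpha=st.floats(0.1, 10.0))
    def test_linear_levels_scale_exactly_with_amplitude(self, alpha):
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.1, N)
        rec = make_recording([noise] * 2, [noise + tone(0.325, 1.0)] * 2)
        scaled = make_recording(
            [alpha * p for p in rec.pulses[:2]], [alpha * p for p in rec.pulses[2:]]
        )
        d1 = compute_cavitation_doses(rec, self.bands)
        d2 = compute_cavitation_doses(scaled, self.bands)
        assert np.allclose(d2.sc_linear, alpha * d1.sc_linear, rtol=1e-12)
        assert np.allclose(d2.ic_linear, alpha * d1.ic_linear, rtol=1e-12)

    def test_no_baseline_raises_and_zero_baseline_flags_db(self, rng):
        pulse = rng.normal(0, 1, N)
        rec = make_recording([pulse] * 2, [pulse] * 2)
        rec.mb_injection_time = -1.0  # every pulse is post-MB
        with pytest.raises(AnalysisError, match="baseline"):
            compute_cavitation_doses(rec, self.bands)
        # zero-energy baseline: linear levels still returned, dB undefined
        rec2 = make_recording([np.zeros(N)] * 2, [pulse] * 2)
        dose = compute_cavitation_doses(rec2, self.bands)
        assert not dose.sc_db_defined and not dose.ic_db_defined
        assert np.all(np.isfinite(dose.sc_linear))


class TestComparePrePost:
    bands = build_band_set(F0)

    def _doses(self, n_animals, sc_effect, seed0=100):
        out = []
        for i in range(n_animals):
            cfg = PCDSimConfig(
                pulse_duration=2.0,
                n_baseline_pulses=5,
                n_post_pulses=10,
                subharmonic_amp=0.4 if sc_effect else 0.0,
                broadband_sd=0.02,
                seed=seed0 + i,
            )
            out.append(compute_cavitation_doses(simulate_pcd(cfg), self.bands))
        return out

    def test_identical_pre_post_gives_null_result(self, rng):
        pulse = rng.normal(0, 1, N)
        doses = [
            compute_cavitation_doses(make_recording([pulse] * 2, [pulse] * 2), self.bands)
            for _ in range(3)
        ]
        res = compare_pre_post(doses)
        assert res["SC"].statistic == 0.0 and res["SC"].p_two_sided == 1.0

    def test_constant_shift_surfaces_degenerate_variance(self, rng):
        pulse = rng.normal(0, 1, N)
        doses = [
            compute_cavitation_doses(
                make_recording([pulse] * 2, [2.0 * pulse] * 2), self.bands
            )
            for _ in range(7)
        ]
        with pytest.raises(DegenerateVarianceError):
            compare_pre_post(doses)

    def test_sc_effect_detected_ic_not(self):
        res = compare_pre_post(self._doses(7, sc_effect=True))
        assert res["SC"].p_two_sided < 0.05
        assert res["IC"].p_two_sided > 0.05

    def test_fewer_than_two_animals_rejected(self):
        with pytest.raises(AnalysisError):
            compare_pre_post(self._doses(1, sc_effect=False))


def test_pcd_binary_roundtrip(tmp_path):
    cfg = PCDSimConfig(pulse_duration=0.1, n_baseline_pulses=3, n_post_pulses=4, seed=2)
    rec = simulate_pcd(cfg)
    write_pcd_recording(rec, tmp_path / "rec.bin")
    back = read_pcd_recording(tmp_path / "rec.bin")
    assert back.fs == rec.fs and back.f0 == rec.f0
    assert back.mb_injection_time == rec.mb_injection_time
    np.testing.assert_allclose(back.pulses, rec.pulses, atol=1e-6)  # float32 storage
    np.testing.assert_array_equal(back.pulse_times, rec.pulse_times)
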