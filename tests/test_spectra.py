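"""Spectrum synthesis, integration, noise estimation and peak picking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragscreen.spectra import (
    Multiplet,
    PredictedSpectrum,
    Region,
    Spectrum1D,
    estimate_noise,
    integrate,
    pick_peaks,
    synthesize_spectrum,
)

AXIS = Region(0.0, 12.0)


def make_multiplet(center, n_protons=1, half=0.05, **kw):
    return Multiplet(center=center, low=center - half, high=center + half,
                     n_protons=n_protons, **kw)


class TestTypes:
    def test_region_requires_low_below_high(self):
        with pytest.raises(ValueError):
            Region(7.0, 7.0)

    def test_multiplet_center_must_lie_in_range(self):
        with pytest.raises(ValueError):
            Multiplet(center=9.0, low=7.0, high=8.0)

    def test_multiplet_rejects_zero_protons(self):
        with pytest.raises(ValueError):
            make_multiplet(7.0, n_protons=0)

    def test_predicted_spectrum_rejects_implausible_shift(self):
        with pytest.raises(ValueError):
            PredictedSpectrum("X", [Multiplet(center=20.0, low=19.0, high=21.0)])

    def test_axis_must_be_strictly_monotone(self):
        with pytest.raises(ValueError):
            Spectrum1D(ppm=np.array([1.0, 1.0, 2.0]), intensity=np.zeros(3))

    def test_descending_axis_stored_ascending(self):
        s = Spectrum1D(ppm=np.array([3.0, 2.0, 1.0]), intensity=np.array([1.0, 2.0, 3.0]))
        assert s.ppm[0] == 1.0 and s.intensity[0] == 3.0


class TestSynthesize:
    def test_no_multiplets_no_noise_gives_zero_spectrum(self):
        s = synthesize_spectrum([], noise_sd=0.0, axis=AXIS, n_points=512)
        assert np.all(s.intensity == 0.0)

    def test_area_proportional_to_proton_count(self):
        # 1H vs 2H at the same scale: integrated areas in ratio 1:2 within 1%
        one = synthesize_spectrum([make_multiplet(6.0, 1)], axis=AXIS, n_points=8192)
        two = synthesize_spectrum([make_multiplet(6.0, 2)], axis=AXIS, n_points=8192)
        region = Region(4.0, 8.0)
        ratio = integrate(two, region) / integrate(one, region)
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_seeded_synthesis_is_bit_identical(self):
        kw = dict(multiplets=[make_multiplet(7.0)], noise_sd=0.3, seed=42,
                  axis=AXIS, n_points=1024)
        a, b = synthesize_spectrum(**kw), synthesize_spectrum(**kw)
        assert np.array_equal(a.intensity, b.intensity)

    def test_nonpositive_linewidth_rejected(self):
        with pytest.raises(ValueError):
            synthesize_spectrum([make_multiplet(7.0)], linewidth=0.0)

    def test_fine_structure_splits_area_equally(self):
        # a doublet covers its range with two lines but conserves total area
        singlet = make_multiplet(7.0, 2, label="s")
        doublet = make_multiplet(7.0, 2, half=0.06, label="d")
        region = Region(5.0, 9.0)
        a_s = integrate(synthesize_spectrum([singlet], axis=AXIS, n_points=8192), region)
        a_d = integrate(synthesize_spectrum([doublet], axis=AXIS, n_points=8192), region)
        assert a_d == pytest.approx(a_s, rel=0.01)

    def test_round_trip_area_matches_scale_times_protons(self):
        mults = [make_multiplet(6.5, 2), make_multiplet(8.2, 3)]
        s = synthesize_spectrum(mults, scale=0.7, axis=AXIS, n_points=16384)
        recovered = integrate(s, Region(4.0, 11.0))
        assert 0.98 <= recovered / (0.7 * 5) <= 1.02


class TestIntegrate:
    def test_zero_spectrum_integrates_to_zero(self):
        s = synthesize_spectrum([], axis=AXIS, n_points=256)
        assert integrate(s, Region(1.0, 5.0)) == 0.0

    def test_unit_area_lorentzian(self):
        s = synthesize_spectrum([make_multiplet(6.0)], scale=1.0, axis=AXIS, n_points=16384)
        assert integrate(s, Region(2.0, 10.0)) == pytest.approx(1.0, rel=0.02)

    def test_linearity_in_intensity(self):
        s = synthesize_spectrum([make_multiplet(6.0)], axis=AXIS, n_points=2048)
        region = Region(5.0, 7.0)
        scaled = s.with_intensity(3.0 * s.intensity)
        assert integrate(scaled, region) == pytest.approx(3 * integrate(s, region))

    def test_disjoint_region_is_an_error(self):
        s = synthesize_spectrum([], axis=AXIS, n_points=256)
        with pytest.raises(ValueError):
            integrate(s, Region(20.0, 21.0))

    @settings(max_examples=25, derandomize=True)
    @given(split=st.floats(min_value=2.1, max_value=9.9))
    def test_area_additivity_over_adjacent_regions(self, split):
        s = synthesize_spectrum([make_multiplet(6.0, 2)], axis=AXIS, n_points=4096,
                                noise_sd=0.1, seed=7)
        whole = integrate(s, Region(2.0, 10.0))
        # split at an exact grid point so the trapezoids tile the interval
        split = float(s.ppm[np.searchsorted(s.ppm, split)])
        parts = integrate(s, Region(2.0, split)) + integrate(s, Region(split, 10.0))
        assert parts == pytest.approx(whole, abs=1e-9)


class TestNoise:
    def test_zero_spectrum_has_zero_noise(self):
        s = synthesize_spectrum([], axis=AXIS, n_points=256)
        assert estimate_noise(s, Region(1.0, 11.0)) == 0.0

    def test_recovers_known_sd(self):
        s = synthesize_spectrum([], noise_sd=0.1, seed=5, axis=AXIS, n_points=10_000)
        assert estimate_noise(s, AXIS) == pytest.approx(0.1, abs=0.01)

    def test_constant_offset_does_not_change_sd(self):
        s = synthesize_spectrum([], noise_sd=0.1, seed=5, axis=AXIS, n_points=10_000)
        sd = estimate_noise(s, AXIS, store=False)
        shifted = s.with_intensity(s.intensity + 10.0)
        assert estimate_noise(shifted, AXIS, store=False) == pytest.approx(sd)

    def test_too_few_points_rejected(self):
        s = synthesize_spectrum([], axis=AXIS, n_points=256)
        with pytest.raises(ValueError):
            estimate_noise(s, Region(0.0, 0.2))

    def test_estimate_is_stored_on_spectrum(self):
        s = synthesize_spectrum([], noise_sd=0.2, seed=1, axis=AXIS, n_points=1024)
        estimate_noise(s, AXIS)
        assert s.noise_sd is not None and s.noise_sd > 0


class TestPickPeaks:
    def test_unset_noise_is_an_error(self):
        s = synthesize_spectrum([], axis=AXIS, n_points=256)
        with pytest.raises(ValueError):
            pick_peaks(s, AXIS)

    def test_flat_spectrum_gives_no_peaks(self):
        s = synthesize_spectrum([], noise_sd=0.05, seed=3, axis=AXIS, n_points=4096)
        estimate_noise(s, Region(0.0, 4.0))
        assert pick_peaks(s, Region(5.0, 10.0), k_noise=5.0, min_width=0.01) == []

    def test_planted_peak_found_at_its_shift(self):
        m = make_multiplet(7.22, 1, half=0.02)
        height = 2.0 / (np.pi * 0.02)  # unit-area Lorentzian peak height
        s = synthesize_spectrum([m], linewidth=0.02, noise_sd=0.1 * height, seed=11,
                                axis=AXIS, n_points=8192)
        estimate_noise(s, Region(0.0, 4.0))
        peaks = pick_peaks(s, Region(6.0, 8.0), k_noise=3.0, min_width=0.01)
        assert len(peaks) == 1
        assert abs(peaks[0][0] - 7.22) < 0.02

    def test_subthreshold_peak_not_picked(self):
        m = make_multiplet(7.22, 1, half=0.02)
        height = 2.0 / (np.pi * 0.02)
        # plant at 2x noise with a 3x threshold
        s = synthesize_spectrum([m], linewidth=0.02, scale=2 / height, noise_sd=1.0,
                                seed=13, axis=AXIS, n_points=8192)
        s.noise_sd = 1.0
        peaks = pick_peaks(s, Region(7.0, 7.5), k_noise=3.0, min_width=0.01)
        assert peaks == []

    def test_count_matches_resolved_multiplets_noise_free(self):
        mults = [make_multiplet(c, half=0.02) for c in (6.2, 7.4, 8.8)]
        s = synthesize_spectrum(mults, linewidth=0.02, axis=AXIS, n_points=8192)
        s.noise_sd = 1e-6
        peaks = pick_peaks(s, Region(5.0, 10.0), k_noise=3.0)
        assert len(peaks) == 3

    def test_shoulders_merge_to_taller_peak(self):
        mults = [make_multiplet(7.00, 3, half=0.02), make_multiplet(7.03, 1, half=0.02)]
        s = synthesize_spectrum(mults, linewidth=0.02, axis=AXIS, n_points=16384)
        s.noise_sd = 1e-6
        merged = pick_peaks(s, Region(6.5, 7.5), k_noise=3.0, merge_width=0.05)
        assert len(merged) == 1
        assert abs(merged[0][0] - 7.00) < 0.01
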