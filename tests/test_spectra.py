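import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chromachoice as cc
from chromachoice.spectra import Spectrum

from conftest import random_spectrum


class TestReadWrite:
    def test_identity_read(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,value\n400,1\n401,2\n")
        s = cc.read_spectrum(p)
        assert len(s) == 2
        np.testing.assert_allclose(s.values, [1.0, 2.0])

    def test_rows_sorted(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("500,1\n400,2\n")
        s = cc.read_spectrum(p)
        np.testing.assert_allclose(s.wavelengths, [400.0, 500.0])
        np.testing.assert_allclose(s.values, [2.0, 1.0])

    def test_duplicate_wavelengths_averaged(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("400,1\n400,3\n")
        s = cc.read_spectrum(p)
        assert len(s) == 1
        assert s.values[0] == pytest.approx(2.0)

    def test_unit_comment_and_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        s = random_spectrum(rng, unit="energy")
        p = tmp_path / "round.csv"
        cc.write_spectrum(s, p)
        back = cc.read_spectrum(p)
        assert back.unit == "energy"
        np.testing.assert_allclose(back.wavelengths, s.wavelengths, rtol=1e-6)
        np.testing.assert_allclose(back.values, s.values, rtol=1e-9)

    def test_bad_inputs(self, tmp_path):
        empty = tmp_path / "e.csv"
        empty.write_text("")
        with pytest.raises(ValueError):
            cc.read_spectrum(empty)
        bad = tmp_path / "b.csv"
        bad.write_text("400,1\nfoo,bar\n")
        with pytest.raises(ValueError):
            cc.read_spectrum(bad)


class TestSpectrumInvariants:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([400.0, 500.0]), np.array([1.0, -0.1]))

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0, 400.0]), np.array([1.0, 1.0]))

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([400.0]), np.array([1.0]), unit="parsecs")


class TestResample:
    def test_own_grid_is_identity(self):
        rng = np.random.default_rng(1)
        s = random_spectrum(rng)
        out = cc.resample(s, s.wavelengths)
        np.testing.assert_allclose(out.values, s.values)

    def test_linear_ramp_midpoints(self):
        wl = np.arange(400.0, 411.0)
        s = Spectrum(wl, wl.copy())
        mid = wl[:-1] + 0.5
        out = cc.resample(s, mid)
        np.testing.assert_allclose(out.values, mid)

    def test_against_pointwise_interpolation_oracle(self):
        rng = np.random.default_rng(2)
        s = random_spectrum(rng)
        grid = np.sort(rng.uniform(s.wavelengths[0], s.wavelengths[-1], 37))
        out = cc.resample(s, grid)
        # independent oracle: scalar linear interpolation, point by point
        for g, got in zip(grid, out.values):
            j = np.searchsorted(s.wavelengths, g)
            if s.wavelengths[j] == g:
                expected = s.values[j]
            else:
                x0, x1 = s.wavelengths[j - 1], s.wavelengths[j]
                y0, y1 = s.values[j - 1], s.values[j]
                expected = y0 + (y1 - y0) * (g - x0) / (x1 - x0)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_out_of_support_pads_zero_with_warning(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([1.0, 1.0]))
        with pytest.warns(UserWarning):
            out = cc.resample(s, np.array([300.0, 450.0]))
        assert out.values[0] == 0.0

    def test_empty_grid_errors(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            cc.resample(s, np.array([]))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent_on_same_grid(self, seed):
        rng = np.random.default_rng(seed)
        s = random_spectrum(rng)
        grid = np.linspace(s.wavelengths[0], s.wavelengths[-1], 25)
        once = cc.resample(s, grid)
        twice = cc.resample(once, grid)
        np.testing.assert_allclose(twice.values, once.values)


class TestUnitConversions:
    def test_zero_spectrum_stays_zero(self):
        s = Spectrum(np.array([400.0, 500.0]), np.zeros(2), unit="energy")
        assert np.all(cc.energy_to_photons(s).values == 0)

    def test_photon_ratio_doubles_with_wavelength(self):
        s = Spectrum(np.array([400.0, 800.0]), np.array([1.0, 1.0]), unit="energy")
        n = cc.energy_to_photons(s)
        assert n.values[1] / n.values[0] == pytest.approx(2.0, rel=1e-12)

    def test_one_watt_at_555nm_hand_value(self):
        # N = E·λ/(h·c) with λ = 555e-9 m, computed by hand:
        # 555e-9 / (6.62607015e-34 * 2.99792458e8) = 2.7939347...e18 photons/s
        s = Spectrum(np.array([555.0]), np.array([1.0]), unit="energy")
        n = cc.energy_to_photons(s)
        assert n.values[0] == pytest.approx(2.79393469e18, rel=1e-6)

    def test_roundtrip_inverse(self):
        rng = np.random.default_rng(3)
        s = random_spectrum(rng, unit="energy")
        back = cc.photons_to_energy(cc.energy_to_photons(s))
        np.testing.assert_allclose(back.values, s.values, rtol=1e-12)

    def test_wrong_unit_tag_errors(self):
        s = Spectrum(np.array([400.0]), np.array([1.0]), unit="photon_flux")
        with pytest.raises(ValueError):
            cc.energy_to_photons(s)


class TestLuminousIntensity:
    def test_monochromatic_555nm_gives_683cd(self):
        # triangular 1 W/(sr·nm) line at 555 nm: integral = 1 W/sr at V=1
        s = Spectrum(np.array([554.0, 555.0, 556.0]), np.array([0.0, 1.0, 0.0]),
                     unit="radiance")
        assert cc.luminous_intensity(s) == pytest.approx(683.0, abs=0.1)

    def test_zero_spectrum(self):
        s = Spectrum(np.array([500.0, 600.0]), np.zeros(2), unit="radiance")
        with pytest.warns(UserWarning):
            assert cc.luminous_intensity(s) == 0.0

    def test_disjoint_support_zero_with_warning(self):
        s = Spectrum(np.array([300.0, 320.0]), np.array([1.0, 1.0]), unit="radiance")
        with pytest.warns(UserWarning):
            assert cc.luminous_intensity(s) == 0.0

    def test_against_independent_trapezoid_oracle(self):
        rng = np.random.default_rng(4)
        wl = np.linspace(400.0, 700.0, 61)
        v = rng.uniform(0, 2, wl.size)
        s = Spectrum(wl, v, unit="radiance")
        vl = cc.photopic_luminosity(wl).values
        prod = v * vl
        manual = 0.0  # hand-rolled trapezoid
        for i in range(wl.size - 1):
            manual += 0.5 * (prod[i] + prod[i + 1]) * (wl[i + 1] - wl[i])
        assert cc.luminous_intensity(s) == pytest.approx(683.002 * manual, rel=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        wl = np.linspace(450.0, 650.0, 41)
        a = Spectrum(wl, rng.uniform(0, 1, wl.size), unit="radiance")
        b = Spectrum(wl, rng.uniform(0, 1, wl.size), unit="radiance")
        both = Spectrum(wl, a.values + 2 * b.values, unit="radiance")
        assert cc.luminous_intensity(both) == pytest.approx(
            cc.luminous_intensity(a) + 2 * cc.luminous_intensity(b), rel=1e-10
        )

    def test_photopic_peak_at_555(self, grid):
        vl = cc.photopic_luminosity(grid)
        assert vl.peak_wavelength == 555.0
        assert vl.values.max() == pytest.approx(1.0)


class TestNormalizePeak:
    def test_peak_hits_target(self):
        rng = np.random.default_rng(6)
        s = random_spectrum(rng)
        out = cc.normalize_peak(s, 4000.0)
        assert out.values.max() == pytest.approx(4000.0)

    def test_idempotent_at_target(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([10.0, 5.0]))
        out = cc.normalize_peak(s, 10.0)
        np.testing.assert_allclose(out.values, s.values)

    def test_ratios_preserved(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([1.0, 0.5]))
        out = cc.normalize_peak(s, 10.0)
        np.testing.assert_allclose(out.values, [10.0, 5.0])

    def test_all_zero_errors(self):
        s = Spectrum(np.array([400.0, 500.0]), np.zeros(2))
        with pytest.raises(ValueError):
            cc.normalize_peak(s, 1.0)

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, k):
        wl = np.array([400.0, 500.0, 600.0])
        s = Spectrum(wl, np.array([1.0, 3.0, 2.0]))
        scaled = Spectrum(wl, k * s.values)
        np.testing.assert_allclose(
            cc.normalize_peak(scaled, 7.0).values, cc.normalize_peak(s, 7.0).values,
            rtol=1e-12,
        )


class TestTotalsAndAverages:
    def test_total_photon_output(self):
        wl = np.array([500.0, 501.0, 502.0])
        assert cc.total_photon_output(Spectrum(wl, np.array([10.0, 20.0, 30.0]))) == 60.0
        assert cc.total_photon_output(Spectrum(wl, np.zeros(3))) == 0.0
        with pytest.raises(ValueError):
            cc.total_photon_output(Spectrum(wl, np.ones(3), unit="energy"))

    def test_average_single_is_identity(self):
        rng = np.random.default_rng(7)
        s = random_spectrum(rng)
        np.testing.assert_allclose(cc.average_spectra([s]).values, s.values)

    def test_average_constants(self):
        wl = np.array([400.0, 500.0])
        a = Spectrum(wl, np.full(2, 1.0))
        b = Spectrum(wl, np.full(2, 3.0))
        np.testing.assert_allclose(cc.average_spectra([a, b]).values, [2.0, 2.0])

    def test_average_matches_pointwise_mean_oracle(self):
        rng = np.random.default_rng(8)
        wl = np.linspace(300.0, 700.0, 81)
        specs = [Spectrum(wl, rng.uniform(0, 5, wl.size)) for _ in range(10)]
        mean = cc.average_spectra(specs)
        manual = sum(s.values for s in specs) / 10.0
        np.testing.assert_allclose(mean.values, manual, rtol=1e-12)

    def test_unit_mismatch_errors(self):
        wl = np.array([400.0, 500.0])
        a = Spectrum(wl, np.ones(2), unit="photon_flux")
        b = Spectrum(wl, np.ones(2), unit="energy")
        with pytest.raises(ValueError):
            cc.average_spectra([a, b])
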