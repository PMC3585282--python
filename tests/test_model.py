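"""Forward-model unit tests: membrane impedance, Bessel kernel, Z_c limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bessel_ratio_series
from ecisfit.errors import InvalidArgumentError
from ecisfit.model import (
    ComplexSpectrum,
    ElectrodeGeometry,
    MonolayerParams,
    bessel_ratio,
    cell_covered_impedance,
    from_specific,
    membrane_impedance,
    series_rc_equivalent,
    to_specific,
)


class TestMonolayerParams:
    def test_rejects_invalid(self):
        with pytest.raises(InvalidArgumentError):
            MonolayerParams(-1.0, 4.0, 1.8)
        with pytest.raises(InvalidArgumentError):
            MonolayerParams(6.0, -0.1, 1.8)
        with pytest.raises(InvalidArgumentError):
            MonolayerParams(6.0, 4.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            MonolayerParams(np.inf, 4.0, 1.8)

    def test_array_round_trip(self):
        p = MonolayerParams(6.0, 4.0, 1.8)
        assert MonolayerParams.from_array(p.as_array()) == p


class TestMembraneImpedance:
    def test_closed_form_value(self):
        # cm = 1 µF/cm² at f = 1/(π·1e-6) Hz gives exactly -1j Ω·cm²
        z = membrane_impedance(1.0 / (np.pi * 1e-6), cm=1.0)
        assert z == pytest.approx(-1j, abs=1e-12)

    def test_capacitor_shorts_at_high_frequency(self):
        assert abs(membrane_impedance(1e12, cm=1.8)) < 1e-6

    def test_inverse_proportional_to_cm(self):
        f = np.array([100.0, 4000.0, 16000.0])
        assert np.allclose(np.abs(membrane_impedance(f, 2.0)),
                           np.abs(membrane_impedance(f, 1.0)) / 2.0)

    def test_negative_imaginary_part(self):
        z = membrane_impedance(4000.0, 1.8)
        assert z.real == 0 and z.imag < 0

    @pytest.mark.parametrize("f,cm", [(0.0, 1.0), (-5.0, 1.0), (100.0, 0.0), (100.0, -1.0)])
    def test_invalid_arguments(self, f, cm):
        with pytest.raises(InvalidArgumentError):
            membrane_impedance(f, cm)


class TestBesselRatio:
    def test_small_argument_limit(self):
        # z·I0/I1 -> 2 as z -> 0 (I0 ~ 1, I1 ~ z/2)
        for z in [1e-6, 1e-6 + 1e-6j, 1e-8j + 1e-9]:
            assert z * bessel_ratio(z) == pytest.approx(2.0, rel=1e-6)

    def test_real_value_against_series_oracle(self):
        # frozen from the Decimal power-series oracle at z = 2
        assert bessel_ratio(2.0 + 0j) == pytest.approx(1.4331274267223117, rel=1e-12)

    def test_asymptotic_limit(self):
        assert bessel_ratio(1e4 + 0j) == pytest.approx(1.0, abs=1e-3)

    def test_matches_series_oracle_on_complex_grid(self):
        for mod in np.geomspace(1e-3, 50, 12):
            for arg in np.linspace(-np.pi / 2 + 0.05, np.pi / 2 - 0.05, 7):
                z = complex(mod * np.exp(1j * arg))
                assert bessel_ratio(z) == pytest.approx(bessel_ratio_series(z), rel=1e-10)

    def test_rejects_zero_and_left_half_plane(self):
        with pytest.raises(InvalidArgumentError):
            bessel_ratio(0.0)
        with pytest.raises(InvalidArgumentError):
            bessel_ratio(-1.0 + 0.5j)


class TestCellCoveredImpedance:
    def test_reduces_to_naked_electrode(self, clean_model, doubling_freqs):
        zn = clean_model.interface_specific(doubling_freqs)
        for cm in (0.5, 1.8, 4.0):
            zc = cell_covered_impedance(doubling_freqs, zn,
                                        MonolayerParams(0.0, 0.0, cm))
            assert np.max(np.abs(zc - zn) / np.abs(zn)) < 1e-12

    def test_infinite_barrier_forces_membrane_path(self, clean_model, doubling_freqs):
        """Z_c -> Z_n + Z_m as rb -> inf, converging at the 1/rb rate.

        The deviation decays like 1/(rb·|1/Z_n + 1/Z_m|), so at the lowest
        frequencies (where the admittance sum is smallest) rb = 1e9 is not
        yet fully converged; above a few hundred Hz it is well inside 1e-6.
        """
        zn = clean_model.interface_specific(doubling_freqs)
        zm = membrane_impedance(doubling_freqs, 1.8)
        ceiling = zn + zm
        dev = {rb: np.abs(cell_covered_impedance(doubling_freqs, zn,
                                                 MonolayerParams(6.0, rb, 1.8))
                          - ceiling) / np.abs(ceiling)
               for rb in (1e9, 1e10)}
        assert np.max(dev[1e9][doubling_freqs >= 250.0]) < 1e-6
        assert np.max(dev[1e10]) < 1e-6
        # 1/rb convergence rate: a tenfold rb cuts the deviation tenfold
        assert np.all(dev[1e10] < 0.11 * dev[1e9])

    def test_frozen_value_and_direct_evaluation(self, clean_model):
        """Z_c at 4000 Hz for (6, 4, 1.8) against an independent formula evaluation."""
        from scipy.special import iv

        zn = complex(clean_model.interface_specific(4000.0))
        zc = cell_covered_impedance(4000.0, zn, MonolayerParams(6.0, 4.0, 1.8))
        # frozen from the direct evaluation below
        assert zc == pytest.approx(9.016439536878949 - 3.970140169549051j, rel=1e-12)
        zm = 1 / (1j * np.pi * 4000 * 1.8e-6)
        s = 1 / zn + 1 / zm
        g = 6.0 * np.sqrt(s)
        inv = (1 / zn) * (zn / (zn + zm)
                          + (zm / (zn + zm)) / ((g / 2) * iv(0, g) / iv(1, g) + 4.0 * s))
        assert zc == pytest.approx(1 / inv, rel=1e-12)

    def test_monotone_nondecreasing_in_rb(self, clean_model, doubling_freqs):
        """|Z_c| grows with rb over [0, 100] at every windowed frequency.

        The rb -> inf limit |Z_n + Z_m| is approached but may be slightly
        overshot in magnitude at finite rb (complex components add with
        different phases), so only monotonicity and the limit are asserted.
        """
        f = doubling_freqs[(doubling_freqs >= 62.5) & (doubling_freqs <= 16000)]
        zn = clean_model.interface_specific(f)
        mags = [np.abs(cell_covered_impedance(f, zn, MonolayerParams(6.0, rb, 1.8)))
                for rb in [0.0, 0.5, 1, 2, 5, 10, 30, 100]]
        for lo, hi in zip(mags, mags[1:]):
            assert np.all(hi >= lo - 1e-9)
        limit = np.abs(cell_covered_impedance(f, zn, MonolayerParams(6.0, 1e12, 1.8)))
        assert np.allclose(limit, np.abs(zn + membrane_impedance(f, 1.8)), rtol=1e-9)

    def test_continuous_at_alpha_zero(self, clean_model, doubling_freqs):
        zn = clean_model.interface_specific(doubling_freqs)
        z0 = cell_covered_impedance(doubling_freqs, zn, MonolayerParams(0.0, 2.0, 1.8))
        z1 = cell_covered_impedance(doubling_freqs, zn, MonolayerParams(1e-8, 2.0, 1.8))
        assert np.max(np.abs(z1 - z0) / np.abs(z0)) < 1e-9

    def test_smooth_in_parameters(self, clean_model, doubling_freqs):
        """Finite central differences exist and are finite over a parameter grid."""
        zn = clean_model.interface_specific(doubling_freqs)
        for base in [(3.0, 1.0, 0.8), (6.0, 4.0, 1.8), (12.0, 9.0, 3.5)]:
            for k, h in [(0, 1e-6), (1, 1e-6), (2, 1e-7)]:
                lo, hi = list(base), list(base)
                lo[k] -= h
                hi[k] += h
                d = (cell_covered_impedance(doubling_freqs, zn, MonolayerParams(*hi))
                     - cell_covered_impedance(doubling_freqs, zn, MonolayerParams(*lo))) / (2 * h)
                assert np.all(np.isfinite(d.view(float)))

    def test_rejects_zero_reference(self):
        with pytest.raises(InvalidArgumentError):
            cell_covered_impedance(100.0, 0.0, MonolayerParams(6.0, 4.0, 1.8))


class TestSeriesRc:
    def test_closed_form(self):
        r, c = series_rc_equivalent(100.0 - 50.0j, 4000.0)
        assert r == 100.0
        assert c == pytest.approx(1.0 / (2 * np.pi * 4000 * 50))

    def test_purely_real_has_undefined_capacitance(self):
        r, c = series_rc_equivalent(75.0 + 0j, 4000.0)
        assert r == 75.0 and np.isnan(c)

    @settings(deadline=None, derandomize=True)
    @given(r=st.floats(1.0, 1e4), c=st.floats(1e-9, 1e-5), f=st.floats(10.0, 1e5))
    def test_round_trip_recovers_rc(self, r, c, f):
        z = r - 1j / (2 * np.pi * f * c)
        r2, c2 = series_rc_equivalent(z, f)
        assert r2 == pytest.approx(r, rel=1e-12)
        assert c2 == pytest.approx(c, rel=1e-12)


class TestSpecificConversion:
    def test_example_value(self):
        geo = ElectrodeGeometry(area_cm2=5e-3, label="custom")
        assert to_specific(1000.0, geo) == pytest.approx(5.0)

    def test_unit_area_is_identity(self):
        geo = ElectrodeGeometry(area_cm2=1.0, label="unit")
        z = 123.4 - 56.7j
        assert to_specific(z, geo) == z

    def test_round_trip(self, geometry):
        z = np.array([100 - 50j, 2000 - 800j])
        assert np.array_equal(from_specific(to_specific(z, geometry), geometry), z)


class TestComplexSpectrum:
    def test_validation(self):
        with pytest.raises(InvalidArgumentError):
            ComplexSpectrum("e", "cell_covered", "pre", [100, 50, 200], [1, 2, 3], [0, 0, 0])
        with pytest.raises(InvalidArgumentError):
            ComplexSpectrum("e", "bogus", "pre", [1, 2, 3], [1, 2, 3], [0, 0, 0])
        with pytest.raises(InvalidArgumentError):
            ComplexSpectrum("e", "reference", "", [1, 2], [1, 2], [0, 0])

    def test_complex_view(self):
        s = ComplexSpectrum("e", "reference", "", [1, 2, 4], [1, 2, 3], [-1, -2, -3])
        assert np.array_equal(s.z_ohm, np.array([1 - 1j, 2 - 2j, 3 - 3j]))
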