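import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesifit.binding import (
    BindingCurve,
    EquilibriumParams,
    TitrationPoint,
    build_calibration,
    competitive_equilibrium,
    equilibrium_fraction_bound,
    fraction_bound_linear,
)
from vesifit.errors import CalibrationError, InvalidInputError

from oracles import bisect_bound_fraction, grid_scan_competition


class TestLinearConversion:
    def test_endpoints_and_clamp(self):
        assert fraction_bound_linear(3.4, 3.4, 14.9) == 0.0
        assert fraction_bound_linear(14.9, 3.4, 14.9) == 1.0
        assert fraction_bound_linear(2.9, 3.4, 14.9) == 0.0  # noise below free radius
        assert fraction_bound_linear(20.0, 3.4, 14.9) == 1.0

    def test_partial_displacement_value(self):
        """Monomer radius after oligomer addition: straight interpolation."""
        expected = (6.2 - 3.4) / (14.9 - 3.4)
        assert fraction_bound_linear(6.2, 3.4, 14.9) == pytest.approx(expected, rel=1e-12)

    def test_invalid_order(self):
        with pytest.raises(InvalidInputError):
            fraction_bound_linear(5.0, 10.0, 3.0)


class TestCalibration:
    def test_round_trip_large_contrast(self, geometry, solvent, fitter):
        """Inverting the calibration recovers true fractions off-anchor."""
        from vesifit.mds import MixtureModel

        cal = build_calibration(3.3, 64.5, geometry, solvent, fitter=fitter)
        mm = MixtureModel(3.3, 64.5, geometry, solvent, fitter=fitter)
        fracs, radii = mm.radius_table(n=41)  # twice the anchor density
        recovered = cal.fraction_bound(radii)
        assert np.max(np.abs(recovered - fracs)) < 0.02

    def test_small_contrast_is_nearly_linear(self, geometry, solvent, fitter):
        cal = build_calibration(12.3, 13.0, geometry, solvent, fitter=fitter)
        radii = np.array(cal.anchor_radii)
        linear = fraction_bound_linear(radii, radii[0], radii[-1])
        assert np.max(np.abs(cal.fraction_bound(radii) - linear)) < 0.01

    def test_monotone_on_valid_range(self, geometry, solvent, fitter):
        cal = build_calibration(3.3, 64.5, geometry, solvent, fitter=fitter)
        grid = np.linspace(*cal.valid_range, 201)
        vals = cal.fraction_bound(grid)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_too_few_anchors_rejected(self, geometry, solvent):
        with pytest.raises(InvalidInputError):
            build_calibration(3.3, 64.5, geometry, solvent, n_anchor=3)


class TestEquilibrium:
    def test_zero_lipid(self):
        p = EquilibriumParams(5e-9, 1e-4, 35)
        assert equilibrium_fraction_bound(p, 0.0, 2e-6) == 0.0

    def test_stoichiometric_limit(self):
        """Vanishing K_d with excess sites binds everything."""
        p = EquilibriumParams(1e-30, 1e-4, 35)
        f = equilibrium_fraction_bound(p, 2e-3, 2e-6)  # S0 = 200 nM >> P0 = 57 nM
        assert f == pytest.approx(1.0, abs=1e-9)

    def test_against_bisection_oracle(self):
        """Closed-form quadratic vs bisection on the mass-action system."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            kd = 10 ** rng.uniform(-11, -4)
            a = 10 ** rng.uniform(-7, -0.3)
            b = int(rng.integers(1, 41))
            lipid = 10 ** rng.uniform(-7, -2)
            protein = 10 ** rng.uniform(-8, -4)
            params = EquilibriumParams(kd, a, b)
            ours = equilibrium_fraction_bound(params, lipid, protein)
            oracle = bisect_bound_fraction(kd, a, b, lipid, protein)
            assert abs(ours - oracle) < 1e-10

    def test_weak_binding_linear_limit(self):
        """P0 << K_d reduces to the single-site isotherm S0/(S0+K_d)."""
        kd, a = 1e-6, 1e-3
        p = EquilibriumParams(kd, a, 1)
        for lipid in (1e-5, 1e-4, 1e-3):
            s0 = a * lipid
            f = equilibrium_fraction_bound(p, lipid, kd * 1e-4)
            assert f == pytest.approx(s0 / (s0 + kd), rel=1e-3)

    @settings(max_examples=50, derandomize=True)
    @given(
        lkd=st.floats(-10, -5),
        la=st.floats(-6, -1),
        b=st.integers(1, 40),
        lb0=st.floats(-8, -5),
    )
    def test_monotonicity(self, lkd, la, b, lb0):
        p = EquilibriumParams(10**lkd, 10**la, b)
        lipids = np.geomspace(1e-7, 1e-2, 12)
        f = equilibrium_fraction_bound(p, lipids, 10**lb0)
        assert np.all(np.diff(f) >= -1e-12)
        weaker = EquilibriumParams(10 ** (lkd + 1), 10**la, b)
        f2 = equilibrium_fraction_bound(weaker, lipids, 10**lb0)
        assert np.all(f2 <= f + 1e-12)


MONO = EquilibriumParams(750e-9, 1.0 / 30.0, 1)
OLIG = EquilibriumParams(5e-9, 1e-4, 35)


class TestCompetition:
    def test_reduces_to_single_species(self):
        for m_tot, o_tot in ((2e-6, 0.0), (0.0, 2e-6)):
            f_m, f_o = competitive_equilibrium(MONO, OLIG, 150e-6, m_tot, o_tot)
            if m_tot > 0:
                assert abs(f_m - equilibrium_fraction_bound(MONO, 150e-6, m_tot)) < 1e-10
                assert f_o == 0.0
            else:
                assert abs(f_o - equilibrium_fraction_bound(OLIG, 150e-6, o_tot)) < 1e-10
                assert f_m == 0.0

    def test_symmetry_identical_species(self):
        f_m, f_o = competitive_equilibrium(MONO, MONO, 100e-6, 2e-6, 2e-6)
        assert f_m == pytest.approx(f_o, abs=1e-12)

    def test_against_grid_scan_oracle(self):
        """Subsaturating lipid with a 150-fold affinity gap, vs brute force."""
        f_m, f_o = competitive_equilibrium(MONO, OLIG, 150e-6, 2e-6, 2e-6)
        gm, go = grid_scan_competition(
            MONO.k_d, MONO.a, MONO.b, OLIG.k_d, OLIG.a, OLIG.b, 150e-6, 2e-6, 2e-6
        )
        assert f_m == pytest.approx(gm, abs=1e-6)
        assert f_o == pytest.approx(go, abs=1e-6)
        # oligomer addition displaces monomer
        before = equilibrium_fraction_bound(MONO, 150e-6, 2e-6)
        assert f_m < before

    @settings(max_examples=25, derandomize=True)
    @given(o_tot=st.floats(0.0, 1e-5))
    def test_monomer_binding_non_increasing_in_oligomer(self, o_tot):
        f_ref, _ = competitive_equilibrium(MONO, OLIG, 150e-6, 2e-6, 0.0)
        f_m, f_o = competitive_equilibrium(MONO, OLIG, 150e-6, 2e-6, o_tot)
        assert f_m <= f_ref + 1e-12
        # bookkeeping: bound amounts never exceed totals or capacity
        bound_sites = f_m * 2e-6 / MONO.b / MONO.a + f_o * o_tot / OLIG.b / OLIG.a
        assert bound_sites <= 150e-6 + 1e-18


class TestCurveValidation:
    def test_requires_four_points(self):
        pts = tuple(TitrationPoint(1e-6 * i, 5.0) for i in range(1, 4))
        with pytest.raises(InvalidInputError):
            BindingCurve(pts, protein_total=2e-6, r_free=3.3, r_bound=14.9)
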