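"""Potential terms: values, forces, invariants, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cphkit.constants import KB, LN10
from cphkit.errors import InvalidModelError
from cphkit.model import (
    BiasPotentialParams,
    CorrectionPotential,
    LambdaSite,
    PHPotentialParams,
    PotentialSet,
    TorsionModel,
    ExtrapolationWarning,
    eval_torsion,
    eval_vbias,
    eval_vmm,
    eval_vph,
)


class TestLambdaSite:
    def test_defaults_match_production_setup(self):
        s = LambdaSite("asp")
        assert s.lambda_mass == 5.0
        assert (s.prot_threshold, s.deprot_threshold) == (0.2, 0.8)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"prot_threshold": 0.9},  # thresholds out of order
            {"lambda_mass": 0.0},
            {"n_states": 3},  # multisite required
            {"representation": "multisite", "n_states": 1},
        ],
    )
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            LambdaSite("bad", **kwargs)


class TestCorrectionPotential:
    def test_constant_dvdl_integrates_to_minus_c0_lambda(self):
        cp = CorrectionPotential.from_dvdl([3.5])
        assert eval_vmm(cp, 1.0) == pytest.approx(-3.5)
        assert eval_vmm(cp, 0.0) == 0.0

    def test_vmm_matches_trapezoid_oracle_for_cubic(self):
        # oracle: dense trapezoid integration of the known cubic
        coeffs = [10.0, -40.0, 25.0, 8.0]
        cp = CorrectionPotential.from_dvdl(coeffs)
        lam = np.linspace(0.0, 1.0, 100)
        dense = np.linspace(0.0, 1.0, 20001)
        curve = np.polynomial.polynomial.polyval(dense, coeffs)
        from scipy.integrate import cumulative_trapezoid

        vtrapz = -cumulative_trapezoid(curve, dense, initial=0.0)
        expected = np.interp(lam, dense, vtrapz)
        assert np.allclose(cp.value(lam), expected, atol=1e-6)

    def test_extrapolation_warns(self):
        cp = CorrectionPotential.from_dvdl([1.0], fit_domain=(-0.1, 1.1))
        with pytest.warns(ExtrapolationWarning):
            eval_vmm(cp, 2.0)

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(InvalidModelError):
            CorrectionPotential.from_dvdl([np.nan, 1.0])

    def test_inconsistent_vmm_rejected(self):
        with pytest.raises(InvalidModelError):
            CorrectionPotential(
                dvdl_coeffs=[1.0], vmm_coeffs=[0.0, 2.0], fit_order=0
            )

    def test_json_round_trip(self):
        cp = CorrectionPotential.from_dvdl([1.0, -2.0, 3.0], mean_abs_error_dvdl=0.1)
        cp2 = CorrectionPotential.from_dict(cp.to_dict())
        assert np.array_equal(cp2.dvdl_coeffs, cp.dvdl_coeffs)
        assert np.array_equal(cp2.vmm_coeffs, cp.vmm_coeffs)


class TestPHPotential:
    def test_flat_at_ph_equal_pka(self):
        p = PHPotentialParams(pH=4.0, pKa=4.0)
        assert np.all(eval_vph(p, np.linspace(-0.1, 1.1, 13)) == 0.0)

    def test_zero_at_lambda_zero(self):
        assert eval_vph(PHPotentialParams(pH=7.0, pKa=4.0), 0.0) == 0.0

    def test_hand_value(self):
        # pKa - pH = -1 at 300 K, lambda = 1: -ln(10) kB 300 ~ -5.743 kJ/mol
        p = PHPotentialParams(pH=5.0, pKa=4.0, temperature=300.0)
        assert eval_vph(p, 1.0) == pytest.approx(-LN10 * KB * 300.0)
        assert eval_vph(p, 1.0) == pytest.approx(-5.743, abs=2e-3)


class TestBiasPotential:
    def test_flat_when_zero_barrier(self):
        b = BiasPotentialParams(0.0)
        lam = np.linspace(-0.05, 1.05, 23)
        assert np.all(eval_vbias(b, lam) == 0.0)

    def test_barrier_height_at_center(self):
        b = BiasPotentialParams(7.5)
        assert eval_vbias(b, 0.5) == pytest.approx(7.5)

    def test_end_states_unbiased(self):
        b = BiasPotentialParams(7.5)
        assert abs(eval_vbias(b, 0.0)) <= 1e-6 * 7.5
        assert abs(eval_vbias(b, 1.0)) <= 1e-6 * 7.5

    def test_walls_rise_outside_bounds(self):
        b = BiasPotentialParams(7.5)
        v1, v2 = eval_vbias(b, -0.5), eval_vbias(b, -0.8)
        assert v1 > 100.0 and v2 > v1
        assert eval_vbias(b, 1.6) > 100.0

    def test_wall_bounds_must_contain_unit_interval(self):
        with pytest.raises(ValueError):
            BiasPotentialParams(0.0, wall_bounds=(0.2, 1.1))


class TestTorsion:
    def test_single_term_extremes(self):
        k = 5.0
        t = TorsionModel(base_terms=[(k, 3, 0.0)])
        assert eval_torsion(t, 0.0) == pytest.approx(2 * k)  # cos(0)=1 maximum
        assert eval_torsion(t, math.pi / 3) == pytest.approx(0.0)  # minimum

    def test_zero_correction_is_identity(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 2 * math.pi, 1000)
        base = TorsionModel(base_terms=[(3.0, 2, 0.4)])
        corr = TorsionModel(base_terms=[(3.0, 2, 0.4)], correction_terms=[(0.0, 2, 0.0)])
        assert np.allclose(eval_torsion(base, phi), eval_torsion(corr, phi))

    def test_aligned_correction_lowers_barrier_by_eps(self):
        k, eps = 8.0, 4.0
        t = TorsionModel(base_terms=[(k, 3, 0.0)], correction_terms=[(eps, 3, 0.0)])
        phi = np.linspace(0, 2 * math.pi, 3600, endpoint=False)
        e = eval_torsion(t, phi)
        assert e.max() - e.min() == pytest.approx(2 * k - eps, abs=1e-3)

    @given(
        phi=st.floats(-10.0, 10.0),
        k=st.floats(0.0, 30.0),
        n=st.integers(1, 4),
        delta=st.floats(0.0, 6.28),
    )
    def test_two_pi_periodicity(self, phi, k, n, delta):
        t = TorsionModel(base_terms=[(k, n, delta)], correction_terms=[(k / 2, n, 0.1)])
        assert eval_torsion(t, phi) == pytest.approx(
            eval_torsion(t, phi + 2 * math.pi), abs=1e-9, rel=1e-12
        )

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            TorsionModel(base_terms=[(-1.0, 3, 0.0)])
        with pytest.raises(ValueError):
            TorsionModel(correction_terms=[(1.0, 0, 0.0)])

    def test_yaml_dict_round_trip_uses_degrees(self):
        t = TorsionModel(base_terms=[(8.0, 3, math.radians(60.0))])
        d = t.to_dict()
        assert d["base_terms"][0]["phase_deg"] == pytest.approx(60.0)
        t2 = TorsionModel.from_dict(d)
        phi = np.linspace(0, 6, 50)
        assert np.allclose(t.value(phi), t2.value(phi))


def _num_force(fun, x, h=1e-6):
    return -(fun(x + h) - fun(x - h)) / (2 * h)


class TestForceConsistency:
    """Analytic forces match central-difference derivatives of the energies."""

    def test_all_potentials(self):
        rng = np.random.default_rng(1)
        cp = CorrectionPotential.from_dvdl([10.0, -40.0, 25.0, 8.0])
        ph = PHPotentialParams(pH=6.0, pKa=4.0)
        bias = BiasPotentialParams(7.5, wall_stiffness=1000.0)
        tor = TorsionModel(base_terms=[(8.0, 3, 0.3)], correction_terms=[(2.0, 3, 0.1)])
        x = rng.uniform(-0.3, 1.3, 100)
        for obj in (cp, ph, bias):
            num = np.array([_num_force(obj.value, xi) for xi in x])
            ana = np.array([obj.force(xi) for xi in x])
            assert np.allclose(ana, num, rtol=1e-5, atol=1e-3)
        phi = rng.uniform(0, 2 * math.pi, 100)
        num = np.array([_num_force(tor.value, p) for p in phi])
        assert np.allclose(tor.force(phi), num, rtol=1e-5, atol=1e-4)


class TestPotentialSet:
    def test_sum_of_parts_no_cross_terms(self):
        cp = CorrectionPotential.from_dvdl([5.0, -3.0])
        ph = PHPotentialParams(pH=5.0, pKa=4.0)
        bias = BiasPotentialParams(7.5)
        pot = PotentialSet(env=[1.0, 2.0], correction=cp, ph=ph, bias=bias)
        lam = np.linspace(0, 1, 17)
        parts = (
            np.polynomial.polynomial.polyval(lam, [1.0, 2.0])
            + cp.value(lam)
            + ph.value(lam)
            + bias.value(lam)
        )
        assert np.allclose(pot.value(lam), parts, rtol=0, atol=1e-12)

    def test_tabulated_env_is_accepted(self):
        lam = np.linspace(-0.1, 1.1, 25)
        tab = (lam, 3.0 - 2.0 * lam + 5.0 * lam**2)
        pot = PotentialSet(env=tab)
        assert pot.value(0.5) == pytest.approx(3.0 - 1.0 + 1.25, abs=1e-8)
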