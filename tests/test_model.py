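"""Rate laws, stoichiometry, Jacobian and feedback hooks of the core model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import approx_fprime

from nutriredox.model import (
    STATE_NAMES,
    ContractViolationError,
    FeedbackConfiguration,
    NutrientEnvironment,
    RedoxState,
    apply_feedback_perturbation,
    compute_fluxes,
    derivative,
    fluxes_to_derivative,
    jacobian,
)

from conftest import jitter_params


def _random_state(rng, params):
    vals = {
        "cys2_in": rng.uniform(1, 500),
        "cys": rng.uniform(1, 300),
        "glu": rng.uniform(100, 5000),
        "nadph": rng.uniform(0.01, 0.99) * params.NADP_total,
        "gsh": rng.uniform(10, 4000),
        "gssg": rng.uniform(0.1, 1000),
        "ros": rng.uniform(1e-4, 5),
        "ca": rng.uniform(0.01, 2),
        "pptase_red": rng.uniform(0.01, 0.99) * params.PPTase_total,
        "tk_phos": rng.uniform(0.01, 0.99) * params.TK_total,
    }
    return RedoxState(**vals)


def _reference_fluxes(s, e, p):
    """Independent re-implementation of the printed rate laws."""
    sat_c2 = e.cys2_ext / (p.K_cys2_import + e.cys2_ext)
    sat_glc = e.glc_ext / (p.K_glc_import + e.glc_ext)
    sat_gln = e.gln_ext / (p.K_gln_import + e.gln_ext)
    out = {}
    out["cystine_uptake"] = p.k_cys2_import * sat_c2 * p.SLC7A11 * s.glu
    out["cystine_reduction"] = p.k_cys2_reduction * s.cys2_in * s.nadph
    out["gsh_synthesis"] = p.k_gsh_production * s.cys * s.glu
    out["glutamate_production"] = p.k_glu_production * sat_gln
    out["nadph_regen_glc"] = (p.k_nadp_reduction_glc * sat_glc
                             * (p.NADP_total - s.nadph) * (1 + p.switch_nadp_import))
    out["nadph_regen_glu"] = (p.k_nadp_reduction_glu * s.glu
                              * (p.NADP_total - s.nadph) * (1 - p.switch_nadp_import))
    out["gsh_oxidation"] = p.k_gsh_oxidation * s.ros * s.gsh**2
    out["gsh_regeneration"] = p.k_gsh_reduction * s.nadph * s.gssg
    hill = p.K_ros_inhibition**p.n1 / (p.K_ros_inhibition**p.n1 + s.ros**p.n1)
    partition = (p.k_ros_production_basal * (1 - p.f_ros_from_glc - p.f_ros_from_glu)
                 + p.k_ros_production_from_glc * sat_glc * p.f_ros_from_glc
                 + p.k_ros_production_from_glu * s.glu
                 / (p.K_glu_import_ros + s.glu) * p.f_ros_from_glu)
    out["ros_production"] = partition * s.ca * s.tk_phos * hill
    out["ros_degradation"] = p.k_ros_degradation * s.gsh**2 * s.ros
    out["ca_import_ros"] = p.k_ca_import_ros * s.ros
    out["pptase_reduction"] = (p.k_pptase_reduction_gsh * s.gsh
                               * (p.PPTase_total - s.pptase_red))
    out["tk_dephosphorylation"] = p.k_tk_dephosphorylation * s.pptase_red * s.tk_phos
    return out


class TestComputeFluxes:
    def test_hill_factor_edge_cases(self, params, env, high_state):
        s0 = RedoxState(**{**{n: getattr(high_state, n) for n in STATE_NAMES},
                           "ros": 0.0, "gssg": 0.0})
        fx = compute_fluxes(s0, env, params)
        assert fx.ros_autoinhibition_factor == 1.0
        assert fx.gsh_oxidation == 0.0
        s_half = RedoxState(**{**{n: getattr(high_state, n) for n in STATE_NAMES},
                               "ros": params.K_ros_inhibition})
        fx = compute_fluxes(s_half, env, params)
        assert fx.ros_autoinhibition_factor == pytest.approx(0.5, rel=1e-12)

    def test_exhausted_nadp_pool_stops_regeneration(self, params, env, high_state):
        s = RedoxState(**{**{n: getattr(high_state, n) for n in STATE_NAMES},
                          "nadph": params.NADP_total})
        fx = compute_fluxes(s, env, params)
        assert fx.nadph_regen_glc == 0.0
        assert fx.nadph_regen_glu == 0.0

    def test_fluxes_match_independent_formulas(self, params, env, rng):
        for _ in range(20):
            p = jitter_params(params, rng)
            s = _random_state(rng, p)
            fx = compute_fluxes(s, env, p)
            ref = _reference_fluxes(s, env, p)
            for name, expected in ref.items():
                assert getattr(fx, name) == pytest.approx(expected, rel=1e-12), name

    def test_antiport_coupling_exact(self, params, env, rng):
        s = _random_state(rng, params)
        fx = compute_fluxes(s, env, params)
        assert fx.glutamate_export_via_antiport == fx.cystine_uptake

    def test_negative_concentration_rejected(self, params, env, high_state):
        with pytest.raises(ContractViolationError):
            bad = RedoxState(**{**{n: getattr(high_state, n) for n in STATE_NAMES},
                                "gsh": -1.0})
            compute_fluxes(bad, env, params)

    def test_nadph_above_total_rejected(self, params, env, high_state):
        bad = RedoxState(**{**{n: getattr(high_state, n) for n in STATE_NAMES},
                            "nadph": 2 * params.NADP_total})
        with pytest.raises(ContractViolationError):
            compute_fluxes(bad, env, params)


class TestDerivative:
    def test_flux_derivative_identity(self, params, env, rng):
        """The rate vector equals the signed stoichiometric sum of fluxes."""
        for _ in range(10):
            s = _random_state(rng, params)
            d = derivative(s, env, params)
            d2 = fluxes_to_derivative(compute_fluxes(s, env, params))
            np.testing.assert_array_equal(d, d2)

    def test_gssg_no_source_no_sink(self, params, env, high_state):
        s = RedoxState(**{**{n: getattr(high_state, n) for n in STATE_NAMES},
                          "gssg": 0.0, "ros": 0.0})
        d = derivative(s, env, params)
        assert d[STATE_NAMES.index("gssg")] == 0.0

    def test_gsh_gssg_stoichiometry_factors(self, params, env, rng):
        """dGSH/dt carries 2x the regeneration/oxidation event fluxes."""
        s = _random_state(rng, params)
        fx = compute_fluxes(s, env, params)
        d = derivative(s, env, params)
        i_gsh, i_gssg = STATE_NAMES.index("gsh"), STATE_NAMES.index("gssg")
        assert d[i_gsh] == pytest.approx(
            2 * fx.gsh_regeneration + fx.gsh_synthesis
            - 2 * fx.gsh_oxidation - fx.gsh_degradation, rel=1e-12)
        assert d[i_gssg] == pytest.approx(
            fx.gsh_oxidation - fx.gsh_regeneration - fx.gssg_degradation, rel=1e-12)

    def test_derivative_zero_at_calibrated_steady_state(self, params, env, high_state):
        d = derivative(high_state, env, params)
        assert np.max(np.abs(d)) < 1e-9


class TestJacobian:
    def test_matches_finite_differences(self, params, env, rng):
        from nutriredox.model import rhs

        for _ in range(5):
            p = jitter_params(params, rng, cv=0.2)
            s = _random_state(rng, p)
            y = s.to_array()
            J = jacobian(y, env, p)
            J_num = np.empty_like(J)
            for i in range(10):
                J_num[i] = approx_fprime(
                    y, lambda yy, i=i: rhs(0.0, yy, env, p)[i],
                    np.maximum(np.abs(y), 1e-6) * 1e-7)
            assert np.allclose(J, J_num, rtol=2e-4, atol=1e-7 * np.max(np.abs(J)))


class TestFeedbackPerturbation:
    def test_identity_at_unit_factors(self, params):
        out = apply_feedback_perturbation(params, FeedbackConfiguration())
        assert out == params

    def test_loop_constants_rescaled_together(self, params):
        cfg = FeedbackConfiguration(scale_cys2_nadph=0.25, scale_ros_gsh=0.5,
                                    scale_ros_ca=0.1, scale_ros_pptase_tk=0.0)
        out = apply_feedback_perturbation(params, cfg)
        assert out.k_cys2_reduction == 0.25 * params.k_cys2_reduction
        assert out.k_nadph_oxidation_cys2 == 0.25 * params.k_nadph_oxidation_cys2
        assert out.k_gsh_oxidation == 0.5 * params.k_gsh_oxidation
        assert out.k_ros_degradation == 0.5 * params.k_ros_degradation
        assert out.k_ca_import_ros == 0.1 * params.k_ca_import_ros
        assert out.k_pptase_oxidation_ros == 0.0
        # everything else untouched
        assert out.k_gsh_production == params.k_gsh_production
        assert out.SLC7A11 == params.SLC7A11

    @given(f=st.floats(min_value=-10, max_value=10))
    @settings(max_examples=20, deadline=None)
    def test_factor_bounds_enforced(self, f):
        if 0.0 <= f <= 1.0:
            FeedbackConfiguration(scale_ros_ca=f)
        else:
            with pytest.raises(ContractViolationError):
                FeedbackConfiguration(scale_ros_ca=f)


class TestNutrientEnvironment:
    def test_schedule_lookup_piecewise_constant(self):
        e = NutrientEnvironment(10000.0, 2000.0, 200.0,
                                schedule=((0.0, 0.0, 2000.0, 200.0),
                                          (60.0, 25.0, 2000.0, 200.0)))
        assert e.at(-1.0).glc_ext == 10000.0
        assert e.at(0.0).glc_ext == 0.0
        assert e.at(59.9).glc_ext == 0.0
        assert e.at(60.0).glc_ext == 25.0

    def test_schedule_times_must_increase(self):
        with pytest.raises(ContractViolationError):
            NutrientEnvironment(1.0, 1.0, 1.0,
                                schedule=((10.0, 1, 1, 1), (5.0, 1, 1, 1)))

    def test_negative_concentrations_rejected(self):
        with pytest.raises(ContractViolationError):
            NutrientEnvironment(-1.0, 1.0, 1.0)
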