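"""Steady-state calibration of the redox model's rate constants.

The estimator follows a two-stage closure procedure.  Stage 1 computes every
rate constant whose reaction flux is tabulated directly, by dividing the flux
by the product of the participating concentrations (and fixed saturation
factors).  Stage 2 assumes the tabulated state is a steady state and solves
each ODE balance that is left with exactly one unknown constant, iterating in
automatic dependency order until the system closes.  Signaling-loop constants
(calcium, phosphatase, kinase), whose absolute fluxes are typically unknown,
can instead be constrained by fold activations across the redox catastrophe
plus one timescale parameter per loop.

Everything here is linear in the unknown constants, so each extraction is a
single division and the round trip `calibrate(steady state of P) == P` is
exact to floating-point error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    PARAM_NAMES,
    STATE_NAMES,
    ContractViolationError,
    ModelParameters,
    NutrientEnvironment,
    RedoxState,
    compute_fluxes,
    derivative,
)

__all__ = [
    "SteadyStateConstraintSet",
    "CalibrationResult",
    "SteadyStateCalibration",
    "estimate_rate_constants",
    "verify_steady_state",
    "estimate_slc7a11_concentration",
    "constraints_from_model",
    "UnresolvableClosureError",
    "InfeasibleConstraintError",
]


class UnresolvableClosureError(ValueError):
    """A balance equation retained >= 2 unknown constants after stage 1."""


class InfeasibleConstraintError(ValueError):
    """A closure solve produced a negative rate constant."""


#: Parameters taken as given (literature/assumed inputs), never calibrated.
FIXED_PARAM_NAMES = (
    "K_cys2_import", "K_gln_import", "K_glc_import", "K_glu_import_ros",
    "f_ros_from_glc", "f_ros_from_glu", "K_ros_inhibition", "n1",
    "SLC7A11", "NADP_total", "PPTase_total", "TK_total", "switch_nadp_import",
)

RATE_PARAM_NAMES = tuple(n for n in PARAM_NAMES if n not in FIXED_PARAM_NAMES)

#: flux name -> (rate constant, coefficient so that flux = k * coefficient)
_FLUX_CONSTANT = {
    "cystine_uptake": "k_cys2_import",
    "cystine_reduction": "k_cys2_reduction",
    "cysteine_degradation": "k_cys_degradation",
    "gsh_synthesis": "k_gsh_production",
    "glutamate_production": "k_glu_production",
    "glutamate_degradation": "k_glu_degradation",
    "nadph_regen_glc": "k_nadp_reduction_glc",
    "nadph_regen_glu": "k_nadp_reduction_glu",
    "nadph_ox_anabolism": "k_nadph_oxidation_anabolism",
    "nadph_ox_cys2": "k_nadph_oxidation_cys2",
    "nadph_ox_gssg": "k_nadph_oxidation_gssg",
    "gsh_regeneration": "k_gsh_reduction",
    "gsh_oxidation": "k_gsh_oxidation",
    "gsh_degradation": "k_gsh_degradation",
    "gssg_degradation": "k_gsh_degradation",
    "ros_production_basal": "k_ros_production_basal",
    "ros_production_glc": "k_ros_production_from_glc",
    "ros_production_glu": "k_ros_production_from_glu",
    "ros_degradation": "k_ros_degradation",
    "ca_import_basal": "k_ca_import_basal",
    "ca_import_ros": "k_ca_import_ros",
    "ca_export": "k_ca_out",
    "pptase_reduction": "k_pptase_reduction_gsh",
    "pptase_oxidation": "k_pptase_oxidation_ros",
    "tk_phosphorylation": "k_tk_phosphorylation",
    "tk_dephosphorylation": "k_tk_dephosphorylation",
}

#: balance equations: state -> [(flux name, signed stoichiometry), ...]
_BALANCES = {
    "cys2_in": [("cystine_uptake", 1), ("cystine_reduction", -1)],
    "cys": [("cystine_reduction", 2), ("cysteine_degradation", -1),
            ("gsh_synthesis", -1)],
    "glu": [("glutamate_production", 1), ("glutamate_degradation", -1),
            ("gsh_synthesis", -1), ("cystine_uptake", -1)],
    "nadph": [("nadph_regen_glc", 1), ("nadph_regen_glu", 1),
              ("nadph_ox_anabolism", -1), ("nadph_ox_cys2", -1),
              ("nadph_ox_gssg", -1)],
    "gsh": [("gsh_regeneration", 2), ("gsh_synthesis", 1),
            ("gsh_oxidation", -2), ("gsh_degradation", -1)],
    "gssg": [("gsh_oxidation", 1), ("gsh_regeneration", -1),
             ("gssg_degradation", -1)],
    "ros": [("ros_production_basal", 1), ("ros_production_glc", 1),
            ("ros_production_glu", 1), ("ros_degradation", -1)],
    "ca": [("ca_import_basal", 1), ("ca_import_ros", 1), ("ca_export", -1)],
    "pptase_red": [("pptase_reduction", 1), ("pptase_oxidation", -1)],
    "tk_phos": [("tk_phosphorylation", 1), ("tk_dephosphorylation", -1)],
}

#: stoichiometric tie fallbacks (1:1 coupling of named reaction pairs),
#: applied only when a constant cannot be closed from the tables themselves.
_TIES = (
    ("k_nadph_oxidation_cys2", "k_cys2_reduction"),
    ("k_nadph_oxidation_gssg", "k_gsh_reduction"),
    ("k_ros_degradation", "k_gsh_oxidation"),
)


@dataclass
class SteadyStateConstraintSet:
    """Concentration/flux/fold-activation tables defining one calibration.

    ``concentrations`` must cover all ten state variables (µM).  ``fluxes``
    maps reaction names (see the model flux vocabulary) to µM/min values
    measured at the reference steady state.  ``fold_activations`` carries
    fold changes across the redox catastrophe ("ros", "ca") used to constrain
    the calcium loop; ``loop_timescales`` supplies the one absolute rate per
    signaling loop that fold data cannot fix ("ca": calcium export 1/min,
    "pptase": phosphatase oxidation 1/(µM·min), "tk": kinase phosphorylation
    1/min).  ``fixed`` holds the literature/assumed parameters (saturation
    constants, totals, partition fractions, Hill exponent, SLC7A11, switch).
    """

    concentrations: dict
    fluxes: dict
    environment: NutrientEnvironment
    fixed: dict
    fold_activations: dict = field(default_factory=dict)
    loop_timescales: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [n for n in STATE_NAMES if n not in self.concentrations]
        if missing:
            raise ContractViolationError(f"missing steady-state concentrations: {missing}")
        unknown = [n for n in self.fluxes if n not in _FLUX_CONSTANT]
        if unknown:
            raise ContractViolationError(f"unknown reaction names in flux table: {unknown}")
        missing_fixed = [n for n in FIXED_PARAM_NAMES if n not in self.fixed]
        if missing_fixed:
            raise ContractViolationError(f"missing fixed parameters: {missing_fixed}")

    def state(self) -> RedoxState:
        return RedoxState(**{n: float(self.concentrations[n]) for n in STATE_NAMES})


def _coefficients(cs: SteadyStateConstraintSet) -> dict:
    """flux -> coefficient such that flux = k * coefficient, at the tabulated
    state; all coefficients use only concentrations and fixed parameters."""
    c = cs.concentrations
    fx = cs.fixed
    env = cs.environment.at(0.0)
    sat_c2 = env.cys2_ext / (fx["K_cys2_import"] + env.cys2_ext) if env.cys2_ext > 0 else 0.0
    sat_glc = env.glc_ext / (fx["K_glc_import"] + env.glc_ext) if env.glc_ext > 0 else 0.0
    sat_gln = env.gln_ext / (fx["K_gln_import"] + env.gln_ext) if env.gln_ext > 0 else 0.0
    glu = c["glu"]
    sat_glu_ros = glu / (fx["K_glu_import_ros"] + glu) if glu > 0 else 0.0
    Kn = fx["K_ros_inhibition"] ** fx["n1"]
    hill = Kn / (Kn + c["ros"] ** fx["n1"])
    nadp_free = fx["NADP_total"] - c["nadph"]
    sig = c["ca"] * c["tk_phos"] * hill
    return {
        "cystine_uptake": sat_c2 * fx["SLC7A11"] * glu,
        "cystine_reduction": c["cys2_in"] * c["nadph"],
        "cysteine_degradation": c["cys"],
        "gsh_synthesis": c["cys"] * glu,
        "glutamate_production": sat_gln,
        "glutamate_degradation": glu,
        "nadph_regen_glc": sat_glc * nadp_free * (1 + fx["switch_nadp_import"]),
        "nadph_regen_glu": glu * nadp_free * (1 - fx["switch_nadp_import"]),
        "nadph_ox_anabolism": c["nadph"],
        "nadph_ox_cys2": c["cys2_in"] * c["nadph"],
        "nadph_ox_gssg": c["gssg"] * c["nadph"],
        "gsh_regeneration": c["nadph"] * c["gssg"],
        "gsh_oxidation": c["ros"] * c["gsh"] ** 2,
        "gsh_degradation": c["gsh"],
        "gssg_degradation": c["gssg"],
        "ros_production_basal": (1 - fx["f_ros_from_glc"] - fx["f_ros_from_glu"]) * sig,
        "ros_production_glc": sat_glc * fx["f_ros_from_glc"] * sig,
        "ros_production_glu": sat_glu_ros * fx["f_ros_from_glu"] * sig,
        "ros_degradation": c["gsh"] ** 2 * c["ros"],
        "ca_import_basal": 1.0,
        "ca_import_ros": c["ros"],
        "ca_export": c["ca"],
        "pptase_reduction": c["gsh"] * (fx["PPTase_total"] - c["pptase_red"]),
        "pptase_oxidation": c["ros"] * c["pptase_red"],
        "tk_phosphorylation": fx["TK_total"] - c["tk_phos"],
        "tk_dephosphorylation": c["pptase_red"] * c["tk_phos"],
    }


def _signaling_from_folds(cs: SteadyStateConstraintSet, known: dict, prov: dict):
    """Constrain loop constants from fold activations + one timescale each."""
    c = cs.concentrations
    folds = cs.fold_activations
    ts = cs.loop_timescales
    if "ca" in ts and "k_ca_out" not in known:
        if not {"ros", "ca"} <= set(folds):
            raise ContractViolationError(
                "calcium-loop timescale given but fold_activations lack 'ros'/'ca'")
        k_co = float(ts["ca"])
        ros_lo, ca_lo = c["ros"], c["ca"]
        rf, cf = float(folds["ros"]), float(folds["ca"])
        if rf <= 1:
            raise InfeasibleConstraintError("ros fold activation must exceed 1")
        k_cr = k_co * ca_lo * (cf - 1.0) / (ros_lo * (rf - 1.0))
        k_cb = k_co * ca_lo - k_cr * ros_lo
        if min(k_cr, k_cb) < 0:
            raise InfeasibleConstraintError("calcium-loop fold constraints are infeasible")
        known.update(k_ca_out=k_co, k_ca_import_ros=k_cr, k_ca_import_basal=k_cb)
        prov.update(k_ca_out="timescale", k_ca_import_ros="fold_activation",
                    k_ca_import_basal="fold_activation")
    if "pptase" in ts and "k_pptase_oxidation_ros" not in known:
        k_po = float(ts["pptase"])
        denom = c["gsh"] * (cs.fixed["PPTase_total"] - c["pptase_red"])
        if denom <= 0:
            raise InfeasibleConstraintError("phosphatase ratio constraint needs pptase_red < PPTase_total")
        k_pr = k_po * c["ros"] * c["pptase_red"] / denom
        known.update(k_pptase_oxidation_ros=k_po, k_pptase_reduction_gsh=k_pr)
        prov.update(k_pptase_oxidation_ros="timescale",
                    k_pptase_reduction_gsh="fold_activation")
    if "tk" in ts and "k_tk_phosphorylation" not in known:
        k_tp = float(ts["tk"])
        denom = c["pptase_red"] * c["tk_phos"]
        if denom <= 0:
            raise InfeasibleConstraintError("kinase ratio constraint needs positive pptase_red and tk_phos")
        k_td = k_tp * (cs.fixed["TK_total"] - c["tk_phos"]) / denom
        known.update(k_tk_phosphorylation=k_tp, k_tk_dephosphorylation=k_td)
        prov.update(k_tk_phosphorylation="timescale",
                    k_tk_dephosphorylation="fold_activation")


@dataclass
class CalibrationResult:
    """Calibrated parameters, per-equation residuals and provenance."""

    params: ModelParameters
    residuals: pd.Series  # relative steady-state residual per equation
    provenance: pd.Series  # parameter -> {fixed|direct|closure|tie|fold_activation|timescale}
    constraints: SteadyStateConstraintSet

    @property
    def max_residual(self) -> float:
        return float(self.residuals.max())

    def summary(self) -> str:
        lines = ["Steady-state calibration", "=" * 58]
        lines.append(f"{'parameter':<30}{'value':>16}  source")
        for name in PARAM_NAMES:
            lines.append(f"{name:<30}{getattr(self.params, name):>16.6g}  "
                         f"{self.provenance.get(name, '?')}")
        lines.append("-" * 58)
        lines.append("relative steady-state residual per balance equation:")
        for eq, r in self.residuals.items():
            lines.append(f"  d{eq}/dt {r:>12.3e}")
        return "\n".join(lines)


class SteadyStateCalibration:
    """Model object: calibrate rate constants from steady-state tables.

    Usage::

        cal = SteadyStateCalibration(constraints)
        result = cal.fit()
        params = result.params
    """

    def __init__(self, constraints: SteadyStateConstraintSet):
        self.constraints = constraints

    def fit(self) -> CalibrationResult:
        cs = self.constraints
        coef = _coefficients(cs)
        known: dict = {}
        prov: dict = {n: "fixed" for n in FIXED_PARAM_NAMES}

        # stage 1: direct division for tabulated fluxes
        for flux_name, v in cs.fluxes.items():
            k_name = _FLUX_CONSTANT[flux_name]
            cf = coef[flux_name]
            if cf <= 0:
                if v == 0:
                    continue  # zero/zero: leave for closure or ties
                raise InfeasibleConstraintError(
                    f"flux {flux_name!r} is nonzero but its concentration product vanishes")
            k = float(v) / cf
            if k < 0:
                raise InfeasibleConstraintError(f"negative constant for {flux_name!r}")
            if k_name in known and not math.isclose(known[k_name], k, rel_tol=1e-9, abs_tol=1e-30):
                raise InfeasibleConstraintError(
                    f"inconsistent direct constraints for {k_name!r}")
            known[k_name] = k
            prov[k_name] = "direct"

        # signaling loops from fold activations + timescales, when given
        _signaling_from_folds(cs, known, prov)

        # stage 2: iterate single-unknown balance closures (automatic
        # dependency order), with stoichiometric ties as a last resort
        ties = list(_TIES)
        while True:
            progressed = False
            for eq, terms in _BALANCES.items():
                unknown_terms = {}
                acc = 0.0
                for flux_name, stoich in terms:
                    k_name = _FLUX_CONSTANT[flux_name]
                    if k_name in known:
                        acc += stoich * known[k_name] * coef[flux_name]
                    else:
                        unknown_terms.setdefault(k_name, 0.0)
                        unknown_terms[k_name] += stoich * coef[flux_name]
                if len(unknown_terms) != 1:
                    continue
                (k_name, cf), = unknown_terms.items()
                if cf == 0:
                    continue
                k = -acc / cf
                if k < -1e-9 * max(1.0, abs(acc)):
                    raise InfeasibleConstraintError(
                        f"closure of d{eq}/dt yields negative {k_name} = {k:.3g}")
                known[k_name] = max(k, 0.0)
                prov[k_name] = "closure"
                progressed = True
            if progressed:
                continue
            applied_tie = False
            for target, source in ties:
                if target not in known and source in known:
                    known[target] = known[source]
                    prov[target] = "tie"
                    ties.remove((target, source))
                    applied_tie = True
                    break
            if not applied_tie:
                break

        missing = [n for n in RATE_PARAM_NAMES if n not in known]
        if missing:
            bad_eqs = [eq for eq, terms in _BALANCES.items()
                       if any(_FLUX_CONSTANT[f] in missing for f, _ in terms)]
            raise UnresolvableClosureError(
                f"cannot close constants {missing}; balance equations "
                f"{bad_eqs} retain more than one unknown")

        params = ModelParameters(**{**{n: float(cs.fixed[n]) for n in FIXED_PARAM_NAMES},
                                    **known})
        residuals = verify_steady_state(params, cs.state(), cs.environment)
        return CalibrationResult(params=params, residuals=residuals,
                                 provenance=pd.Series(prov), constraints=cs)


def estimate_rate_constants(constraints: SteadyStateConstraintSet):
    """Functional façade over :class:`SteadyStateCalibration`.

    Returns ``(params, residual_report)``.
    """
    res = SteadyStateCalibration(constraints).fit()
    return res.params, res.residuals


def verify_steady_state(
    params: ModelParameters,
    state: RedoxState,
    env: NutrientEnvironment,
    tolerance: float = 1e-8,
) -> pd.Series:
    """Per-equation |d/dt| relative to the largest flux in that equation."""
    from .steadystate import _scale_per_equation

    y = state.to_array()
    f = derivative(state, env, params, validate=False)
    scale = _scale_per_equation(y, env.at(state.time), params)
    rel = np.abs(f) / scale
    out = pd.Series(rel, index=list(STATE_NAMES), name="relative_residual")
    out.attrs["pass"] = bool(out.max() < tolerance)
    out.attrs["tolerance"] = tolerance
    return out


def estimate_slc7a11_concentration(target_ppm, reference_ppm, reference_molar):
    """Convert proteomic abundance (ppm) to molarity via a reference protein.

    Scalars give a scalar; ``(lo, hi)`` ranges give an interval.  The
    canonical use converts SLC7A11 ppm to µM with actin as the reference.
    """
    def _as_range(x):
        if np.iterable(x):
            lo, hi = float(min(x)), float(max(x))
        else:
            lo = hi = float(x)
        return lo, hi

    t_lo, t_hi = _as_range(target_ppm)
    r_lo, r_hi = _as_range(reference_ppm)
    if r_lo <= 0:
        raise ContractViolationError("reference abundance must be positive")
    if t_lo < 0:
        raise ContractViolationError("target abundance must be non-negative")
    m_lo, m_hi = _as_range(reference_molar)
    lo = t_lo / r_hi * m_lo
    hi = t_hi / r_lo * m_hi
    if lo == hi:
        return lo
    return (lo, hi)


def constraints_from_model(
    params: ModelParameters,
    env: NutrientEnvironment,
    state: RedoxState | None = None,
    signaling_mode: str = "flux",
    ros_fold: float = 100.0,
) -> SteadyStateConstraintSet:
    """Build a self-consistent constraint set from a model steady state.

    With ``signaling_mode='flux'`` the signaling-loop fluxes are tabulated
    directly (full parameter recovery for arbitrary admissible parameters);
    with ``'fold'`` the loops are encoded as fold activations plus timescales,
    mirroring calibration from fold-change data.
    """
    if state is None:
        from .dynamics import steady_initial_state

        state = steady_initial_state(env, params, branch="high_gsh")
    fx = compute_fluxes(state, env, params)
    flux_table = {
        "cystine_uptake": fx.cystine_uptake,
        "gsh_synthesis": fx.gsh_synthesis,
        "glutamate_production": fx.glutamate_production,
        "nadph_regen_glc": fx.nadph_regen_glc,
        "nadph_regen_glu": fx.nadph_regen_glu,
        "nadph_ox_anabolism": fx.nadph_ox_anabolism,
        "nadph_ox_gssg": fx.nadph_ox_gssg,
        "gsh_oxidation": fx.gsh_oxidation,
        "gsh_degradation": fx.gsh_degradation,
        "ros_production_basal": fx.ros_production_basal_part * state.ca
        * state.tk_phos * fx.ros_autoinhibition_factor,
        "ros_production_glc": fx.ros_production_glc_part * state.ca
        * state.tk_phos * fx.ros_autoinhibition_factor,
        "ros_production_glu": fx.ros_production_glu_part * state.ca
        * state.tk_phos * fx.ros_autoinhibition_factor,
    }
    folds = {}
    timescales = {}
    if signaling_mode == "flux":
        flux_table.update(
            ca_import_basal=fx.ca_import_basal,
            ca_import_ros=fx.ca_import_ros,
            ca_export=fx.ca_export,
            pptase_reduction=fx.pptase_reduction,
            pptase_oxidation=fx.pptase_oxidation,
            tk_phosphorylation=fx.tk_phosphorylation,
            tk_dephosphorylation=fx.tk_dephosphorylation,
        )
    elif signaling_mode == "fold":
        timescales = {"ca": params.k_ca_out,
                      "pptase": params.k_pptase_oxidation_ros,
                      "tk": params.k_tk_phosphorylation}
        # calcium fold consistent with the model's own coupling constant
        ca_fold = 1.0 + params.k_ca_import_ros * state.ros * (ros_fold - 1.0) / (
            params.k_ca_out * state.ca)
        folds = {"ros": ros_fold, "ca": ca_fold}
    else:
        raise ContractViolationError("signaling_mode must be 'flux' or 'fold'")
    return SteadyStateConstraintSet(
        concentrations={n: getattr(state, n) for n in STATE_NAMES},
        fluxes=flux_table,
        environment=env,
        fixed={n: getattr(params, n) for n in FIXED_PARAM_NAMES},
        fold_activations=folds,
        loop_timescales=timescales,
    )
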