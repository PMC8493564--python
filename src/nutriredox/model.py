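"""Core definitions of the nutrient-redox kinetic model.

The model tracks ten intracellular quantities (concentrations in µM, time in
minutes): intracellular cystine, cysteine, glutamate, NADPH, reduced and
oxidized glutathione (GSH/GSSG), a lumped reactive-oxygen-species pool (ROS,
proxying H2O2), cytosolic calcium, reduced (active) tyrosine phosphatase and
phosphorylated (active) tyrosine kinase.  Extracellular glucose, glutamine and
cystine are inputs, not state variables.

Conserved moieties are represented algebraically: NADP+ is
``NADP_total - nadph``, oxidized phosphatase is ``PPTase_total - pptase_red``
and unphosphorylated kinase is ``TK_total - tk_phos``; they are never
integrated separately.

All rate laws are mass action except nutrient transport (hyperbolic in the
extracellular nutrient) and ROS autoinhibition (a decreasing Hill function).
Removal of one ROS consumes two GSH, making GSH oxidation third order; cystine
uptake through the cystine/glutamate antiporter (SLC7A11/xCT) exports one
glutamate per cystine imported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "STATE_NAMES",
    "PARAM_NAMES",
    "FLUX_NAMES",
    "RedoxState",
    "NutrientEnvironment",
    "ModelParameters",
    "FeedbackConfiguration",
    "FluxBreakdown",
    "compute_fluxes",
    "derivative",
    "jacobian",
    "apply_feedback_perturbation",
    "RedoxModel",
]

#: Canonical ordering of the dynamical variables in every state vector.
STATE_NAMES = (
    "cys2_in",
    "cys",
    "glu",
    "nadph",
    "gsh",
    "gssg",
    "ros",
    "ca",
    "pptase_red",
    "tk_phos",
)


class ContractViolationError(ValueError):
    """A precondition on states, parameters or environments was violated."""


class NumericModelError(ArithmeticError):
    """A rate-law evaluation produced a non-finite value."""


@dataclass(frozen=True)
class RedoxState:
    """The ten dynamical concentrations (µM) at one instant (minutes)."""

    cys2_in: float
    cys: float
    glu: float
    nadph: float
    gsh: float
    gssg: float
    ros: float
    ca: float
    pptase_red: float
    tk_phos: float
    time: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float], time: float = 0.0) -> "RedoxState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_NAMES),):
            raise ContractViolationError(
                f"state vector must have length {len(STATE_NAMES)}, got {y.shape}"
            )
        return cls(**dict(zip(STATE_NAMES, map(float, y))), time=time)

    def validate(self, params: "ModelParameters | None" = None) -> None:
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise NumericModelError(f"state variable {name!r} is not finite: {v}")
            if v < 0:
                raise ContractViolationError(f"state variable {name!r} is negative: {v}")
        if params is not None:
            if self.nadph > params.NADP_total * (1 + 1e-9):
                raise ContractViolationError("nadph exceeds NADP_total")
            if self.pptase_red > params.PPTase_total * (1 + 1e-9):
                raise ContractViolationError("pptase_red exceeds PPTase_total")
            if self.tk_phos > params.TK_total * (1 + 1e-9):
                raise ContractViolationError("tk_phos exceeds TK_total")


@dataclass(frozen=True)
class NutrientEnvironment:
    """Extracellular nutrient concentrations (µM), optionally scheduled.

    ``schedule`` is an ordered list of ``(t_switch_min, glc, gln, cys2)``
    segments; the top-level concentrations apply before the first switch time.
    Switches are instantaneous (piecewise-constant media composition).
    """

    glc_ext: float
    gln_ext: float
    cys2_ext: float
    schedule: tuple = ()

    def __post_init__(self):
        for name in ("glc_ext", "gln_ext", "cys2_ext"):
            if getattr(self, name) < 0:
                raise ContractViolationError(f"{name} must be non-negative")
        times = [seg[0] for seg in self.schedule]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ContractViolationError("schedule times must be strictly increasing")
        for seg in self.schedule:
            if len(seg) != 4:
                raise ContractViolationError(
                    "schedule segments are (t_switch_min, glc, gln, cys2)"
                )
            if any(c < 0 for c in seg[1:]):
                raise ContractViolationError("scheduled concentrations must be >= 0")

    def at(self, t: float) -> "NutrientEnvironment":
        """The constant environment in effect at time ``t`` (minutes)."""
        glc, gln, cys2 = self.glc_ext, self.gln_ext, self.cys2_ext
        for t_sw, g, q, c in self.schedule:
            if t >= t_sw:
                glc, gln, cys2 = g, q, c
            else:
                break
        return NutrientEnvironment(glc, gln, cys2)

    @property
    def switch_times(self) -> tuple:
        return tuple(seg[0] for seg in self.schedule)


#: Parameter fields that are plain rate or saturation constants (must be >= 0).
_RATE_CONSTANT_NAMES = (
    "k_cys2_import",
    "K_cys2_import",
    "k_cys2_reduction",
    "k_cys_degradation",
    "k_gsh_production",
    "k_glu_production",
    "K_gln_import",
    "k_glu_degradation",
    "k_nadp_reduction_glc",
    "K_glc_import",
    "k_nadp_reduction_glu",
    "k_nadph_oxidation_anabolism",
    "k_nadph_oxidation_cys2",
    "k_nadph_oxidation_gssg",
    "k_gsh_reduction",
    "k_gsh_oxidation",
    "k_gsh_degradation",
    "k_ros_degradation",
    "k_ros_production_basal",
    "k_ros_production_from_glc",
    "k_ros_production_from_glu",
    "K_glu_import_ros",
    "K_ros_inhibition",
    "k_ca_import_basal",
    "k_ca_import_ros",
    "k_ca_out",
    "k_pptase_reduction_gsh",
    "k_pptase_oxidation_ros",
    "k_tk_phosphorylation",
    "k_tk_dephosphorylation",
    "SLC7A11",
)


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, saturation constants, totals and handles.

    Units follow the µM/min convention throughout: first-order constants in
    1/min, bimolecular constants in 1/(µM·min), trimolecular constants in
    1/(µM²·min); saturation constants and totals in µM.
    ``switch_nadp_import`` in [-1, 1] biases NADPH regeneration between the
    glucose (oxPPP) route (+1: fully glucose-dependent) and the glutamate
    (TCA-associated) route (-1).  ``f_ros_from_glc``/``f_ros_from_glu``
    partition ROS production between glucose metabolism, glutamate metabolism
    and nutrient-independent basal processes.
    """

    k_cys2_import: float
    K_cys2_import: float
    k_cys2_reduction: float
    k_cys_degradation: float
    k_gsh_production: float
    k_glu_production: float
    K_gln_import: float
    k_glu_degradation: float
    k_nadp_reduction_glc: float
    K_glc_import: float
    k_nadp_reduction_glu: float
    k_nadph_oxidation_anabolism: float
    k_nadph_oxidation_cys2: float
    k_nadph_oxidation_gssg: float
    k_gsh_reduction: float
    k_gsh_oxidation: float
    k_gsh_degradation: float
    k_ros_degradation: float
    k_ros_production_basal: float
    k_ros_production_from_glc: float
    k_ros_production_from_glu: float
    K_glu_import_ros: float
    f_ros_from_glc: float
    f_ros_from_glu: float
    K_ros_inhibition: float
    n1: float
    k_ca_import_basal: float
    k_ca_import_ros: float
    k_ca_out: float
    k_pptase_reduction_gsh: float
    k_pptase_oxidation_ros: float
    k_tk_phosphorylation: float
    k_tk_dephosphorylation: float
    SLC7A11: float
    NADP_total: float
    PPTase_total: float
    TK_total: float
    switch_nadp_import: float

    def __post_init__(self):
        for name in _RATE_CONSTANT_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ContractViolationError(f"parameter {name!r} must be >= 0, got {v}")
        for name in ("NADP_total", "PPTase_total", "TK_total"):
            if not getattr(self, name) > 0:
                raise ContractViolationError(f"{name} must be > 0")
        if not -1.0 <= self.switch_nadp_import <= 1.0:
            raise ContractViolationError("switch_nadp_import must lie in [-1, 1]")
        if not (0 <= self.f_ros_from_glc and 0 <= self.f_ros_from_glu):
            raise ContractViolationError("ROS partition fractions must be >= 0")
        if self.f_ros_from_glc + self.f_ros_from_glu > 1 + 1e-12:
            raise ContractViolationError("f_ros_from_glc + f_ros_from_glu must be <= 1")
        if self.n1 < 1:
            raise ContractViolationError("Hill exponent n1 must be >= 1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


PARAM_NAMES = tuple(f.name for f in fields(ModelParameters))


@dataclass(frozen=True)
class FeedbackConfiguration:
    """Multiplicative knockdown factors for the four feedback loops.

    1.0 reproduces the unperturbed model; 0.0 severs the loop.  The
    double-negative cystine-NADPH loop scales cystine reduction together with
    its NADPH cost; the double-negative ROS-GSH loop scales GSH oxidation
    together with GSH-dependent ROS removal; the positive ROS-calcium loop
    scales ROS-stimulated calcium influx; the positive ROS-PPTase-TK loop
    scales ROS-mediated phosphatase inactivation.
    """

    scale_cys2_nadph: float = 1.0
    scale_ros_gsh: float = 1.0
    scale_ros_ca: float = 1.0
    scale_ros_pptase_tk: float = 1.0

    def __post_init__(self):
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not 0.0 <= v <= 1.0:
                raise ContractViolationError(f"{f_.name} must lie in [0, 1], got {v}")


LOOP_NAMES = ("cys2_nadph", "ros_gsh", "ros_ca", "ros_pptase_tk")


def apply_feedback_perturbation(
    params: ModelParameters, config: FeedbackConfiguration
) -> ModelParameters:
    """Rescale the coupling constants of the four feedback loops."""
    return params.replace(
        k_nadph_oxidation_cys2=params.k_nadph_oxidation_cys2 * config.scale_cys2_nadph,
        k_cys2_reduction=params.k_cys2_reduction * config.scale_cys2_nadph,
        k_gsh_oxidation=params.k_gsh_oxidation * config.scale_ros_gsh,
        k_ros_degradation=params.k_ros_degradation * config.scale_ros_gsh,
        k_ca_import_ros=params.k_ca_import_ros * config.scale_ros_ca,
        k_pptase_oxidation_ros=params.k_pptase_oxidation_ros * config.scale_ros_pptase_tk,
    )


FLUX_NAMES = (
    "cystine_uptake",
    "cystine_reduction",
    "cysteine_degradation",
    "gsh_synthesis",
    "glutamate_production",
    "glutamate_degradation",
    "glutamate_export_via_antiport",
    "nadph_regen_glc",
    "nadph_regen_glu",
    "nadph_ox_anabolism",
    "nadph_ox_cys2",
    "nadph_ox_gssg",
    "gsh_regeneration",
    "gsh_oxidation",
    "gsh_degradation",
    "gssg_degradation",
    "ros_production",
    "ros_production_basal_part",
    "ros_production_glc_part",
    "ros_production_glu_part",
    "ros_autoinhibition_factor",
    "ros_degradation",
    "ca_import_basal",
    "ca_import_ros",
    "ca_export",
    "pptase_reduction",
    "pptase_oxidation",
    "tk_phosphorylation",
    "tk_dephosphorylation",
)


@dataclass(frozen=True)
class FluxBreakdown:
    """Per-reaction fluxes (µM/min) at one state.

    ``ros_production_*_part`` are the three additive contributions *before*
    multiplication by calcium, active kinase and the autoinhibition factor;
    ``ros_production`` is the realized production flux.
    ``ros_autoinhibition_factor`` is dimensionless.  ``gsh_oxidation`` and
    ``gsh_regeneration`` are per-ROS / per-GSSG event fluxes; the GSH balance
    applies their factor-of-two stoichiometry.
    """

    cystine_uptake: float
    cystine_reduction: float
    cysteine_degradation: float
    gsh_synthesis: float
    glutamate_production: float
    glutamate_degradation: float
    glutamate_export_via_antiport: float
    nadph_regen_glc: float
    nadph_regen_glu: float
    nadph_ox_anabolism: float
    nadph_ox_cys2: float
    nadph_ox_gssg: float
    gsh_regeneration: float
    gsh_oxidation: float
    gsh_degradation: float
    gssg_degradation: float
    ros_production: float
    ros_production_basal_part: float
    ros_production_glc_part: float
    ros_production_glu_part: float
    ros_autoinhibition_factor: float
    ros_degradation: float
    ca_import_basal: float
    ca_import_ros: float
    ca_export: float
    pptase_reduction: float
    pptase_oxidation: float
    tk_phosphorylation: float
    tk_dephosphorylation: float

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in FLUX_NAMES}


def _hill_inhibition(ros: float, K: float, n: float) -> float:
    """Decreasing Hill factor K^n / (K^n + ros^n)."""
    Kn = K**n
    return Kn / (Kn + ros**n)


def compute_fluxes(
    state: RedoxState,
    env: NutrientEnvironment,
    params: ModelParameters,
    validate: bool = True,
) -> FluxBreakdown:
    """Evaluate every elementary reaction flux at one state (µM/min)."""
    if validate:
        state.validate(params)
    p = params
    s = state
    e = env.at(s.time) if env.schedule else env

    sat_cys2 = e.cys2_ext / (p.K_cys2_import + e.cys2_ext) if e.cys2_ext > 0 else 0.0
    sat_glc = e.glc_ext / (p.K_glc_import + e.glc_ext) if e.glc_ext > 0 else 0.0
    sat_gln = e.gln_ext / (p.K_gln_import + e.gln_ext) if e.gln_ext > 0 else 0.0
    sat_glu_ros = s.glu / (p.K_glu_import_ros + s.glu) if s.glu > 0 else 0.0

    uptake = p.k_cys2_import * sat_cys2 * p.SLC7A11 * s.glu
    reduction = p.k_cys2_reduction * s.cys2_in * s.nadph
    syn = p.k_gsh_production * s.cys * s.glu
    nadp_free = p.NADP_total - s.nadph

    hill = _hill_inhibition(s.ros, p.K_ros_inhibition, p.n1)
    basal_part = p.k_ros_production_basal * (1 - p.f_ros_from_glc - p.f_ros_from_glu)
    glc_part = p.k_ros_production_from_glc * sat_glc * p.f_ros_from_glc
    glu_part = p.k_ros_production_from_glu * sat_glu_ros * p.f_ros_from_glu

    out = FluxBreakdown(
        cystine_uptake=uptake,
        cystine_reduction=reduction,
        cysteine_degradation=p.k_cys_degradation * s.cys,
        gsh_synthesis=syn,
        glutamate_production=p.k_glu_production * sat_gln,
        glutamate_degradation=p.k_glu_degradation * s.glu,
        glutamate_export_via_antiport=uptake,
        nadph_regen_glc=p.k_nadp_reduction_glc
        * sat_glc
        * nadp_free
        * (1 + p.switch_nadp_import),
        nadph_regen_glu=p.k_nadp_reduction_glu
        * s.glu
        * nadp_free
        * (1 - p.switch_nadp_import),
        nadph_ox_anabolism=p.k_nadph_oxidation_anabolism * s.nadph,
        nadph_ox_cys2=p.k_nadph_oxidation_cys2 * s.cys2_in * s.nadph,
        nadph_ox_gssg=p.k_nadph_oxidation_gssg * s.gssg * s.nadph,
        gsh_regeneration=p.k_gsh_reduction * s.nadph * s.gssg,
        gsh_oxidation=p.k_gsh_oxidation * s.ros * s.gsh**2,
        gsh_degradation=p.k_gsh_degradation * s.gsh,
        gssg_degradation=p.k_gsh_degradation * s.gssg,
        ros_production=(basal_part + glc_part + glu_part) * s.ca * s.tk_phos * hill,
        ros_production_basal_part=basal_part,
        ros_production_glc_part=glc_part,
        ros_production_glu_part=glu_part,
        ros_autoinhibition_factor=hill,
        ros_degradation=p.k_ros_degradation * s.gsh**2 * s.ros,
        ca_import_basal=p.k_ca_import_basal,
        ca_import_ros=p.k_ca_import_ros * s.ros,
        ca_export=p.k_ca_out * s.ca,
        pptase_reduction=p.k_pptase_reduction_gsh
        * s.gsh
        * (p.PPTase_total - s.pptase_red),
        pptase_oxidation=p.k_pptase_oxidation_ros * s.ros * s.pptase_red,
        tk_phosphorylation=p.k_tk_phosphorylation * (p.TK_total - s.tk_phos),
        tk_dephosphorylation=p.k_tk_dephosphorylation * s.pptase_red * s.tk_phos,
    )
    if validate:
        for name in FLUX_NAMES:
            v = getattr(out, name)
            if not np.isfinite(v):
                raise NumericModelError(f"flux {name!r} is not finite: {v}")
    return out


def fluxes_to_derivative(fx: FluxBreakdown) -> np.ndarray:
    """Signed, stoichiometry-weighted sum of fluxes per state variable."""
    return np.array(
        [
            fx.cystine_uptake - fx.cystine_reduction,
            2 * fx.cystine_reduction - fx.cysteine_degradation - fx.gsh_synthesis,
            fx.glutamate_production
            - fx.glutamate_degradation
            - fx.gsh_synthesis
            - fx.glutamate_export_via_antiport,
            fx.nadph_regen_glc
            + fx.nadph_regen_glu
            - fx.nadph_ox_anabolism
            - fx.nadph_ox_cys2
            - fx.nadph_ox_gssg,
            2 * fx.gsh_regeneration
            + fx.gsh_synthesis
            - 2 * fx.gsh_oxidation
            - fx.gsh_degradation,
            fx.gsh_oxidation - fx.gsh_regeneration - fx.gssg_degradation,
            fx.ros_production - fx.ros_degradation,
            fx.ca_import_basal + fx.ca_import_ros - fx.ca_export,
            fx.pptase_reduction - fx.pptase_oxidation,
            fx.tk_phosphorylation - fx.tk_dephosphorylation,
        ]
    )


def derivative(
    state: RedoxState,
    env: NutrientEnvironment,
    params: ModelParameters,
    validate: bool = True,
) -> np.ndarray:
    """Time derivative (µM/min) of the ten state variables."""
    return fluxes_to_derivative(compute_fluxes(state, env, params, validate=validate))


def rhs(t: float, y: np.ndarray, env: NutrientEnvironment, params: ModelParameters) -> np.ndarray:
    """ODE right-hand side on raw vectors (no validation; solver hot path)."""
    return fluxes_to_derivative(
        compute_fluxes(RedoxState.from_array(y, time=t), env, params, validate=False)
    )


def jacobian(
    state_or_y,
    env: NutrientEnvironment,
    params: ModelParameters,
    t: float = 0.0,
) -> np.ndarray:
    """Analytic 10x10 Jacobian of the right-hand side."""
    if isinstance(state_or_y, RedoxState):
        y = state_or_y.to_array()
        t = state_or_y.time
    else:
        y = np.asarray(state_or_y, dtype=float)
    p = params
    e = env.at(t) if env.schedule else env
    cys2, cys, glu, n, gsh, gssg, ros, ca, pp, tk = y

    sat_cys2 = e.cys2_ext / (p.K_cys2_import + e.cys2_ext) if e.cys2_ext > 0 else 0.0
    sat_glc = e.glc_ext / (p.K_glc_import + e.glc_ext) if e.glc_ext > 0 else 0.0
    A = p.k_cys2_import * sat_cys2 * p.SLC7A11  # uptake = A * glu
    Rg = p.k_nadp_reduction_glc * sat_glc * (1 + p.switch_nadp_import)
    Ru = p.k_nadp_reduction_glu * (1 - p.switch_nadp_import)

    Kn = p.K_ros_inhibition**p.n1
    denom = Kn + ros**p.n1
    hill = Kn / denom
    # d/d ros of K^n/(K^n + ros^n); ros=0 is safe for n1 >= 1
    dhill = -p.n1 * ros ** (p.n1 - 1) * Kn / denom**2 if ros > 0 or p.n1 == 1 else 0.0

    sat_glu_ros = glu / (p.K_glu_import_ros + glu) if glu > 0 else 0.0
    dsat_glu = (
        p.K_glu_import_ros / (p.K_glu_import_ros + glu) ** 2
        if glu > 0 or p.K_glu_import_ros > 0
        else 0.0
    )
    basal_part = p.k_ros_production_basal * (1 - p.f_ros_from_glc - p.f_ros_from_glu)
    glc_part = p.k_ros_production_from_glc * sat_glc * p.f_ros_from_glc
    glu_part = p.k_ros_production_from_glu * sat_glu_ros * p.f_ros_from_glu
    P_total = basal_part + glc_part + glu_part
    dP_dglu = p.k_ros_production_from_glu * p.f_ros_from_glu * dsat_glu

    J = np.zeros((10, 10))
    # cys2_in
    J[0, 0] = -p.k_cys2_reduction * n
    J[0, 2] = A
    J[0, 3] = -p.k_cys2_reduction * cys2
    # cys
    J[1, 0] = 2 * p.k_cys2_reduction * n
    J[1, 1] = -p.k_cys_degradation - p.k_gsh_production * glu
    J[1, 2] = -p.k_gsh_production * cys
    J[1, 3] = 2 * p.k_cys2_reduction * cys2
    # glu
    J[2, 1] = -p.k_gsh_production * glu
    J[2, 2] = -p.k_glu_degradation - p.k_gsh_production * cys - A
    # nadph
    J[3, 0] = -p.k_nadph_oxidation_cys2 * n
    J[3, 2] = Ru * (p.NADP_total - n)
    J[3, 3] = (
        -Rg
        - Ru * glu
        - p.k_nadph_oxidation_anabolism
        - p.k_nadph_oxidation_cys2 * cys2
        - p.k_nadph_oxidation_gssg * gssg
    )
    J[3, 5] = -p.k_nadph_oxidation_gssg * n
    # gsh
    J[4, 1] = p.k_gsh_production * glu
    J[4, 2] = p.k_gsh_production * cys
    J[4, 3] = 2 * p.k_gsh_reduction * gssg
    J[4, 4] = -4 * p.k_gsh_oxidation * ros * gsh - p.k_gsh_degradation
    J[4, 5] = 2 * p.k_gsh_reduction * n
    J[4, 6] = -2 * p.k_gsh_oxidation * gsh**2
    # gssg
    J[5, 3] = -p.k_gsh_reduction * gssg
    J[5, 4] = 2 * p.k_gsh_oxidation * ros * gsh
    J[5, 5] = -p.k_gsh_reduction * n - p.k_gsh_degradation
    J[5, 6] = p.k_gsh_oxidation * gsh**2
    # ros
    J[6, 2] = dP_dglu * ca * tk * hill
    J[6, 4] = -2 * p.k_ros_degradation * gsh * ros
    J[6, 6] = P_total * ca * tk * dhill - p.k_ros_degradation * gsh**2
    J[6, 7] = P_total * tk * hill
    J[6, 9] = P_total * ca * hill
    # ca
    J[7, 6] = p.k_ca_import_ros
    J[7, 7] = -p.k_ca_out
    # pptase
    J[8, 4] = p.k_pptase_reduction_gsh * (p.PPTase_total - pp)
    J[8, 6] = -p.k_pptase_oxidation_ros * pp
    J[8, 8] = -p.k_pptase_reduction_gsh * gsh - p.k_pptase_oxidation_ros * ros
    # tk
    J[9, 8] = -p.k_tk_dephosphorylation * tk
    J[9, 9] = -p.k_tk_phosphorylation - p.k_tk_dephosphorylation * pp
    return J


class RedoxModel:
    """A parameterized nutrient-redox model bound to a nutrient environment.

    This is the central object: it evaluates rate laws, integrates the ODEs
    and enumerates steady states.  Heavy operations are delegated to the
    :mod:`nutriredox.dynamics` and :mod:`nutriredox.steadystate` modules and
    exposed here as methods.

    Parameters
    ----------
    params :
        A fully specified :class:`ModelParameters`.
    env :
        The nutrient environment (may carry a piecewise-constant schedule).
    """

    def __init__(self, params: ModelParameters, env: NutrientEnvironment):
        self.params = params
        self.env = env

    # -- local evaluations -------------------------------------------------
    def fluxes(self, state: RedoxState) -> FluxBreakdown:
        return compute_fluxes(state, self.env, self.params)

    def derivative(self, state: RedoxState) -> np.ndarray:
        return derivative(state, self.env, self.params)

    def jacobian(self, state: RedoxState) -> np.ndarray:
        return jacobian(state, self.env, self.params)

    def with_feedback(self, config: FeedbackConfiguration) -> "RedoxModel":
        return RedoxModel(apply_feedback_perturbation(self.params, config), self.env)

    def with_env(self, env: NutrientEnvironment) -> "RedoxModel":
        return RedoxModel(self.params, env)

    # -- delegated heavy operations ---------------------------------------
    def simulate(self, initial, t_end, sampling=1.0, rtol=1e-8, atol=1e-12):
        from .dynamics import simulate

        return simulate(initial, self.env, self.params, t_end, sampling, rtol=rtol, atol=atol)

    def steady_states(self, **kwargs):
        from .steadystate import find_steady_states

        return find_steady_states(self.env, self.params, **kwargs)

    def steady_initial_state(self, branch: str = "high_gsh", **kwargs):
        from .dynamics import steady_initial_state

        return steady_initial_state(self.env, self.params, branch=branch, **kwargs)

    def bifurcation_scan(self, axis_name: str, axis_values, **kwargs):
        from .steadystate import bifurcation_scan

        return bifurcation_scan(axis_name, axis_values, self.env, self.params, **kwargs)
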