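"""Fixed points, stability and bifurcation structure of the redox model.

The reference implementation solves the ten-dimensional algebraic system
numerically: damped Powell root finding on log-transformed concentrations
(which enforces positivity and conditions the search across the >= 6 orders
of magnitude spanned by the state), seeded from a deterministic multi-start
scheme (Latin-hypercube subsample of a log-spaced lattice plus the endpoints
of long integrations from extreme initial conditions).  Stability is read off
the analytic Jacobian's eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .model import (
    LOOP_NAMES,
    STATE_NAMES,
    ContractViolationError,
    FeedbackConfiguration,
    ModelParameters,
    NutrientEnvironment,
    RedoxState,
    apply_feedback_perturbation,
    jacobian,
    rhs,
)

__all__ = [
    "FixedPoint",
    "SteadyStateBranch",
    "find_steady_states",
    "bifurcation_scan",
    "classify_regime",
    "regime_map",
]

#: Plausible log10 search ranges (µM) per state variable for multi-starts.
_SEARCH_RANGES = {
    "cys2_in": (-2.0, 4.5),
    "cys": (-3.0, 3.5),
    "glu": (-1.0, 4.5),
    "nadph": (-4.0, 0.0),  # rescaled to (eps, NADP_total)
    "gsh": (-4.0, 4.5),
    "gssg": (-3.0, 4.5),
    "ros": (-4.0, 4.0),
    "ca": (-3.0, 3.0),
    "pptase_red": (-4.0, 0.0),  # rescaled to (eps, PPTase_total)
    "tk_phos": (-4.0, 0.0),  # rescaled to (eps, TK_total)
}

_FLOOR = 1e-12  # absolute concentration floor (µM) for log transforms


@dataclass(frozen=True)
class FixedPoint:
    """A fixed point of the redox ODEs with its local stability."""

    state: RedoxState
    stability: str  # "stable" | "unstable"
    leading_eigenvalue_real_part: float  # 1/min
    environment: NutrientEnvironment
    residual_norm: float  # µM/min

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class SteadyStateBranch:
    """Glucose- (or other-axis-) indexed fixed points with fold locations."""

    axis_name: str
    axis_values: np.ndarray
    points: list  # list of lists of FixedPoint, parallel to axis_values
    fold_points: list = field(default_factory=list)  # axis values (µM)

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(fp.is_stable for fp in pts) for pts in self.points])

    def regime_labels(self) -> list:
        return [classify_regime(pts) for pts in self.points]

    def bistable_window(self):
        """(lo, hi) axis range classified bistable, or None."""
        labels = self.regime_labels()
        idx = [i for i, lab in enumerate(labels) if lab == "bistable"]
        if not idx:
            return None
        return float(self.axis_values[idx[0]]), float(self.axis_values[idx[-1]])

    def to_frame(self):
        import pandas as pd

        rows = []
        for x, pts in zip(self.axis_values, self.points):
            for j, fp in enumerate(sorted(pts, key=lambda f: f.state.gsh, reverse=True)):
                row = {self.axis_name: x, "branch_id": j, "stability": fp.stability,
                       "leading_eigenvalue_real_part": fp.leading_eigenvalue_real_part}
                row.update({n: getattr(fp.state, n) for n in STATE_NAMES})
                rows.append(row)
        return pd.DataFrame(rows)


def _bounded_names(params: ModelParameters):
    return {"nadph": params.NADP_total, "pptase_red": params.PPTase_total,
            "tk_phos": params.TK_total}


def _make_starts(params: ModelParameters, n_starts: int, seed: int) -> np.ndarray:
    """Deterministic Latin-hypercube subsample of the log-spaced search box."""
    sampler = qmc.LatinHypercube(d=len(STATE_NAMES), seed=seed)
    u = sampler.random(n=n_starts)
    lo = np.array([_SEARCH_RANGES[n][0] for n in STATE_NAMES])
    hi = np.array([_SEARCH_RANGES[n][1] for n in STATE_NAMES])
    logx = lo + u * (hi - lo)
    starts = 10.0**logx
    bounded = _bounded_names(params)
    for i, name in enumerate(STATE_NAMES):
        if name in bounded:
            total = bounded[name]
            starts[:, i] = total * (0.02 + 0.96 * u[:, i])
    return starts


def _integration_endpoints(env, params, t_end=3000.0):
    """Endpoints of long integrations from reduced/oxidized extremes."""
    from .dynamics import _integrate_raw

    ends = []
    extremes = [
        # strongly reduced start: high GSH, low ROS
        np.array([10.0, 100.0, 2000.0, 0.9 * params.NADP_total, 4000.0, 10.0,
                  1e-3, 0.1, 0.9 * params.PPTase_total, 0.1 * params.TK_total]),
        # strongly oxidized start: collapsed GSH, high ROS
        np.array([500.0, 1.0, 500.0, 0.01 * params.NADP_total, 1.0, 1500.0,
                  5.0, 0.5, 0.01 * params.PPTase_total, 0.95 * params.TK_total]),
        # oxidized start with full glutathione pool as GSSG and kinase on
        np.array([5000.0, 1.0, 3000.0, 0.005 * params.NADP_total, 1.0, 1400.0,
                  2.0, 0.3, 0.001 * params.PPTase_total, 0.99 * params.TK_total]),
    ]
    for y0 in extremes:
        try:
            y_end = _integrate_raw(y0, env, params, t_end)
            ends.append(np.maximum(y_end, 0.0))
        except Exception:  # integration failure only loses a seed
            continue
    return ends


def _polish_root(y0, env, params):
    """Damped root solve in log space; returns polished y or None."""
    y0 = np.maximum(np.asarray(y0, dtype=float), _FLOOR)
    bounded = _bounded_names(params)
    for i, name in enumerate(STATE_NAMES):
        if name in bounded:
            y0[i] = min(y0[i], bounded[name] * (1 - 1e-9))
    x0 = np.log(y0)

    _XCAP = 45.0  # |log y| cap keeps powers of y finite in the rate laws

    def fun(x):
        y = np.exp(np.clip(x, -_XCAP, _XCAP))
        f = rhs(0.0, y, env, params)
        J = jacobian(y, env, params) * y[np.newaxis, :]
        return f, J

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = optimize.root(fun, x0, jac=True, method="hybr",
                            options={"xtol": 1e-12, "maxfev": 4000})
    if not sol.success or np.max(np.abs(sol.x)) > _XCAP - 1e-9:
        return None
    y = np.exp(sol.x)
    if not np.all(np.isfinite(y)):
        return None
    for i, name in enumerate(STATE_NAMES):
        if name in bounded and y[i] > bounded[name] * (1 + 1e-9):
            return None
    return y


def _scale_per_equation(y, env, params):
    """Largest |flux| entering each balance, for relative residuals."""
    from .model import RedoxState, compute_fluxes

    fx = compute_fluxes(RedoxState.from_array(y), env, params, validate=False)
    g = fx
    return np.array([
        max(g.cystine_uptake, g.cystine_reduction, 1e-30),
        max(2 * g.cystine_reduction, g.cysteine_degradation, g.gsh_synthesis, 1e-30),
        max(g.glutamate_production, g.glutamate_degradation, g.gsh_synthesis,
            g.glutamate_export_via_antiport, 1e-30),
        max(g.nadph_regen_glc, g.nadph_regen_glu, g.nadph_ox_anabolism,
            g.nadph_ox_cys2, g.nadph_ox_gssg, 1e-30),
        max(2 * g.gsh_regeneration, g.gsh_synthesis, 2 * g.gsh_oxidation,
            g.gsh_degradation, 1e-30),
        max(g.gsh_oxidation, g.gsh_regeneration, g.gssg_degradation, 1e-30),
        max(g.ros_production, g.ros_degradation, 1e-30),
        max(g.ca_import_basal, g.ca_import_ros, g.ca_export, 1e-30),
        max(g.pptase_reduction, g.pptase_oxidation, 1e-30),
        max(g.tk_phosphorylation, g.tk_dephosphorylation, 1e-30),
    ])


def _classify_point(y, env, params, residual_tol):
    f = rhs(0.0, y, env, params)
    scale = _scale_per_equation(y, env, params)
    rel_res = float(np.max(np.abs(f) / scale))
    if rel_res > residual_tol:
        return None
    J = jacobian(y, env, params)
    eig = np.linalg.eigvals(J)
    lead = float(np.max(eig.real))
    stability = "stable" if lead < 0 else "unstable"
    return FixedPoint(
        state=RedoxState.from_array(np.maximum(y, 0.0)),
        stability=stability,
        leading_eigenvalue_real_part=lead,
        environment=env,
        residual_norm=float(np.linalg.norm(f)),
    )


def _dedup(roots, rel_tol=1e-5):
    kept = []
    for y in roots:
        ly = np.log(np.maximum(y, _FLOOR))
        if any(np.max(np.abs(ly - np.log(np.maximum(k, _FLOOR)))) < rel_tol * max(1.0, np.max(np.abs(ly)))
               for k in kept):
            continue
        kept.append(y)
    return kept


def find_steady_states(
    env: NutrientEnvironment,
    params: ModelParameters,
    n_starts: int = 512,
    seed: int = 20210480,
    residual_tol: float = 1e-6,
    extra_starts=None,
    use_integration_endpoints: bool = True,
) -> list:
    """All nonnegative fixed points found by deterministic multi-start search.

    Returns a list of :class:`FixedPoint` sorted by decreasing GSH.  An empty
    list corresponds to the "no steady state available" regime class.
    """
    starts = list(_make_starts(params, n_starts, seed)) if n_starts > 0 else []
    if use_integration_endpoints:
        starts.extend(_integration_endpoints(env, params))
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    roots = []
    for y0 in starts:
        y = _polish_root(y0, env, params)
        if y is not None:
            roots.append(y)
    points = []
    for y in _dedup(roots):
        fp = _classify_point(y, env, params, residual_tol)
        if fp is not None:
            points.append(fp)
    # second pass: (i) saddle seeding — the unstable middle state lies
    # between coexisting attractors, so log-interpolants of found points are
    # excellent extra starts; (ii) reflection through unstable points finds
    # the attractor on the far side of a saddle
    found_ys = [fp.state.to_array() for fp in points]
    stabilities = [fp.is_stable for fp in points]
    extra = []
    for i in range(len(found_ys)):
        for j in range(i + 1, len(found_ys)):
            la = np.log(np.maximum(found_ys[i], _FLOOR))
            lb = np.log(np.maximum(found_ys[j], _FLOOR))
            for w in (0.3, 0.5, 0.7):
                extra.append(np.exp(w * la + (1 - w) * lb))
            if stabilities[i] != stabilities[j]:
                lu, ls = (la, lb) if not stabilities[i] else (lb, la)
                extra.append(np.exp(2 * lu - ls))   # reflect stable over saddle
    for y0 in extra:
        y = _polish_root(y0, env, params)
        if y is not None:
            fp = _classify_point(y, env, params, residual_tol)
            if fp is not None:
                points.append(fp)
    # dedup again post-classification (distinct seeds may polish to the
    # same point at slightly different accuracy)
    uniq = []
    for fp in sorted(points, key=lambda f: f.residual_norm):
        if any(_same_point(fp, other) for other in uniq):
            continue
        uniq.append(fp)
    return sorted(uniq, key=lambda f: f.state.gsh, reverse=True)


def _same_point(a: FixedPoint, b: FixedPoint, rel_tol=1e-4) -> bool:
    ya = np.maximum(a.state.to_array(), _FLOOR)
    yb = np.maximum(b.state.to_array(), _FLOOR)
    return bool(np.max(np.abs(np.log(ya) - np.log(yb))) < rel_tol * max(1.0, np.max(np.abs(np.log(ya)))))


def classify_regime(points) -> str:
    """'bistable' (>=2 stable), 'monostable' (exactly 1) or 'none' (0)."""
    n_stable = sum(fp.is_stable for fp in points)
    if n_stable >= 2:
        return "bistable"
    if n_stable == 1:
        return "monostable"
    return "none"


def _env_on_axis(env: NutrientEnvironment, axis_name: str, value: float) -> NutrientEnvironment:
    if axis_name not in ("glc_ext", "gln_ext", "cys2_ext"):
        raise ContractViolationError(f"unknown scan axis {axis_name!r}")
    kwargs = {"glc_ext": env.glc_ext, "gln_ext": env.gln_ext, "cys2_ext": env.cys2_ext}
    kwargs[axis_name] = float(value)
    return NutrientEnvironment(**kwargs)


def bifurcation_scan(
    axis_name: str,
    axis_values,
    env: NutrientEnvironment,
    params: ModelParameters,
    n_starts: int = 256,
    seed: int = 20210480,
    fold_tol: float = 0.1,
) -> SteadyStateBranch:
    """Scan an extracellular-nutrient axis and locate fold (saddle-node) points.

    Every grid value runs the full multi-start search, merged with warm
    starts from the neighboring grid point (branch continuation: warm starts
    polish faster and keep branch identity through narrow windows).  Fold
    points are refined by bisection on the count of stable states to an axis
    tolerance of ``fold_tol`` µM.
    """
    axis_values = np.asarray(axis_values, dtype=float)
    if axis_values.ndim != 1 or len(axis_values) < 2 or np.any(np.diff(axis_values) <= 0):
        raise ContractViolationError("axis grid must be sorted ascending with >= 2 points")

    points = []
    warm = None
    for i, x in enumerate(axis_values):
        e = _env_on_axis(env, axis_name, x)
        pts = find_steady_states(e, params, n_starts=n_starts, seed=seed,
                                 extra_starts=warm)
        if warm is not None and len(pts) < sum(1 for _ in points[-1]):
            warnings.warn(
                f"branch tracking lost a point at {axis_name}={x}")
        points.append(pts)
        warm = [fp.state.to_array() for fp in pts] or warm

    branch = SteadyStateBranch(axis_name=axis_name, axis_values=axis_values, points=points)
    counts = branch.stable_counts()
    folds = []
    for i in range(len(axis_values) - 1):
        if counts[i] != counts[i + 1]:
            folds.append(
                _refine_fold(axis_name, axis_values[i], axis_values[i + 1],
                             counts[i], env, params, points[i], points[i + 1],
                             seed, n_starts, fold_tol))
    branch.fold_points = folds
    return branch


def _refine_fold(axis_name, lo, hi, count_lo, env, params, pts_lo, pts_hi,
                 seed, n_starts, tol):
    warm_lo = [fp.state.to_array() for fp in pts_lo]
    warm_hi = [fp.state.to_array() for fp in pts_hi]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        e = _env_on_axis(env, axis_name, mid)
        pts = find_steady_states(e, params, n_starts=n_starts, seed=seed,
                                 extra_starts=warm_lo + warm_hi,
                                 use_integration_endpoints=False)
        n_stable = sum(fp.is_stable for fp in pts)
        if n_stable == count_lo:
            lo = mid
            warm_lo = [fp.state.to_array() for fp in pts] or warm_lo
        else:
            hi = mid
            warm_hi = [fp.state.to_array() for fp in pts] or warm_hi
    return float(0.5 * (lo + hi))


def regime_map(
    loop: str,
    factor_grid,
    glucose_grid,
    env: NutrientEnvironment,
    params: ModelParameters,
    n_starts: int = 256,
    seed: int = 20210480,
):
    """Regime labels over (feedback knockdown factor, glucose) grid cells."""
    if loop not in LOOP_NAMES:
        raise ContractViolationError(f"unknown feedback loop {loop!r}; choose from {LOOP_NAMES}")
    factor_grid = np.asarray(factor_grid, dtype=float)
    glucose_grid = np.asarray(glucose_grid, dtype=float)
    labels = np.empty((len(factor_grid), len(glucose_grid)), dtype=object)
    for i, fac in enumerate(factor_grid):
        cfg = FeedbackConfiguration(**{f"scale_{loop}": float(fac)})
        p = apply_feedback_perturbation(params, cfg)
        warm = None
        for j, g in enumerate(glucose_grid):
            e = _env_on_axis(env, "glc_ext", g)
            pts = find_steady_states(e, p, n_starts=n_starts, seed=seed,
                                     extra_starts=warm)
            labels[i, j] = classify_regime(pts)
            warm = [fp.state.to_array() for fp in pts] or warm
    return labels
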