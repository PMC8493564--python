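"""Time-domain simulation of the redox model and its dynamic read-outs.

Integration is stiff-capable (LSODA with the analytic Jacobian), restarted at
every nutrient-schedule switch time so the discontinuous inputs never cross a
solver step.  The headline statistic is the redox-catastrophe time: the time
of maximum ROS rate of increase after a perturbation, evaluated from the
analytic right-hand side along the trajectory (not from finite differences of
the samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    FLUX_NAMES,
    STATE_NAMES,
    ContractViolationError,
    ModelParameters,
    NutrientEnvironment,
    RedoxState,
    compute_fluxes,
    jacobian,
    rhs,
)

__all__ = [
    "Trajectory",
    "IntegrationError",
    "simulate",
    "steady_initial_state",
    "catastrophe_time",
    "decline_time",
    "run_protocol",
    "PROTOCOLS",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last good state/time."""

    def __init__(self, message, last_time=None, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


@dataclass
class Trajectory:
    """A sampled solution of the redox ODEs under a nutrient protocol."""

    times: np.ndarray  # minutes
    states: np.ndarray  # (n_times, 10) µM
    protocol: NutrientEnvironment
    params: ModelParameters

    def state_at(self, i: int) -> RedoxState:
        return RedoxState.from_array(self.states[i], time=float(self.times[i]))

    def series(self, name: str) -> np.ndarray:
        if name not in STATE_NAMES:
            raise ContractViolationError(f"unknown species {name!r}")
        return self.states[:, STATE_NAMES.index(name)]

    def fluxes(self) -> pd.DataFrame:
        rows = []
        for t, y in zip(self.times, self.states):
            fx = compute_fluxes(
                RedoxState.from_array(np.maximum(y, 0.0), time=float(t)),
                self.protocol, self.params, validate=False)
            rows.append(fx.to_dict())
        return pd.DataFrame(rows, index=pd.Index(self.times, name="time_min"))

    def to_frame(self, include_fluxes: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_min", self.times)
        if include_fluxes:
            df = pd.concat([df, self.fluxes().reset_index(drop=True)], axis=1)
        return df

    def ros_rate(self) -> np.ndarray:
        """dROS/dt along the trajectory from the analytic right-hand side."""
        idx = STATE_NAMES.index("ros")
        return np.array([
            rhs(float(t), np.maximum(y, 0.0), self.protocol, self.params)[idx]
            for t, y in zip(self.times, self.states)
        ])


def _integrate_raw(y0, env, params, t_end, t_eval=None, rtol=1e-8, atol=1e-12,
                   t0=0.0):
    """Integrate between schedule switches; returns endpoint or sampled array."""
    switch_times = [t for t in env.switch_times if t0 < t < t_end]
    seg_edges = [t0] + switch_times + [t_end]
    ys = []
    ts = []
    y = np.asarray(y0, dtype=float)
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        seg_env = env.at(0.5 * (a + b))
        if t_eval is not None:
            mask = (t_eval >= a) & (t_eval <= b)
            seg_eval = np.unique(np.concatenate([[a], t_eval[mask], [b]]))
        else:
            seg_eval = None
        sol = solve_ivp(
            lambda t, yy: rhs(t, np.maximum(yy, 0.0), seg_env, params),
            (a, b), y, method="LSODA",
            jac=lambda t, yy: jacobian(np.maximum(yy, 0.0), seg_env, params),
            rtol=rtol, atol=atol, t_eval=seg_eval, dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"integrator failed in segment [{a}, {b}]: {sol.message}",
                last_time=float(sol.t[-1]) if len(sol.t) else a,
                last_state=sol.y[:, -1] if sol.y.size else y)
        y = sol.y[:, -1]
        if t_eval is not None:
            ts.append(sol.t)
            ys.append(sol.y.T)
    if t_eval is None:
        return y
    t_all = np.concatenate(ts)
    y_all = np.vstack(ys)
    # keep requested grid plus switch times, deduplicated
    keep = np.unique(np.round(t_all, 10), return_index=True)[1]
    return t_all[keep], y_all[keep]


def simulate(
    initial,
    schedule: NutrientEnvironment,
    params: ModelParameters,
    t_end: float,
    sampling: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the ODEs under a (possibly scheduled) nutrient environment.

    Samples land on the requested grid plus all schedule switch times.
    """
    if t_end <= 0:
        raise ContractViolationError("t_end must be positive")
    if isinstance(initial, RedoxState):
        initial.validate(params)
        y0 = initial.to_array()
    else:
        y0 = np.asarray(initial, dtype=float)
        RedoxState.from_array(y0).validate(params)
    t_eval = np.arange(0.0, t_end + 0.5 * sampling, sampling)
    t_eval = t_eval[t_eval <= t_end]
    times, states = _integrate_raw(y0, schedule, params, t_end, t_eval=t_eval,
                                   rtol=rtol, atol=atol)
    return Trajectory(times=times, states=states, protocol=schedule, params=params)


def steady_initial_state(
    env: NutrientEnvironment,
    params: ModelParameters,
    branch: str = "high_gsh",
    **solver_kwargs,
) -> RedoxState:
    """The requested stable fixed point (high_gsh or low_gsh) at ``env``."""
    from .steadystate import find_steady_states

    if branch not in ("high_gsh", "low_gsh"):
        raise ContractViolationError("branch must be 'high_gsh' or 'low_gsh'")
    pts = [fp for fp in find_steady_states(env.at(0.0), params, **solver_kwargs)
           if fp.is_stable]
    if not pts:
        raise ContractViolationError("no stable steady state at this environment")
    pts.sort(key=lambda fp: fp.state.gsh, reverse=True)
    if branch == "high_gsh":
        return pts[0].state
    if len(pts) < 2:
        raise ContractViolationError(
            f"low_gsh branch absent; available branches: high_gsh "
            f"(GSH={pts[0].state.gsh:.3g} µM)")
    return pts[-1].state


def catastrophe_time(
    traj: Trajectory,
    t_perturb: float = 0.0,
    rate_floor: float | None = None,
    surge_fold: float = 2.0,
) -> float | None:
    """Time of maximum ROS rate of increase after the perturbation.

    Returns None — no catastrophe within the simulated horizon — unless the
    trajectory shows a genuine redox collapse: the maximum dROS/dt must
    exceed ``rate_floor`` (default 1% of the trajectory's ROS range per
    hour) *and* ROS must surge to at least ``surge_fold`` times its
    pre-perturbation level (the same twofold criterion used to call
    single cells responsive).  Without the surge condition, small relaxation
    wiggles of a homeostatic trajectory would register as catastrophes.
    """
    mask = traj.times >= t_perturb
    if not np.any(mask):
        raise ContractViolationError("trajectory does not cover the post-perturbation window")
    ros = traj.series("ros")[mask]
    # the collapse is an essentially irreversible switch: judge the surge by
    # where the trajectory ends up, so brief relaxation spikes do not count
    if float(ros[-1]) < surge_fold * ros[0]:
        return None
    rates = traj.ros_rate()[mask]
    times = traj.times[mask]
    if rate_floor is None:
        ros_scale = float(np.max(ros))
        rate_floor = 0.01 * ros_scale / 60.0
    i = int(np.argmax(rates))
    if rates[i] < rate_floor:
        return None
    return float(times[i])


def decline_time(
    traj: Trajectory,
    species: str,
    fraction: float,
    t_perturb: float = 0.0,
) -> float | None:
    """First time the species falls to (1 - fraction) of its pre-perturbation
    value, by linear interpolation between samples; None if never reached."""
    if not 0.0 < fraction < 1.0:
        raise ContractViolationError("fraction must lie in (0, 1)")
    y = traj.series(species)
    mask = traj.times >= t_perturb
    times = traj.times[mask]
    y = y[mask]
    target = (1.0 - fraction) * y[0]
    below = np.nonzero(y <= target)[0]
    if len(below) == 0:
        return None
    j = below[0]
    if j == 0:
        return float(times[0])
    t0, t1 = times[j - 1], times[j]
    y0, y1 = y[j - 1], y[j]
    if y1 == y0:
        return float(t1)
    return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))


# ---------------------------------------------------------------------------
# Protocol registry
# ---------------------------------------------------------------------------

def _deprivation_schedule(env, glc_low, t_perturb=0.0):
    return NutrientEnvironment(
        env.glc_ext, env.gln_ext, env.cys2_ext,
        schedule=((t_perturb, glc_low, env.gln_ext, env.cys2_ext),))


def _protocol_glucose_deprivation(params, env, glc_levels=(0.0, 3.0, 6.0, 9.0, 12.0),
                                  t_end=600.0, sampling=1.0, rate_window=5.0):
    """Step glucose from the reference level to each low level; summarize
    catastrophe times, 90% decline times and initial depletion rates."""
    init = steady_initial_state(env, params, branch="high_gsh")
    rows = []
    trajs = {}
    for g in glc_levels:
        sched = _deprivation_schedule(env, g)
        traj = simulate(init, sched, params, t_end, sampling)
        trajs[g] = traj
        t_cat = catastrophe_time(traj)
        n90 = decline_time(traj, "nadph", 0.9)
        g90 = decline_time(traj, "gsh", 0.9)
        # initial rates over the first rate_window minutes by linear fit
        w = traj.times <= rate_window
        nadph_rate = -np.polyfit(traj.times[w], traj.series("nadph")[w], 1)[0]
        cys2_rate = np.polyfit(traj.times[w], traj.series("cys2_in")[w], 1)[0]
        rows.append({
            "glc_low_uM": g, "catastrophe_time_min": t_cat,
            "nadph_decline90_min": n90, "gsh_decline90_min": g90,
            "decline90_gap_min": (g90 - n90) if (g90 is not None and n90 is not None) else None,
            "nadph_depletion_rate_uM_per_min": nadph_rate,
            "cys2_accumulation_rate_uM_per_min": cys2_rate,
        })
    return trajs, pd.DataFrame(rows)


def _protocol_glucose_addback(params, env, glc_addback=(25.0, 200.0),
                              glc_low=0.0, dwell_extra=30.0, t_end=900.0,
                              sampling=1.0, fold_threshold=2.0):
    """Deprive to glc_low, dwell until catastrophe + dwell_extra, then add
    glucose back; flag whether ROS reverts to the low branch."""
    init = steady_initial_state(env, params, branch="high_gsh")
    probe = simulate(init, _deprivation_schedule(env, glc_low), params, 600.0, sampling)
    t_cat = catastrophe_time(probe)
    if t_cat is None:
        raise ContractViolationError("deprivation did not produce a catastrophe; no add-back dwell defined")
    t_add = t_cat + dwell_extra
    ros0 = init.ros
    rows = []
    trajs = {}
    for g_back in glc_addback:
        sched = NutrientEnvironment(
            env.glc_ext, env.gln_ext, env.cys2_ext,
            schedule=((0.0, glc_low, env.gln_ext, env.cys2_ext),
                      (t_add, g_back, env.gln_ext, env.cys2_ext)))
        traj = simulate(init, sched, params, t_end, sampling)
        trajs[g_back] = traj
        ros_final = traj.series("ros")[-1]
        rows.append({
            "glc_addback_uM": g_back, "t_addback_min": t_add,
            "ros_final_uM": ros_final, "ros_fold_final": ros_final / ros0,
            "reverted": bool(ros_final / ros0 < fold_threshold),
        })
    return trajs, pd.DataFrame(rows)


def _protocol_nadph_pool(params, env, totals=(0.05, 0.1, 0.2), deprive=False,
                         glc_low=0.0, t_end=600.0, sampling=1.0):
    """Change total NADP(H) pool size (optionally together with glucose
    deprivation) and test for GSH collapse / redox catastrophe."""
    rows = []
    trajs = {}
    for total in totals:
        p2 = params.replace(NADP_total=total)
        if deprive:
            init0 = steady_initial_state(env, p2, branch="high_gsh")
            sched = _deprivation_schedule(env, glc_low)
            traj = simulate(init0, sched, p2, t_end, sampling)
        else:
            # sudden pool decrease from the reference steady state
            init = steady_initial_state(env, params, branch="high_gsh")
            y0 = init.to_array()
            y0[STATE_NAMES.index("nadph")] = min(init.nadph, total * (1 - 1e-9))
            traj = simulate(RedoxState.from_array(y0), env, p2, t_end, sampling)
        trajs[total] = traj
        t_cat = catastrophe_time(traj)
        gsh = traj.series("gsh")
        rows.append({
            "nadp_total_uM": total, "deprived": deprive,
            "catastrophe_time_min": t_cat,
            "catastrophe": t_cat is not None,
            "gsh_final_uM": gsh[-1], "gsh_depleted": bool(gsh[-1] < 0.1 * gsh[0]),
        })
    return trajs, pd.DataFrame(rows)


def _protocol_cystine_titration(params, env, folds=(0.125, 0.25, 0.5, 1.0, 2.0),
                                co_titrate_gln=False, glc_low=0.0, t_end=600.0,
                                sampling=1.0):
    """Dilute/concentrate cystine (optionally co-titrating glutamine) during
    glucose deprivation; a fold of 1 reproduces plain deprivation."""
    rows = []
    trajs = {}
    for fold in folds:
        cys2 = env.cys2_ext * fold
        gln = env.gln_ext * (fold if co_titrate_gln else 1.0)
        pre = NutrientEnvironment(env.glc_ext, env.gln_ext, env.cys2_ext)
        init = steady_initial_state(pre, params, branch="high_gsh")
        sched = NutrientEnvironment(
            env.glc_ext, env.gln_ext, env.cys2_ext,
            schedule=((0.0, glc_low, gln, cys2),))
        traj = simulate(init, sched, params, t_end, sampling)
        trajs[fold] = traj
        t_cat = catastrophe_time(traj)
        rows.append({
            "cys2_fold": fold, "gln_fold": fold if co_titrate_gln else 1.0,
            "cys2_ext_uM": cys2, "gln_ext_uM": gln,
            "catastrophe_time_min": t_cat, "rescued": t_cat is None,
        })
    return trajs, pd.DataFrame(rows)


def _protocol_addiction_handles(params, env, slc7a11_levels=(1.0, 5.0, 10.0),
                                switches=(0.0, 0.5, 0.9, 0.99),
                                glu_ros_scales=(0.5, 1.0, 2.0),
                                glc_low=0.0, t_end=600.0, sampling=2.0):
    """Vary the three glucose-addiction handles (SLC7A11 expression, glucose
    dependence of NADPH regeneration, glutamate-anaplerosis ROS production)
    and record catastrophe occurrence after full deprivation."""
    rows = []
    trajs = {}
    base_regen = {}

    def run(tag, p2):
        try:
            init = steady_initial_state(env, p2, branch="high_gsh")
        except ContractViolationError:
            rows.append({"handle": tag[0], "value": tag[1],
                         "catastrophe_time_min": None, "catastrophe": None,
                         "note": "no high-GSH steady state at reference"})
            return
        traj = simulate(init, _deprivation_schedule(env, glc_low), p2, t_end, sampling)
        trajs[tag] = traj
        t_cat = catastrophe_time(traj)
        rows.append({"handle": tag[0], "value": tag[1],
                     "catastrophe_time_min": t_cat,
                     "catastrophe": t_cat is not None, "note": ""})

    for lvl in slc7a11_levels:
        run(("SLC7A11", lvl), params.replace(SLC7A11=lvl))
    for sw in switches:
        run(("switch_nadp_import", sw), params.replace(switch_nadp_import=sw))
    for sc in glu_ros_scales:
        run(("k_ros_production_from_glu_scale", sc),
            params.replace(k_ros_production_from_glu=params.k_ros_production_from_glu * sc))
    return trajs, pd.DataFrame(rows)


PROTOCOLS = {
    "glucose_deprivation": _protocol_glucose_deprivation,
    "glucose_addback": _protocol_glucose_addback,
    "nadph_pool": _protocol_nadph_pool,
    "cystine_titration": _protocol_cystine_titration,
    "cys_gln_cotitration": lambda params, env, **kw: _protocol_cystine_titration(
        params, env, co_titrate_gln=True, **kw),
    "addiction_handles": _protocol_addiction_handles,
}


def run_protocol(name: str, params: ModelParameters, env: NutrientEnvironment, **options):
    """Run a registered in-silico protocol; returns (trajectories, summary)."""
    if name not in PROTOCOLS:
        raise ContractViolationError(
            f"unknown protocol {name!r}; registered: {sorted(PROTOCOLS)}")
    return PROTOCOLS[name](params, env, **options)
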