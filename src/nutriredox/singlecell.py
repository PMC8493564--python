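"""Synthetic single-cell ROS traces and the matching population statistics.

The generator emulates ratiometric H2O2-probe (HyPer7-style) time-lapse data:
each cell draws a jittered parameter set (lognormal multiplicative jitter on
a configurable subset, reflecting cell-to-cell differences in transporter
expression and basal metabolism), is simulated under a nutrient protocol,
baseline-normalized, and sampled every 15 minutes with multiplicative
measurement noise.  The probe read-out is modeled as directly proportional to
the model's ROS concentration (linear gain in the operating regime).

Statistics implemented on such traces: the twofold-within-90-min
responsive/non-responsive classification, Hill fitting of the glucose
dose-response of ROS, and responsive/irreversible fraction summaries that
quantify hysteresis between glucose withdrawal and add-back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dynamics import catastrophe_time, simulate
from .model import (
    ContractViolationError,
    ModelParameters,
    NutrientEnvironment,
)

__all__ = [
    "CellPopulationSpec",
    "SingleCellTrace",
    "generate_population",
    "classify_responsive",
    "fit_hill",
    "hysteresis_summary",
    "HillFit",
]

#: Default heterogeneous parameter subset (transporter expression, basal ROS
#: production, cofactor pool size).
DEFAULT_JITTER_PARAMS = ("SLC7A11", "k_ros_production_basal", "NADP_total")


@dataclass(frozen=True)
class CellPopulationSpec:
    """Statistical description of a synthetic cell population."""

    n_cells: int = 100
    parameter_jitter: float = 0.1  # lognormal CV per jittered parameter
    jitter_params: tuple = DEFAULT_JITTER_PARAMS
    nonresponder_fraction: float = 0.0
    nonresponder_scale: float = 3.0  # NADP_total multiplier for forced non-responders
    measurement_noise_cv: float = 0.05
    sampling_interval: float = 15.0  # minutes, imaging cadence
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ContractViolationError("n_cells must be >= 1")
        if self.parameter_jitter < 0 or self.measurement_noise_cv < 0:
            raise ContractViolationError("coefficients of variation must be >= 0")
        if not 0.0 <= self.nonresponder_fraction <= 1.0:
            raise ContractViolationError("nonresponder_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SingleCellTrace:
    """One cell's baseline-normalized ROS-ratio time series."""

    cell_id: int
    times: np.ndarray  # minutes, perturbation at t=0
    ros_ratio: np.ndarray  # dimensionless fold over pre-perturbation baseline
    protocol: NutrientEnvironment
    committed: bool  # ground truth: noiseless trajectory reached catastrophe
    true_catastrophe_time: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_id, "time_min": self.times,
                             "ros_ratio": self.ros_ratio})


def _jittered_params(base: ModelParameters, spec: CellPopulationSpec,
                     rng: np.random.Generator, force_nonresponder: bool) -> ModelParameters:
    changes = {}
    if spec.parameter_jitter > 0:
        sigma = np.sqrt(np.log1p(spec.parameter_jitter**2))
        for name in spec.jitter_params:
            factor = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            changes[name] = getattr(base, name) * factor
    if force_nonresponder:
        # a cell outside the catastrophe-committed region: oversized NADPH pool
        changes["NADP_total"] = changes.get("NADP_total", base.NADP_total) * spec.nonresponder_scale
    return base.replace(**changes)


def generate_population(
    spec: CellPopulationSpec,
    base_params: ModelParameters,
    protocol: NutrientEnvironment,
    t_end: float = 300.0,
    t_baseline: float = 0.0,
    rtol: float = 1e-7,
    atol: float = 1e-10,
) -> list:
    """Simulate a heterogeneous cell population under one nutrient protocol.

    Each cell uses an independent, cell-id-keyed random stream, so trace sets
    are reproducible given ``spec.seed`` and insensitive to generation order.
    The perturbation is assumed to occur at t=0 (protocol schedule times are
    relative to simulation start); ``ros_ratio`` is normalized to the mean of
    samples at t <= t_baseline.
    """
    from .dynamics import steady_initial_state
    from .steadystate import _classify_point, _polish_root

    base_env = protocol.at(-1.0) if protocol.schedule else protocol
    base_init = steady_initial_state(base_env, base_params, branch="high_gsh")
    traces = []
    root = np.random.SeedSequence(spec.seed)
    committed_draws = np.random.default_rng(root.spawn(1)[0]).random(spec.n_cells)
    for cell_id in range(spec.n_cells):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed,
                                                           spawn_key=(1, cell_id)))
        force_non = committed_draws[cell_id] < spec.nonresponder_fraction
        p = _jittered_params(base_params, spec, rng, force_non)
        # warm-start the cell's own high-GSH fixed point from the base cell's
        y = _polish_root(base_init.to_array(), base_env, p)
        fp = _classify_point(y, base_env, p, 1e-6) if y is not None else None
        if fp is not None and fp.is_stable:
            init = fp.state
        else:
            init = steady_initial_state(base_env, p, branch="high_gsh")
        traj = simulate(init, protocol, p, t_end, spec.sampling_interval,
                        rtol=rtol, atol=atol)
        t_cat = catastrophe_time(traj)
        ros = traj.series("ros").copy()
        baseline_mask = traj.times <= t_baseline
        baseline = float(np.mean(ros[baseline_mask])) if baseline_mask.any() else ros[0]
        ratio = ros / baseline
        if spec.measurement_noise_cv > 0:
            sigma = np.sqrt(np.log1p(spec.measurement_noise_cv**2))
            ratio = ratio * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=ratio.shape))
        traces.append(SingleCellTrace(
            cell_id=cell_id, times=traj.times, ros_ratio=ratio, protocol=protocol,
            committed=t_cat is not None, true_catastrophe_time=t_cat))
    return traces


def classify_responsive(
    trace: SingleCellTrace,
    window: float = 90.0,
    fold_threshold: float = 2.0,
    t_perturb: float = 0.0,
) -> str:
    """'responsive' iff the ROS ratio reaches ``fold_threshold`` within the
    window after the perturbation; otherwise 'non_responsive'."""
    if trace.times[-1] < t_perturb + window:
        raise ContractViolationError(
            f"trace ends at {trace.times[-1]} min; window needs {t_perturb + window} min")
    mask = (trace.times >= t_perturb) & (trace.times <= t_perturb + window)
    return "responsive" if float(np.max(trace.ros_ratio[mask])) >= fold_threshold else "non_responsive"


@dataclass(frozen=True)
class HillFit:
    """Decreasing Hill dose-response fit with bootstrap confidence interval."""

    hill_exponent: float
    half_point: float  # glucose µM at half response
    ci95: tuple  # (lo, hi) on the Hill exponent
    floor: float
    amplitude: float

    def predict(self, glucose):
        g = np.asarray(glucose, dtype=float)
        return self.floor + self.amplitude * self.half_point**self.hill_exponent / (
            self.half_point**self.hill_exponent + g**self.hill_exponent)


def _hill_decreasing(g, amplitude, half, n, floor):
    return floor + amplitude * half**n / (half**n + g**n)


def _fit_once(doses, response):
    span = response.max() - response.min()
    p0 = [span, float(np.median(doses)), 4.0, float(response.min())]
    lower = [0.0, min(doses[doses > 0], default=1e-3) * 1e-2, 0.5, 0.0]
    upper = [10 * span + 1e-9, max(doses) * 1e2, 50.0, response.max() + 1e-9]
    popt, _ = curve_fit(_hill_decreasing, doses, response, p0=p0,
                        bounds=(lower, upper), maxfev=20000)
    return popt


def fit_hill(
    dose_response,
    n_boot: int = 1000,
    seed: int = 0,
):
    """Fit a decreasing Hill curve to per-dose ROS summaries.

    ``dose_response`` is a sequence of ``(glucose_uM, summary)`` pairs, or of
    ``(glucose_uM, per_cell_values)`` with iterable per-cell summaries, in
    which case the per-dose summary is the median and the 95% CI on the Hill
    exponent comes from bootstrap resampling cells within each dose.
    """
    doses = np.array([d for d, _ in dose_response], dtype=float)
    if len(doses) < 4:
        raise ContractViolationError("need >= 4 dose levels to fit a Hill response")
    per_cell = [np.atleast_1d(np.asarray(v, dtype=float)) for _, v in dose_response]
    response = np.array([float(np.median(v)) for v in per_cell])
    if response.max() - response.min() <= 0 or doses.min() == doses.max():
        raise ContractViolationError("dose-response does not span a transition; Hill fit unidentifiable")
    amplitude, half, n, floor = _fit_once(doses, response)

    lo = hi = n
    if any(len(v) > 1 for v in per_cell) and n_boot > 0:
        rng = np.random.default_rng(seed)
        ns = []
        for _ in range(n_boot):
            resp_b = np.array([
                float(np.median(rng.choice(v, size=len(v), replace=True)))
                for v in per_cell])
            try:
                ns.append(_fit_once(doses, resp_b)[2])
            except RuntimeError:
                continue
        if ns:
            lo, hi = np.percentile(ns, [2.5, 97.5])
    return HillFit(hill_exponent=float(n), half_point=float(half),
                   ci95=(float(lo), float(hi)), floor=float(floor),
                   amplitude=float(amplitude))


def hysteresis_summary(
    up_traces: dict,
    down_traces: dict,
    window: float = 75.0,
    fold_threshold: float = 2.0,
    t_perturb_up: float = 0.0,
    t_perturb_down: float = 0.0,
):
    """Responsive fraction per deprivation level and irreversible fraction per
    add-back level.

    ``up_traces`` maps glucose level -> traces after stepping down to that
    level; ``down_traces`` maps add-back glucose level -> traces of cells
    (restricted by the caller to those classified responsive during the up
    phase) after glucose restoration at ``t_perturb_down``.  Irreversible
    cells still show a ratio >= ``fold_threshold`` at the end of the window
    after add-back.  Levels with no eligible cells are flagged NaN.
    """
    up_rows = []
    for level, traces in sorted(up_traces.items()):
        labels = [classify_responsive(tr, window=window, fold_threshold=fold_threshold,
                                      t_perturb=t_perturb_up) for tr in traces]
        frac = np.mean([lab == "responsive" for lab in labels]) if labels else np.nan
        up_rows.append({"glc_uM": level, "n_cells": len(traces),
                        "percent_responsive": 100.0 * frac})
    down_rows = []
    for level, traces in sorted(down_traces.items()):
        if len(traces) == 0:
            down_rows.append({"glc_uM": level, "n_cells": 0,
                              "percent_irreversible": np.nan})
            continue
        irrevs = []
        for tr in traces:
            t_eval = t_perturb_down + window
            if tr.times[-1] < t_eval:
                raise ContractViolationError("trace does not cover the add-back window")
            i = int(np.argmin(np.abs(tr.times - t_eval)))
            irrevs.append(tr.ros_ratio[i] >= fold_threshold)
        down_rows.append({"glc_uM": level, "n_cells": len(traces),
                          "percent_irreversible": 100.0 * float(np.mean(irrevs))})
    return pd.DataFrame(up_rows), pd.DataFrame(down_rows)


def traces_to_frame(traces) -> pd.DataFrame:
    """Long-form (cell_id, time_min, ros_ratio) table for export."""
    return pd.concat([tr.to_frame() for tr in traces], ignore_index=True)


def ground_truth_frame(traces) -> pd.DataFrame:
    return pd.DataFrame([
        {"cell_id": tr.cell_id, "committed": tr.committed,
         "true_catastrophe_time_min": tr.true_catastrophe_time}
        for tr in traces])
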