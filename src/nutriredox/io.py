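"""Reading and writing of parameter files, protocols, constraint tables and
trajectory/branch outputs.

Parameter files are flat YAML mappings with one entry per model parameter
(units documented in a header comment); unknown keys are rejected.  Constraint
tables are tidy CSVs with columns ``name, kind, value, units`` where kind is
one of concentration, flux, fold_activation, timescale, fixed or environment.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import FIXED_PARAM_NAMES, SteadyStateConstraintSet
from .model import (
    PARAM_NAMES,
    STATE_NAMES,
    ContractViolationError,
    ModelParameters,
    NutrientEnvironment,
)

__all__ = [
    "read_parameters_yaml",
    "write_parameters_yaml",
    "read_constraints_csv",
    "write_constraints_csv",
    "read_protocol_yaml",
    "write_trajectory_csv",
    "write_branch_outputs",
]

_PARAM_HEADER = """\
# nutriredox model parameters
# units: concentrations/totals in uM; first-order constants 1/min;
# bimolecular constants 1/(uM*min); trimolecular constants 1/(uM^2*min);
# switch_nadp_import and partition fractions dimensionless.
"""


def read_parameters_yaml(path_or_buf) -> ModelParameters:
    if hasattr(path_or_buf, "read"):
        data = yaml.safe_load(path_or_buf.read())
    else:
        data = yaml.safe_load(Path(path_or_buf).read_text())
    if not isinstance(data, dict):
        raise ContractViolationError("parameter file must be a flat mapping")
    data = {k: v for k, v in data.items() if not str(k).startswith("_")}
    unknown = sorted(set(data) - set(PARAM_NAMES))
    if unknown:
        raise ContractViolationError(f"unknown parameter keys: {unknown}")
    missing = sorted(set(PARAM_NAMES) - set(data))
    if missing:
        raise ContractViolationError(f"missing parameter keys: {missing}")
    return ModelParameters(**{k: float(v) for k, v in data.items()})


def write_parameters_yaml(params: ModelParameters, path, provenance: dict | None = None) -> None:
    body = yaml.safe_dump({k: float(v) for k, v in params.to_dict().items()},
                          sort_keys=False)
    header = _PARAM_HEADER
    if provenance:
        header += "".join(f"# {k}: {v}\n" for k, v in provenance.items())
    Path(path).write_text(header + body)


_CONSTRAINT_UNITS = {"concentration": "uM", "flux": "uM/min",
                     "fold_activation": "fold", "timescale": "1/min or 1/(uM*min)",
                     "fixed": "model units", "environment": "uM"}


def write_constraints_csv(cs: SteadyStateConstraintSet, path_or_buf) -> None:
    rows = []
    env = cs.environment.at(0.0)
    for name, val in (("glc_ext", env.glc_ext), ("gln_ext", env.gln_ext),
                      ("cys2_ext", env.cys2_ext)):
        rows.append((name, "environment", val))
    for name in STATE_NAMES:
        rows.append((name, "concentration", cs.concentrations[name]))
    for name, val in cs.fluxes.items():
        rows.append((name, "flux", val))
    for name, val in cs.fold_activations.items():
        rows.append((name, "fold_activation", val))
    for name, val in cs.loop_timescales.items():
        rows.append((name, "timescale", val))
    for name in FIXED_PARAM_NAMES:
        rows.append((name, "fixed", cs.fixed[name]))
    df = pd.DataFrame(rows, columns=["name", "kind", "value"])
    df["units"] = df["kind"].map(_CONSTRAINT_UNITS)
    df.to_csv(path_or_buf, index=False)


def read_constraints_csv(path_or_buf) -> SteadyStateConstraintSet:
    df = pd.read_csv(path_or_buf)
    need = {"name", "kind", "value"}
    if not need <= set(df.columns):
        raise ContractViolationError(f"constraint table must have columns {sorted(need)}")

    def grab(kind):
        sub = df[df["kind"] == kind]
        return dict(zip(sub["name"], sub["value"].astype(float)))

    envd = grab("environment")
    missing_env = {"glc_ext", "gln_ext", "cys2_ext"} - set(envd)
    if missing_env:
        raise ContractViolationError(f"constraint table lacks environment rows: {sorted(missing_env)}")
    return SteadyStateConstraintSet(
        concentrations=grab("concentration"),
        fluxes=grab("flux"),
        environment=NutrientEnvironment(envd["glc_ext"], envd["gln_ext"], envd["cys2_ext"]),
        fixed=grab("fixed"),
        fold_activations=grab("fold_activation"),
        loop_timescales=grab("timescale"),
    )


def read_protocol_yaml(path_or_buf) -> NutrientEnvironment:
    """Protocol files: a baseline environment plus ordered schedule segments
    {t_start_min, glc_ext_uM, gln_ext_uM, cys2_ext_uM}."""
    if hasattr(path_or_buf, "read"):
        data = yaml.safe_load(path_or_buf.read())
    else:
        data = yaml.safe_load(Path(path_or_buf).read_text())
    base = data.get("baseline", {})
    segs = tuple(
        (float(s["t_start_min"]), float(s["glc_ext_uM"]), float(s["gln_ext_uM"]),
         float(s["cys2_ext_uM"]))
        for s in data.get("schedule", []))
    return NutrientEnvironment(
        float(base["glc_ext_uM"]), float(base["gln_ext_uM"]), float(base["cys2_ext_uM"]),
        schedule=segs)


def _provenance_header(seed=None, config: dict | None = None) -> str:
    from . import __version__

    parts = [f"# nutriredox v{__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
        parts.append(f"# config_sha256: {digest}")
    return "\n".join(parts) + "\n"


def write_trajectory_csv(traj, path, seed=None, config=None) -> None:
    """Tidy trajectory CSV: time, ten states, every flux column."""
    df = traj.to_frame(include_fluxes=True)
    with open(path, "w") as f:
        f.write(_provenance_header(seed, config))
        df.to_csv(f, index=False)


def write_branch_outputs(branch, csv_path, json_path=None, seed=None, config=None) -> None:
    df = branch.to_frame()
    with open(csv_path, "w") as f:
        f.write(_provenance_header(seed, config))
        df.to_csv(f, index=False)
    if json_path is not None:
        payload = {"axis_name": branch.axis_name,
                   "fold_points": [float(x) for x in branch.fold_points],
                   "bistable_window": branch.bistable_window()}
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
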