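#!/usr/bin/env python
"""Regenerate the shipped default constraint table from its design values.

The reference (glucose-addicted) configuration is specified as a
steady-state design: concentrations of the high-GSH state at abundant
nutrients, a handful of primary fluxes, the fixed (literature-style)
constants, and the signaling-loop fold activations/timescales.  The
remaining fluxes are filled in so every balance closes exactly, which is
what makes the table calibrate back to a parameter set whose steady state
is the tabulated state.  Rationale for the chosen magnitudes is in
docs/methods.md.
"""

from pathlib import Path

from nutriredox.calibration import SteadyStateCalibration, SteadyStateConstraintSet
from nutriredox.io import write_constraints_csv
from nutriredox.model import NutrientEnvironment

ENVIRONMENT = NutrientEnvironment(10_000.0, 2_000.0, 200.0)

CONCENTRATIONS = dict(  # µM, high-GSH reference steady state
    cys2_in=100.0, cys=100.0, glu=3000.0, nadph=0.96, gsh=3000.0,
    gssg=30.0, ros=0.01, ca=0.1, pptase_red=0.0333, tk_phos=0.045)

PRIMARY_FLUXES = dict(  # µM/min
    cystine_uptake=30.0,        # SLC7A11 antiport (glucose-addicted: high)
    gsh_synthesis=30.0,         # de novo glutamate-cysteine ligation
    glutamate_production=64.0,  # glutamine uptake + deamination
    nadph_ox_anabolism=10.0,    # reductive biosynthesis drain
    nadph_regen_glu=5.7,        # glutamate/TCA-route NADPH regeneration
    gsh_oxidation=100.0,        # glutathione redox-cycle flux (per ROS)
)

ROS_PARTITION = dict(basal=0.15, glc=0.10, glu=0.75)  # realized flux shares

FIXED = dict(
    K_cys2_import=300.0, K_gln_import=1000.0, K_glc_import=3000.0,
    K_glu_import_ros=1000.0, f_ros_from_glc=0.10, f_ros_from_glu=0.75,
    K_ros_inhibition=1.5, n1=6.0, SLC7A11=5.0, NADP_total=1.0,
    PPTase_total=0.1, TK_total=0.1, switch_nadp_import=0.95)

SIGNALING = dict(
    fold_activations=dict(ros=100.0, ca=1.7),
    loop_timescales=dict(ca=1.0, pptase=250.0, tk=0.5))


def build() -> SteadyStateConstraintSet:
    c, f = CONCENTRATIONS, dict(PRIMARY_FLUXES)
    # balancing fluxes so the table is exactly self-consistent
    v_gs = f["gsh_synthesis"]
    k_gd = v_gs / (c["gsh"] + 2 * c["gssg"])      # total-glutathione balance
    v_go = f["gsh_oxidation"]
    v_gr = v_go - k_gd * c["gssg"]                # GSSG balance
    f["gsh_degradation"] = k_gd * c["gsh"]
    f["nadph_ox_gssg"] = v_gr
    f["nadph_regen_glc"] = (f["nadph_ox_anabolism"] + f["cystine_uptake"]
                            + v_gr - f["nadph_regen_glu"])  # NADPH balance
    for part, share in ROS_PARTITION.items():
        f[f"ros_production_{part}"] = v_go * share  # ROS balance (1:1 with v_go)
    return SteadyStateConstraintSet(
        concentrations=c, fluxes=f, environment=ENVIRONMENT, fixed=FIXED,
        **SIGNALING)


if __name__ == "__main__":
    cs = build()
    out = Path(__file__).resolve().parents[1] / "src/nutriredox/data/default_constraints.csv"
    write_constraints_csv(cs, out)
    res = SteadyStateCalibration(cs).fit()
    print(f"wrote {out}")
    print(f"max steady-state residual of calibrated set: {res.max_residual:.3e}")
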