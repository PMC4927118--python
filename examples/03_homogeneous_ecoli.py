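"""Homogeneous-weight study on an E. coli reconstruction.

Calibrates the uniform enzyme weight w_E so that the maximal growth
rate at saturating glucose (w_C = 0) equals 1/h, then sweeps the carbon
cost w_C.  Watch three things as glucose becomes scarce: growth slows,
the catabolic proteome share Delta_phi_C rises while Delta_phi_E and
Delta_phi_R shrink, and acetate secretion switches off (the transition
from fermentative to respiratory energy production).

Uses the core E. coli network so it runs in seconds; substitute
load_builtin("iJO1366") for the genome-scale version.
"""

from cafba import (
    BUILTIN_SECTOR_CONFIGS,
    calibrate_homogeneous,
    homogeneous_weights,
    load_builtin,
    prepare_model,
    solve_cafba,
)

model = prepare_model(
    load_builtin("e_coli_core"), BUILTIN_SECTOR_CONFIGS["e_coli_core"]
)
w_E = calibrate_homogeneous(model, 1.0, tol=1e-4)
print(f"calibrated w_E = {w_E:.4g} gh/mmol (lambda_max = 1/h)\n")

header = f"{'w_C':>8} {'lambda':>7} {'glc':>7} {'acetate':>8} " \
         f"{'dphi_C':>7} {'dphi_E':>7} {'dphi_R':>7}"
print(header)
for w_C in [0.0, 1e-3, 2e-3, 4e-3, 6e-3, 8e-3, 1.2e-2]:
    sol = solve_cafba(model, homogeneous_weights(model, w_E, w_C=w_C))
    print(
        f"{w_C:8.4f} {sol.growth_rate:7.3f} {sol.carbon_intake_flux:7.2f} "
        f"{sol.fluxes['EX_ac_e']:8.3f} "
        f"{sol.sector_fractions['C']:7.3f} "
        f"{sol.sector_fractions['E']:7.3f} "
        f"{sol.sector_fractions['R']:7.3f}"
    )
# Acetate is secreted only at fast growth (small w_C): with cheap carbon
# it pays to waste substrate on the proteome-efficient fermentation
# route; once carbon is expensive the high-yield respiratory pathway wins.
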