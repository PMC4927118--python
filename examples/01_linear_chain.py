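"""Closed-form check on the smallest possible network.

A single pathway (uptake -> one enzymatic step -> biomass, yield y)
under the proteome-allocation constraint has the exact optimum

    lambda* = phi_max * y / (w_C + w_1 + y * w_R)

The LP solution must reproduce it to machine precision, and the entire
budget phi_max must be spent across the C/E/R sectors.
"""

from cafba import solve_cafba, verify_solution
from cafba.toys import make_linear_chain

model, weights, lam_exact = make_linear_chain(
    k=1, y=1.0, w_path=[0.1], w_C=0.1, w_R=0.3, phi_max=0.5
)
sol = solve_cafba(model, weights)

print(f"analytic optimum : {lam_exact:.6f} /h")
print(f"LP optimum       : {sol.growth_rate:.6f} /h")
print(f"sector fractions : C={sol.sector_fractions['C']:.4f} "
      f"E={sol.sector_fractions['E']:.4f} R={sol.sector_fractions['R']:.4f}")
print(f"budget slack     : {sol.constraint_slack:.2e}")
print(f"residuals        : {verify_solution(model, weights, sol)}")
# The three sector fractions sum to phi_max = 0.5: at the optimum the
# proteome budget is exhausted, which is what ties growth to allocation.
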