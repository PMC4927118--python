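"""The essence of overflow metabolism in a two-pathway toy.

Two routes feed biomass: H has high yield but a high proteome cost per
unit flux (respiration analogue), F is cheap but wasteful (fermentation
analogue).  The optimum uses whichever minimizes (w_C + w_p)/y_p, so as
the carbon cost w_C rises (glucose becomes scarce) the solution switches
from F to H at the analytic crossover w_C*.
"""

from cafba import solve_cafba
from cafba.toys import make_two_pathway

toy = make_two_pathway(y_H=1.0, y_F=0.5, w_H=0.3, w_F=0.05)
print(f"analytic crossover w_C* = {toy.w_c_star:.4f} gh/mmol\n")
print(f"{'w_C':>8} {'lambda':>8} {'flux H':>8} {'flux F':>8}  regime")
for w_C in [0.0, 0.1, 0.18, 0.22, 0.3, 0.5]:
    sol = solve_cafba(toy.model, toy.weights(w_C))
    regime = "fermentative" if sol.fluxes["PF"] > 1e-6 else "respiratory"
    print(
        f"{w_C:8.3f} {sol.growth_rate:8.4f} "
        f"{sol.fluxes['PH']:8.4f} {sol.fluxes['PF']:8.4f}  {regime}"
    )
# Below w_C* all flux goes through the cheap low-yield route; above it
# the expensive high-yield route takes over -- the proteome-efficiency
# versus carbon-efficiency trade-off behind acetate overflow.
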