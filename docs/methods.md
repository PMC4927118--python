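# Methods

## Model

The package solves growth-rate maximization on a stoichiometric network
subject to one genome-wide proteome-allocation constraint. The biological
premise is the growth-law organization of the bacterial proteome into four
sectors: ribosome-affiliated proteins whose share grows linearly with the
growth rate λ (slope w_R), carbon-catabolic proteins whose share grows
linearly with the carbon intake flux v_C (slope w_C), biosynthetic enzymes
whose individual shares grow linearly with the absolute flux they carry
(slopes w_i), and a growth-rate-independent housekeeping core. Since the
four shares sum to one, the growth-dependent parts obey

    w_C v_C + Σ_i w_i |v_i| + w_R λ ≤ φ_max ,

with φ_max the proteome fraction left over after all constant offsets.
Growth maximization under this constraint plus mass balance and flux bounds
reproduces the respiration-to-fermentation crossover: at low carbon cost
(abundant glucose) the optimum secretes acetate because fermentation buys
more flux per unit proteome, at high carbon cost the high-yield respiratory
pathways win.

Only the constraint's linear outcome is implemented; the underlying
Michaelis–Menten enzyme kinetics that motivate linearity are not (the
sugar-level transform w_C(g) = w_C0 (1 + K_M/[g]) is provided as a
convenience, `wc_from_sugar_level`).

## The LP formulation and its exactness

Absolute values make the problem a MILP in general. Each weighted flux with
a negative lower bound is split as v = v⁺ − v⁻ with 0 ≤ v⁺ ≤ u and
0 ≤ v⁻ ≤ −ℓ, and |v| is replaced by v⁺ + v⁻ in the allocation row. At a
growth-maximizing vertex the sum v⁺ + v⁻ is minimized at fixed net flux,
which zeroes one of the two components, so the relaxation is exact. This is
verified rather than assumed: every solution records the largest
min(v⁺, v⁻) before repair, and the test suite checks the split-flux optimum
against a brute-force oracle that enumerates all sign patterns of the
reversible weighted fluxes and solves each direction-restricted LP exactly.
A reaction forced backwards (u < 0) keeps its requirement through a lower
bound on the backward variable.

The allocation row is implemented as an inequality (≤ φ_max) rather than
the strict equality of the sector sum rule. At any optimum where growth is
allocation-limited the row binds and the two are equivalent; the inequality
keeps models feasible when another bound caps growth first, and the
per-solution `constraint_slack` makes such cases visible. The budget is
reported exhausted (|slack| ≤ 1e-6) in all shipped growth-limited cases.

v_C is the uptake magnitude of the designated carbon-source exchange, so
w_C is attached to the backward (uptake) component of that exchange; the
configured carbon-intake pathway reactions (PTS/ABC/permease/hexokinase
routes for glucose) carry no E-sector weight, since their cost is what w_C
represents. Biomass and the ATP-maintenance reaction are likewise excluded;
maintenance keeps its lower bound from the model file.

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| w_R | ribosomal proteome per unit growth rate | 0.169 | h |
| φ_max | growth-dependent proteome budget | 0.484 | — |
| w_E or ⟨w⟩ | enzyme cost scale | calibrated | g·h/mmol |
| δ | decades spanned by the weight density | 1 | — |
| w_C | catabolic cost per unit intake (control dial) | swept from 0 | g·h/mmol |
| ε (transports) | futile-loop suppression weight | 1e-6 | g·h/mmol |
| μ_glc | glucose molecular weight (yield) | 0.18 | g/mmol |

w_R and φ_max are empirical growth-law values for glucose-limited *E. coli*
K-12. The enzyme-cost scale is never taken from kinetic databases; it is
calibrated by bisection so that the maximal growth rate at w_C = 0 (the
extrapolated rate at saturating carbon) matches an empirical target,
1/h by default. λ*(w_E) is monotone, so bisection is exact; for the
heterogeneous scheme the Monte-Carlo mean λ̄(⟨w⟩) is made numerically
monotone by common random numbers — each realization keeps its underlying
uniform draws across bisection steps, only the density's scale moves.

Heterogeneous weights are i.i.d. log-uniform, p(w) ∝ 1/w on
[w_min, w_max]. The pair (⟨w⟩, δ) fixes the bounds through the density's
analytic mean: with r = 10^δ, w_min = ⟨w⟩ ln r/(r − 1), w_max = r·w_min.
A log-normal family (matched arithmetic mean, log-width σ_log) is included
as a robustness alternative. Calibrated on iJO1366 this yields
w_E ≈ 8.9e-4 and ⟨w⟩ ≈ 9.4e-4 g·h/mmol for λ_max = 1/h (literature
calibrations on iJR904 give 8.3e-4 and 8.8e-4; the few-percent shift
reflects the different reconstruction and the (⟨w⟩, δ) → bounds convention,
for which no standard exists).

## Ensembles and sweeps

Because per-enzyme costs are unknown, observables are ensemble averages:
at each control point (w_C, w_R) n independent weight realizations are
solved, realization k seeded deterministically from (master seed, k), and
means/SDs/SEs are reported with failed solves counted separately. Carbon
limitation sweeps w_C up from 0; translational inhibition sweeps w_R up
from 0.169 h at fixed w_C (default 1.4e-3 g·h/mmol, a high-nutritional-
capacity source). Fresh realizations per grid point are the default; a flag holds weights
common across the grid for trajectory studies, which also makes the mean
growth rate exactly monotone along the grid rather than monotone in
expectation. Reporter fluxes follow the published choices: TCA flux is
α-ketoglutarate dehydrogenase, glyoxylate shunt is malate synthase, the
ED pathway is 6-phosphogluconate dehydratase, plus the acetate, CO₂ and
glucose exchanges; the id map is configurable per reconstruction.

The acetate onset is an OLS fit of mean secretion on mean growth rate over
the actively overflowing points (secretion > 1 mmol/gDW/h by default, the
threshold is reported with the fit); λ_ac = −intercept/slope with a
delta-method standard error. Literature onset lines are typically drawn by
eye, so fitted values should be compared at the fit's quoted uncertainty,
not at printed-digit precision.

## Growth-rate-dependent biomass

Biomass coefficients may depend on λ (piecewise-linear knot tables, a JSON
sidecar format, or any callable); the growth-associated ATP demand enters
as β_ATP mmol ATP hydrolyzed per gram of biomass folded into the biomass
column, and the maintenance demand v_ATPM as the ATP-maintenance reaction's
lower bound, so v_ATP = v_ATPM + β_ATP λ holds by construction. The
self-consistent optimum is found by iterating (solve the LP at the current
composition) → (update the composition at the new λ) from λ₀ = 0.5/h until the
growth rate moves less than 1e-6/h. Convergence is typically 2–8 LPs; an
optional damping factor relaxes the update if an exotic composition makes
the undamped map oscillate. On the shipped models a λ-independent
composition converges in ≤ 2 iterations to the fixed-biomass optimum, and
the converged solution is re-verified to be the exact optimum of the
converged composition.

## Numerical choices

LPs are solved with HiGHS (scipy.optimize.linprog) with primal/dual
feasibility tolerances of 1e-9; solution reports flag residuals above 1e-6.
The tight tolerances matter because the allocation row mixes coefficients
of order 1e-6…1e-2 with flux bounds of order 1e3. Futile transport loops
(which carry no real weight) are suppressed by a tiny default ε = 1e-6
g·h/mmol on transports: measured on iJO1366, weights much below this are
invisible at the solver's scaled tolerance and leave saturated loop fluxes
plus an allocation row violated at the 1e-6 level, while ε = 1e-6 removes
the loops, lets the row bind exactly, and shifts the growth rate by less
than 0.05%. Infinite bounds are replaced by ±1000 mmol/gDW/h (COBRA
convention, configurable). If a solver vertex still carries a common
forward/backward component, the common part is subtracted (this preserves
mass balance and can only loosen the allocation row) and its size reported.
Homogeneous-weight optima can be degenerate (alternate pathways with equal
cost); the returned vertex is whatever HiGHS selects deterministically, and
heterogeneous weights make ties measure-zero.

Transport classification strips the compartment suffix from metabolite ids
and calls a reaction a transport when the same base species appear on both
sides across compartments; ambiguous cases default to enzymatic and can be
overridden per reaction in the sector config.

## What the synthetic generators emulate

The toy networks reproduce the *structure* of the allocation problem — a
costed route from intake to biomass (linear chain, closed-form optimum),
competition between a high-yield/expensive and a low-yield/cheap route
(two-pathway toy, analytic crossover w_C*), futile loops, and random
connected stoichiometries with reversible weighted steps for the oracle
equivalence suite. They do not emulate real pathway topology, cofactor
coupling, or realistic yield values, so passing the toy suite demonstrates
solver correctness, not biological calibration; the genome-scale claims
rest on the bundled E. coli reconstructions. Random toys use integer
stoichiometric coefficients in {−2…2} to keep the LPs well conditioned.

## Problem sizes

The acceptance script runs 20 randomized chains, 50 random oracle toys and
20 crossover specs, then the iJO1366 study with 60-realization
calibrations, a 200-realization ensemble at w_C = 0, a 10-point × 100-
realization carbon-limitation sweep, 20-solution overlaps, and a 6-point ×
40-realization variable-biomass sweep. These sizes put a few percent of
Monte-Carlo uncertainty on ensemble means (the published study used
500–1000 realizations per point); the calibration tolerance is 3e-3/h on
the ensemble mean. Single iJO1366 solves take ~0.1 s, so the full script
is minutes on one CPU.

## Known limitations

- No QP/NLP variants, no thermodynamic loopless constraints beyond the
  ε-weights, no explicit macromolecule species (ME-model/RBA territory),
  no gene–protein–reaction rule evaluation.
- Per-reaction empirical weights from proteomics are not fitted; the
  heterogeneous scheme is a prior over unknown costs, not an inference.
- The (⟨w⟩, δ) → (w_min, w_max) convention fixes the density by its mean;
  a median- or mode-matched convention would shift calibrated ⟨w⟩ by a few
  percent.
- Sector classification is heuristic for arbitrary reconstructions;
  the shipped configs cover the standard E. coli models, anything else
  should be reviewed via `category_report` and overridden as needed.
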