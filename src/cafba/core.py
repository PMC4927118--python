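"""Build and solve the constrained-allocation LP.

The optimization problem is

    max  lambda
    s.t. S v = 0
         l_i <= v_i <= u_i
         w_C v_C + sum_i w_i |v_i| + w_R lambda <= phi_max

where lambda is the biomass flux and v_C >= 0 the uptake magnitude of
the designated carbon-source exchange.  The absolute values are removed
by splitting every weighted reversible flux into non-negative forward
and backward components (v = v+ - v-, 0 <= v+ <= u, 0 <= v- <= -l).
Because a growth-maximizing solution also minimizes v+ + v- at fixed
net flux, at the optimum one of the two components vanishes for every
reaction and |v| = v+ + v- holds, so the split problem is an exact LP
reformulation rather than a relaxation.

The allocation row is implemented as `<= phi_max`: at any optimum where
growth is allocation-limited it binds, and the reported slack makes the
rare capped cases visible instead of infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import MetabolicModel, ModelError

#: residual threshold used in solution reports
RESIDUAL_TOL = 1e-6

#: LP solver settings: tight feasibility tolerances are needed because
#: the allocation row mixes O(1e-9) epsilon weights with O(1e3) bounds
LP_OPTIONS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class CafbaWeights:
    """Coefficients of the proteome-allocation constraint.

    ``w_C`` (g h/mmol) multiplies the carbon uptake flux, ``w_R`` (h)
    multiplies the growth rate, ``w`` maps reaction ids to E-sector
    weights (g h/mmol; zero/absent for excluded categories), and
    ``phi_max`` is the dimensionless proteome budget.
    """

    w_C: float
    w_R: float
    phi_max: float
    w: Dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.w_C < 0 or self.w_R < 0:
            raise ValueError("w_C and w_R must be non-negative")
        if not 0 <= self.phi_max <= 1:
            raise ValueError("phi_max must lie in [0, 1]")
        bad = [r for r, v in self.w.items() if v < 0]
        if bad:
            raise ValueError(f"negative weights for {bad}")

    def vector(self, model: MetabolicModel) -> np.ndarray:
        v = np.zeros(model.n_reactions)
        for rid, w in self.w.items():
            v[model.index(rid)] = w
        return v

    def replace(self, **kwargs) -> "CafbaWeights":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class CafbaLP:
    """Split-flux LP in arrays, with the variable layout exposed.

    Variables are ordered as the ``n`` net/forward fluxes followed by
    one backward variable per split reaction (``split`` holds their
    reaction indices in order).
    """

    model: MetabolicModel
    weights: CafbaWeights
    A_eq: sp.csc_matrix
    allocation_row: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    split: List[int]

    @property
    def n_variables(self) -> int:
        return self.A_eq.shape[1]


@dataclass
class CafbaSolution:
    """Optimal flux vector plus the allocation-side bookkeeping."""

    fluxes: Dict[str, float]
    growth_rate: float
    sector_fractions: Dict[str, float]  # keys: C, E, R
    constraint_slack: float
    status: str
    carbon_intake_flux: float = 0.0
    split_violation: float = 0.0
    weights_used: Optional[CafbaWeights] = None
    forward: Optional[Dict[str, float]] = None
    backward: Optional[Dict[str, float]] = None
    objective_reaction: str = ""

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_cafba_lp(model: MetabolicModel, weights: CafbaWeights) -> CafbaLP:
    """Assemble the split-flux LP for ``model`` under ``weights``.

    A backward variable is created for every reaction with a negative
    lower bound that either carries a weight or is the carbon-source
    exchange (whose uptake magnitude defines v_C).  Unweighted
    reactions keep a single net variable.
    """
    n = model.n_reactions
    w = weights.vector(model)
    for rid in model.reactions_in_category("enzymatic"):
        if rid not in weights.w:
            raise ValueError(
                f"weights do not cover enzymatic reaction {rid!r}"
            )
    lb, ub = model.lower_bounds, model.upper_bounds
    cex = model.index(model.carbon_source) if model.carbon_source else None
    if weights.w_C > 0 and cex is None:
        raise ValueError(
            "w_C > 0 but the model has no designated carbon source; "
            "run classify_reactions first"
        )

    split = [
        j
        for j in range(n)
        if lb[j] < 0 and (w[j] > 0 or (cex is not None and j == cex))
    ]
    ns = len(split)
    A_eq = sp.hstack([model.S, -model.S[:, split]], format="csc")

    is_split = np.zeros(n, dtype=bool)
    is_split[split] = True
    # forward component: [0, max(u, 0)]; backward: [max(-u, 0), -l].
    # A forced-backward reaction (u < 0) keeps its requirement through
    # the backward variable's lower bound.
    lo_fwd = np.where(is_split, 0.0, lb)
    hi_fwd = np.where(is_split, np.maximum(ub, 0.0), ub)
    lower = np.concatenate([lo_fwd, np.maximum(-ub[split], 0.0)])
    upper = np.concatenate([hi_fwd, -lb[split]])

    arow = np.concatenate([w, w[split]])
    bio = model.index(model.biomass_reaction)
    arow[bio] += weights.w_R
    if cex is not None and cex in split:
        arow[n + split.index(cex)] += weights.w_C

    c = np.zeros(n + ns)
    c[bio] = -1.0
    return CafbaLP(
        model=model,
        weights=weights,
        A_eq=A_eq,
        allocation_row=arow,
        lower=lower,
        upper=upper,
        objective=c,
        split=split,
    )


def _sector_fractions(
    model: MetabolicModel,
    weights: CafbaWeights,
    v: np.ndarray,
    lam: float,
    v_C: float,
) -> Dict[str, float]:
    w = weights.vector(model)
    return {
        "C": weights.w_C * v_C,
        "E": float(np.sum(w * np.abs(v))),
        "R": weights.w_R * lam,
    }


def solve_cafba(
    model: MetabolicModel,
    weights: CafbaWeights,
    lp: Optional[CafbaLP] = None,
) -> CafbaSolution:
    """Solve the allocation-constrained growth maximization.

    Returns net fluxes ``v = v+ - v-``; if the solver leaves a common
    non-zero part on both split components it is subtracted (this keeps
    mass balance and can only loosen the allocation row) and the size of
    the repair is reported as ``split_violation``.
    """
    if lp is None:
        lp = build_cafba_lp(model, weights)
    n = model.n_reactions
    res = linprog(
        lp.objective,
        A_ub=lp.allocation_row[None, :],
        b_ub=[weights.phi_max],
        A_eq=lp.A_eq,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([lp.lower, lp.upper]),
        method="highs",
        options=LP_OPTIONS,
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return CafbaSolution(
            fluxes={},
            growth_rate=float("nan"),
            sector_fractions={"C": np.nan, "E": np.nan, "R": np.nan},
            constraint_slack=float("nan"),
            status=status,
            weights_used=weights,
            objective_reaction=model.biomass_reaction,
        )

    x = res.x
    fwd = x[:n].copy()
    bwd = np.zeros(n)
    bwd[lp.split] = x[n:]
    common = np.minimum(fwd, bwd)
    split_violation = float(common.max(initial=0.0))
    if split_violation > RESIDUAL_TOL:
        fwd -= common
        bwd -= common
    v = fwd - bwd

    lam = float(v[model.index(model.biomass_reaction)])
    v_C = 0.0
    if model.carbon_source is not None:
        v_C = max(0.0, -float(v[model.index(model.carbon_source)]))
    fractions = _sector_fractions(model, weights, v, lam, v_C)
    slack = weights.phi_max - sum(fractions.values())
    return CafbaSolution(
        fluxes=dict(zip(model.reaction_ids, v.tolist())),
        growth_rate=lam,
        sector_fractions=fractions,
        constraint_slack=float(slack),
        status="optimal",
        carbon_intake_flux=v_C,
        split_violation=split_violation,
        weights_used=weights,
        forward=dict(zip(model.reaction_ids, fwd.tolist())),
        backward=dict(zip(model.reaction_ids, bwd.tolist())),
        objective_reaction=model.biomass_reaction,
    )


def verify_solution(
    model: MetabolicModel,
    weights: CafbaWeights,
    solution: CafbaSolution,
) -> Dict[str, float]:
    """Maximum violations of mass balance, bounds, allocation and split.

    Reports only; all residuals should be below ``RESIDUAL_TOL`` for a
    trustworthy optimum.
    """
    if not solution.optimal:
        raise ValueError("can only verify an optimal solution")
    v = np.array([solution.fluxes[r] for r in model.reaction_ids])
    mass = model.S @ v
    bound_viol = np.maximum(
        model.lower_bounds - v, v - model.upper_bounds
    ).max(initial=0.0)
    w = weights.vector(model)
    v_C = solution.carbon_intake_flux
    lhs = (
        weights.w_C * v_C
        + float(np.sum(w * np.abs(v)))
        + weights.w_R * solution.growth_rate
    )
    split_viol = 0.0
    if solution.forward is not None and solution.backward is not None:
        split_viol = max(
            (
                min(solution.forward[r], solution.backward[r])
                for r in model.reaction_ids
            ),
            default=0.0,
        )
    return {
        "mass_balance": float(np.abs(mass).max(initial=0.0)),
        "bounds": float(bound_viol),
        "allocation": max(0.0, lhs - weights.phi_max),
        "split_property": float(split_viol),
    }


def wc_from_sugar_level(w_C0: float, K_M: float, g_level: float) -> float:
    """C-sector cost at extracellular sugar level ``g_level``.

    w_C = w_C0 * (1 + K_M / [g]): the cost takes its sugar-specific
    minimum w_C0 at saturating concentrations and grows as the sugar is
    diluted, which is how carbon limitation is dialed.
    """
    if w_C0 < 0:
        raise ValueError("w_C0 must be non-negative")
    if K_M <= 0:
        raise ValueError("K_M must be positive")
    if g_level <= 0:
        raise ValueError("sugar level must be positive")
    return w_C0 * (1.0 + K_M / g_level)


def solution_to_frame(model: MetabolicModel, solution: CafbaSolution):
    """Per-reaction table (net, forward, backward, weight) as a DataFrame."""
    import pandas as pd

    w = solution.weights_used.w if solution.weights_used else {}
    return pd.DataFrame(
        {
            "reaction_id": model.reaction_ids,
            "net_flux": [solution.fluxes[r] for r in model.reaction_ids],
            "forward": [
                (solution.forward or {}).get(r, np.nan)
                for r in model.reaction_ids
            ],
            "backward": [
                (solution.backward or {}).get(r, np.nan)
                for r in model.reaction_ids
            ],
            "weight": [w.get(r, 0.0) for r in model.reaction_ids],
        }
    )


def solution_summary(solution: CafbaSolution) -> Dict[str, object]:
    """JSON-ready summary (growth rate, sector fractions, slack, status)."""
    return {
        "growth_rate": solution.growth_rate,
        "sector_fractions": solution.sector_fractions,
        "constraint_slack": solution.constraint_slack,
        "carbon_intake_flux": solution.carbon_intake_flux,
        "split_violation": solution.split_violation,
        "status": solution.status,
    }
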