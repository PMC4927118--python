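"""Toy metabolic networks with known analytic optima, plus a brute-force oracle.

These fixtures make every numerical claim of the solver checkable
without any external model file:

* a linear chain whose optimal growth rate has the closed form
  ``lambda* = phi_max * y / (w_C + sum_i w_i + y * w_R)``;
* a two-pathway network exhibiting the overflow crossover: a low-yield,
  proteome-cheap route wins below an analytic carbon cost ``w_C*`` and a
  high-yield, expensive route wins above it;
* random connected networks with integer stoichiometries;
* a sign-enumeration oracle that solves the allocation problem exactly
  as a sequence of direction-restricted LPs (the MILP route that the
  split-flux LP provably reduces to).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .core import LP_OPTIONS, CafbaSolution, CafbaWeights, _sector_fractions
from .model import MetabolicModel, SectorConfig, classify_reactions

BIG = 1000.0


def _assemble(
    metabolites: List[str],
    reactions: List[Tuple[str, Dict[str, float], float, float]],
    biomass: str,
    carbon_source: str,
    carbon_intake: Sequence[str] = (),
    compartments: Optional[Dict[str, str]] = None,
) -> MetabolicModel:
    mets = {m: i for i, m in enumerate(metabolites)}
    S = sp.lil_matrix((len(metabolites), len(reactions)))
    rids, lbs, ubs = [], [], []
    for j, (rid, stoich, lb, ub) in enumerate(reactions):
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        for m, c in stoich.items():
            S[mets[m], j] = c
    model = MetabolicModel(
        metabolite_ids=metabolites,
        reaction_ids=rids,
        S=S.tocsc(),
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        biomass_reaction=biomass,
        metabolite_compartments=compartments
        or {m: "c" for m in metabolites},
        provenance=["synthetic toy network"],
    )
    config = SectorConfig(
        carbon_source=carbon_source,
        carbon_intake_reactions=list(carbon_intake),
    )
    return classify_reactions(model, config)


def chain_lambda(
    phi_max: float, y: float, w_C: float, w_path: Sequence[float], w_R: float
) -> float:
    """Closed-form optimum of a single linear pathway with yield ``y``."""
    return phi_max * y / (w_C + sum(w_path) + y * w_R)


def make_linear_chain(
    k: int = 1,
    y: float = 1.0,
    w_path: Sequence[float] = (0.1,),
    w_C: float = 0.1,
    w_R: float = 0.3,
    phi_max: float = 0.5,
) -> Tuple[MetabolicModel, CafbaWeights, float]:
    """Intake -> k enzymatic steps -> biomass with yield ``y``.

    Returns the classified model, a matching weight set, and the
    analytic optimal growth rate.
    """
    if k < 1:
        raise ValueError("chain needs at least one enzymatic step")
    w_path = list(w_path)
    if len(w_path) != k:
        raise ValueError("need one weight per enzymatic step")
    metabolites = ["glc_e"] + [f"m{i}_c" for i in range(1, k + 1)]
    compartments = {"glc_e": "e", **{f"m{i}_c": "c" for i in range(1, k + 1)}}
    reactions = [
        ("EX_glc", {"glc_e": -1.0}, -BIG, BIG),
        ("UPT", {"glc_e": -1.0, "m1_c": 1.0}, 0.0, BIG),
    ]
    for i in range(1, k):
        reactions.append(
            (f"E{i}", {f"m{i}_c": -1.0, f"m{i+1}_c": 1.0}, 0.0, BIG)
        )
    # the k-th enzymatic step feeds a dedicated biomass precursor, and
    # the biomass reaction consumes 1/y of it per unit growth rate
    metabolites.append(f"m{k}_c_x")
    compartments[f"m{k}_c_x"] = "c"
    reactions.append((f"E{k}", {f"m{k}_c": -1.0, f"m{k}_c_x": 1.0}, 0.0, BIG))
    reactions.append(("BIOMASS", {f"m{k}_c_x": -1.0 / y}, 0.0, BIG))
    model = _assemble(
        metabolites,
        reactions,
        biomass="BIOMASS",
        carbon_source="EX_glc",
        carbon_intake=["UPT"],
        compartments=compartments,
    )
    w = {f"E{i}": w_path[i - 1] for i in range(1, k + 1)}
    weights = CafbaWeights(
        w_C=w_C, w_R=w_R, phi_max=phi_max, w=w, provenance="linear chain toy"
    )
    lam = chain_lambda(phi_max, y, w_C, w_path, w_R)
    return model, weights, lam


def two_pathway_crossover(
    y_H: float, y_F: float, w_H: float, w_F: float
) -> float:
    """Carbon cost at which the high-yield route H overtakes route F.

    The optimum uses the pathway minimizing (w_C + w_p)/y_p, so the
    switch happens at w_C* = (w_H y_F - w_F y_H) / (y_H - y_F).
    """
    return (w_H * y_F - w_F * y_H) / (y_H - y_F)


@dataclass
class TwoPathwayToy:
    model: MetabolicModel
    w_R: float
    phi_max: float
    w_H: float
    w_F: float
    y_H: float
    y_F: float
    w_c_star: float

    def weights(self, w_C: float) -> CafbaWeights:
        return CafbaWeights(
            w_C=w_C,
            w_R=self.w_R,
            phi_max=self.phi_max,
            w={"PH": self.w_H, "PF": self.w_F},
            provenance="two-pathway toy",
        )

    def lambda_star(self, w_C: float) -> float:
        return max(
            chain_lambda(self.phi_max, self.y_H, w_C, [self.w_H], self.w_R),
            chain_lambda(self.phi_max, self.y_F, w_C, [self.w_F], self.w_R),
        )


def make_two_pathway(
    y_H: float = 1.0,
    y_F: float = 0.5,
    w_H: float = 0.3,
    w_F: float = 0.05,
    w_R: float = 0.2,
    phi_max: float = 0.5,
) -> TwoPathwayToy:
    """Two parallel routes from intake to biomass.

    Route H has the higher yield but the higher proteome cost per unit
    flux (the respiration analogue); route F is cheap but wasteful (the
    fermentation analogue).  Requires ``y_F < y_H`` and ``w_F < w_H``.
    """
    if not (y_F < y_H and w_F < w_H):
        raise ValueError("expected y_F < y_H and w_F < w_H")
    metabolites = ["glc_e", "m_c", "b_c"]
    compartments = {"glc_e": "e", "m_c": "c", "b_c": "c"}
    reactions = [
        ("EX_glc", {"glc_e": -1.0}, -BIG, BIG),
        ("UPT", {"glc_e": -1.0, "m_c": 1.0}, 0.0, BIG),
        ("PH", {"m_c": -1.0, "b_c": y_H}, 0.0, BIG),
        ("PF", {"m_c": -1.0, "b_c": y_F}, 0.0, BIG),
        ("BIOMASS", {"b_c": -1.0}, 0.0, BIG),
    ]
    model = _assemble(
        metabolites,
        reactions,
        biomass="BIOMASS",
        carbon_source="EX_glc",
        carbon_intake=["UPT"],
        compartments=compartments,
    )
    return TwoPathwayToy(
        model=model,
        w_R=w_R,
        phi_max=phi_max,
        w_H=w_H,
        w_F=w_F,
        y_H=y_H,
        y_F=y_F,
        w_c_star=two_pathway_crossover(y_H, y_F, w_H, w_F),
    )


def make_loop_toy(
    w_R: float = 0.2, phi_max: float = 0.5
) -> Tuple[MetabolicModel, CafbaWeights]:
    """Linear chain plus a reversible futile transport loop A<->B.

    The loop (two antiparallel unweighted transports between
    compartments) can carry arbitrary circulating flux without
    affecting growth; it exercises loop suppression via epsilon
    weights and parsimonious flux minimization.
    """
    metabolites = ["glc_e", "a_c", "a_p", "b_x"]
    compartments = {"glc_e": "e", "a_c": "c", "a_p": "p", "b_x": "c"}
    reactions = [
        ("EX_glc", {"glc_e": -1.0}, -BIG, BIG),
        ("UPT", {"glc_e": -1.0, "a_c": 1.0}, 0.0, BIG),
        ("E1", {"a_c": -1.0, "b_x": 1.0}, 0.0, BIG),
        ("BIOMASS", {"b_x": -1.0}, 0.0, BIG),
        ("T1", {"a_c": -1.0, "a_p": 1.0}, -BIG, BIG),
        ("T2", {"a_p": -1.0, "a_c": 1.0}, -BIG, BIG),
    ]
    model = _assemble(
        metabolites,
        reactions,
        biomass="BIOMASS",
        carbon_source="EX_glc",
        carbon_intake=["UPT"],
        compartments=compartments,
    )
    weights = CafbaWeights(
        w_C=0.1,
        w_R=w_R,
        phi_max=phi_max,
        w={"E1": 0.1},
        provenance="loop toy",
    )
    return model, weights


def make_random_toy(
    seed: int, size: int = 12, reversible_fraction: float = 0.4
) -> Tuple[MetabolicModel, CafbaWeights]:
    """Seeded random connected network with integer stoichiometries.

    A backbone chain guarantees a path from intake to biomass; extra
    reactions with coefficients in {-2..2} add branches, loops and
    reversible steps.  Always feasible at zero flux.  Returns the model
    together with a random weight set (log-uniform over one decade).
    """
    if size > 30:
        raise ValueError("random toys are capped at 30 reactions")
    rng = np.random.default_rng(seed)
    n_chain = int(rng.integers(2, 5))
    n_mets = n_chain + int(rng.integers(1, 4))
    met_ids = ["glc_e"] + [f"m{i}_c" for i in range(n_mets)]
    compartments = {"glc_e": "e", **{f"m{i}_c": "c" for i in range(n_mets)}}
    reactions: List[Tuple[str, Dict[str, float], float, float]] = [
        ("EX_glc", {"glc_e": -1.0}, -BIG, BIG),
        ("UPT", {"glc_e": -1.0, "m0_c": 1.0}, 0.0, BIG),
    ]
    for i in range(n_chain - 1):
        reactions.append(
            (f"C{i}", {f"m{i}_c": -1.0, f"m{i+1}_c": 1.0}, 0.0, BIG)
        )
    biomass_stoich = {f"m{n_chain-1}_c": -1.0}
    # occasionally require a second precursor that extra reactions must supply
    reactions.append(("BIOMASS", biomass_stoich, 0.0, BIG))
    n_extra = max(0, size - len(reactions))
    for k in range(n_extra):
        n_part = int(rng.integers(2, 4))
        mets = rng.choice(n_mets, size=n_part, replace=False)
        stoich: Dict[str, float] = {}
        for idx, m in enumerate(mets):
            coef = int(rng.integers(1, 3))
            stoich[f"m{m}_c"] = float(-coef if idx < max(1, n_part // 2) else coef)
        if all(c < 0 for c in stoich.values()):
            stoich[f"m{mets[-1]}_c"] = abs(stoich[f"m{mets[-1]}_c"])
        rev = rng.random() < reversible_fraction
        reactions.append((f"R{k}", stoich, -BIG if rev else 0.0, BIG))
    model = _assemble(
        met_ids,
        reactions,
        biomass="BIOMASS",
        carbon_source="EX_glc",
        carbon_intake=["UPT"],
        compartments=compartments,
    )
    w = {
        rid: float(10 ** rng.uniform(-1.5, -0.5))
        for rid in model.reactions_in_category("enzymatic")
    }
    weights = CafbaWeights(
        w_C=float(10 ** rng.uniform(-2, -1)),
        w_R=float(rng.uniform(0.1, 0.3)),
        phi_max=0.5,
        w=w,
        provenance=f"random toy seed={seed}",
    )
    return model, weights


def milp_oracle(
    model: MetabolicModel,
    weights: CafbaWeights,
    max_reversible: int = 12,
) -> CafbaSolution:
    """Exact optimum by enumerating flux-direction sign patterns.

    For every sign assignment of the reversible weighted fluxes the
    absolute values become linear (|v| = +/- v) and the restricted
    problem is an ordinary LP; the best pattern is the exact optimum of
    the allocation problem with true absolute values, independent of
    the split-flux reformulation it is used to validate.
    """
    n = model.n_reactions
    w = weights.vector(model)
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    cex = model.index(model.carbon_source) if model.carbon_source else None
    bio = model.index(model.biomass_reaction)

    costed = w > 0
    if cex is not None and weights.w_C > 0:
        costed[cex] = True
    enum_idx = [
        j for j in range(n) if costed[j] and lb[j] < 0 and ub[j] > 0
    ]
    if len(enum_idx) > max_reversible:
        raise ValueError(
            f"{len(enum_idx)} reversible weighted reactions exceed the "
            f"enumeration cap of {max_reversible}"
        )

    best = None
    for pattern in itertools.product((1, -1), repeat=len(enum_idx)):
        lo = lb.copy()
        hi = ub.copy()
        arow = np.zeros(n)
        for j in range(n):
            if not costed[j]:
                continue
            if j in enum_idx:
                s = pattern[enum_idx.index(j)]
                if s > 0:
                    lo[j] = 0.0
                else:
                    hi[j] = 0.0
            else:
                s = 1 if lb[j] >= 0 else (-1 if ub[j] <= 0 else 1)
            arow[j] = s * w[j]
            if cex is not None and j == cex and s < 0:
                arow[j] += -weights.w_C
        arow[bio] += weights.w_R
        c = np.zeros(n)
        c[bio] = -1.0
        res = linprog(
            c,
            A_ub=arow[None, :],
            b_ub=[weights.phi_max],
            A_eq=model.S,
            b_eq=np.zeros(model.n_metabolites),
            bounds=np.column_stack([lo, hi]),
            method="highs",
        options=LP_OPTIONS,
        )
        if res.status != 0:
            continue
        lam = -res.fun
        if best is None or lam > best[0] + 1e-12:
            best = (lam, res.x)
    if best is None:
        return CafbaSolution(
            fluxes={},
            growth_rate=float("nan"),
            sector_fractions={"C": np.nan, "E": np.nan, "R": np.nan},
            constraint_slack=float("nan"),
            status="infeasible",
            weights_used=weights,
        )
    lam, v = best
    v_C = 0.0
    if cex is not None:
        v_C = max(0.0, -float(v[cex]))
    fractions = _sector_fractions(model, weights, v, lam, v_C)
    return CafbaSolution(
        fluxes=dict(zip(model.reaction_ids, v.tolist())),
        growth_rate=float(lam),
        sector_fractions=fractions,
        constraint_slack=float(weights.phi_max - sum(fractions.values())),
        status="optimal",
        carbon_intake_flux=v_C,
        weights_used=weights,
        objective_reaction=model.biomass_reaction,
    )
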