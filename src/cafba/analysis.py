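"""Reference pFBA solutions, flux-overlap statistics, acetate-onset fits
and growth yields.

These are the statistics used to characterize how allocation-limited
solutions differ from pure yield-maximizing FBA: the overlap q_R
measures per-reaction agreement between flux vectors, the onset fit
captures the linear rise of acetate secretion above a threshold growth
rate, and the growth yield is grams of biomass per gram of substrate
consumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .core import LP_OPTIONS
from .model import MetabolicModel

#: molecular weight of glucose, g/mmol
MU_GLUCOSE = 0.18

#: conversion for literature secretion rates: 1 mM/OD600/h = 2 mmol/gDW/h
MMOL_PER_GDW_PER_MM_OD600 = 2.0


class AnalysisError(ValueError):
    pass


# -- parsimonious FBA ----------------------------------------------------


def solve_pfba(
    model: MetabolicModel,
    intake_bound: float,
    carbon_source: Optional[str] = None,
) -> Tuple[Dict[str, float], float]:
    """Two-stage parsimonious FBA at a fixed carbon intake bound.

    Stage 1 maximizes the biomass flux with the carbon-source uptake
    limited to ``intake_bound``; stage 2 fixes the optimum and
    minimizes the total absolute flux over a fully split LP, removing
    futile cycles.  Returns (net fluxes, growth rate).
    """
    if intake_bound <= 0:
        raise AnalysisError("intake bound must be positive")
    cex_id = carbon_source or model.carbon_source
    if cex_id is None:
        raise AnalysisError("no carbon source designated")
    cex = model.index(cex_id)
    bio = model.index(model.biomass_reaction)
    n = model.n_reactions

    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    lb[cex] = -float(intake_bound)

    c = np.zeros(n)
    c[bio] = -1.0
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=LP_OPTIONS,
    )
    if res.status != 0:
        raise AnalysisError(f"FBA stage infeasible (status {res.status})")
    lam = -res.fun

    # stage 2: split all reversible fluxes, fix growth, min sum(v+ + v-)
    split = [j for j in range(n) if lb[j] < 0]
    ns = len(split)
    A_eq = sp.hstack([model.S, -model.S[:, split]], format="csc")
    is_split = np.zeros(n, dtype=bool)
    is_split[split] = True
    lo = np.concatenate(
        [np.where(is_split, 0.0, lb), np.maximum(-ub[split], 0.0)]
    )
    hi = np.concatenate(
        [np.where(is_split, np.maximum(ub, 0.0), ub), -lb[split]]
    )
    lo[bio] = hi[bio] = lam
    c2 = np.ones(n + ns)
    res2 = linprog(
        c2,
        A_eq=A_eq,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([lo, hi]),
        method="highs",
        options=LP_OPTIONS,
    )
    if res2.status != 0:
        # tiny numerical slack on the fixed growth rate
        lo[bio] = lam * (1 - 1e-9)
        res2 = linprog(
            c2,
            A_eq=A_eq,
            b_eq=np.zeros(model.n_metabolites),
            bounds=np.column_stack([lo, hi]),
            method="highs",
            options=LP_OPTIONS,
        )
        if res2.status != 0:
            raise AnalysisError("pFBA minimization stage failed")
    v = res2.x[:n].copy()
    v[split] -= res2.x[n:]
    return dict(zip(model.reaction_ids, v.tolist())), float(lam)


def pfba_curve(
    model: MetabolicModel,
    intake_bounds: Sequence[float],
    carbon_source: Optional[str] = None,
) -> List[Tuple[float, Dict[str, float]]]:
    """pFBA flux vectors over a series of intake bounds, sorted by rate."""
    curve = []
    for b in intake_bounds:
        z, lam = solve_pfba(model, b, carbon_source)
        curve.append((lam, z))
    curve.sort(key=lambda t: t[0])
    return curve


# -- overlap -------------------------------------------------------------


def overlap(
    cafba_solutions: Iterable[Mapping[str, float]],
    z: Mapping[str, float],
    reaction_set: Sequence[str],
) -> float:
    """Similarity q_R between solution fluxes and a reference vector.

    Per reaction the term is 2 v z / (v^2 + z^2): +1 for identical
    fluxes, -1 for opposite fluxes.  Both fluxes exactly zero also
    counts as perfect agreement (+1).  Terms are averaged over the
    supplied solutions first, then over the reaction set; the result
    lies in [-1, 1].
    """
    reaction_set = list(reaction_set)
    if not reaction_set:
        raise AnalysisError("empty reaction set")
    sols = list(cafba_solutions)
    if not sols:
        raise AnalysisError("no solutions supplied")
    per_reaction = np.zeros(len(reaction_set))
    for sol in sols:
        for i, rid in enumerate(reaction_set):
            v = sol[rid]
            zi = z[rid]
            denom = v * v + zi * zi
            per_reaction[i] += 1.0 if denom == 0 else 2.0 * v * zi / denom
    return float(per_reaction.mean() / len(sols))


def interpolate_reference(
    z_curve: Sequence[Tuple[float, Mapping[str, float]]],
    lambda_query: float,
) -> Dict[str, float]:
    """Component-wise linear interpolation of a flux curve in growth rate.

    ``z_curve`` is a list of (lambda, flux vector) knots; queries
    outside the knot range raise instead of extrapolating.
    """
    knots = sorted(z_curve, key=lambda t: t[0])
    lams = [t[0] for t in knots]
    if not lams:
        raise AnalysisError("empty reference curve")
    if lambda_query < lams[0] - 1e-12 or lambda_query > lams[-1] + 1e-12:
        raise AnalysisError(
            f"query {lambda_query:g} outside reference range "
            f"[{lams[0]:g}, {lams[-1]:g}]"
        )
    j = int(np.searchsorted(lams, lambda_query))
    if j == 0:
        return dict(knots[0][1])
    if j >= len(lams):
        return dict(knots[-1][1])
    lo_l, lo_z = knots[j - 1]
    hi_l, hi_z = knots[j]
    if hi_l == lo_l:
        return dict(lo_z)
    t = (lambda_query - lo_l) / (hi_l - lo_l)
    return {
        rid: (1 - t) * lo_z[rid] + t * hi_z[rid] for rid in lo_z
    }


# -- acetate onset -------------------------------------------------------


@dataclass
class OnsetFit:
    """Linear overflow-onset fit v_ac = s (lambda - lambda_ac)."""

    slope: float  # s, mmol/gDW
    onset: float  # lambda_ac, 1/h
    slope_se: float
    onset_se: float
    n_points: int
    activity_threshold: float
    residual_std: float
    fit_range: Tuple[float, float]


def fit_acetate_onset(
    points: Sequence[Tuple[float, float]],
    activity_threshold: float = 1.0,
) -> OnsetFit:
    """Fit the overflow line over the actively secreting regime.

    Only points with secretion above ``activity_threshold`` (mmol/gDW/h)
    enter the ordinary-least-squares fit of v_ac on lambda; the onset is
    the extrapolated root lambda_ac = -intercept/slope, with standard
    errors propagated from the OLS covariance (delta method for the
    onset).
    """
    pts = [(float(l), float(v)) for l, v in points]
    active = [(l, v) for l, v in pts if v > activity_threshold]
    if len(active) < 3:
        raise AnalysisError(
            f"need >= 3 points above threshold {activity_threshold:g}, "
            f"got {len(active)}"
        )
    lam = np.array([l for l, _ in active])
    vac = np.array([v for _, v in active])
    X = np.column_stack([np.ones_like(lam), lam])
    beta, res_ss, *_ = np.linalg.lstsq(X, vac, rcond=None)
    b, s = float(beta[0]), float(beta[1])
    resid = vac - X @ beta
    dof = max(1, len(active) - 2)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    var_b, var_s, cov_bs = cov[0, 0], cov[1, 1], cov[0, 1]
    if s == 0:
        raise AnalysisError("degenerate fit: zero slope")
    onset = -b / s
    # delta method: grad of -b/s is (-1/s, b/s^2)
    var_onset = (
        var_b / s**2 + (b**2 / s**4) * var_s - 2 * (b / s**3) * cov_bs
    )
    return OnsetFit(
        slope=s,
        onset=onset,
        slope_se=float(np.sqrt(max(var_s, 0.0))),
        onset_se=float(np.sqrt(max(var_onset, 0.0))),
        n_points=len(active),
        activity_threshold=activity_threshold,
        residual_std=float(np.sqrt(sigma2)),
        fit_range=(float(lam.min()), float(lam.max())),
    )


# -- growth yield --------------------------------------------------------


def growth_yield_from_rates(
    growth_rate: float, intake: float, mu_substrate: float = MU_GLUCOSE
) -> float:
    """Dimensionless yield: lambda / (v_intake * mu_substrate)."""
    if intake <= 0:
        raise AnalysisError("substrate intake must be positive")
    return growth_rate / (intake * mu_substrate)


def growth_yield(solution, mu_substrate: float = MU_GLUCOSE) -> float:
    """Growth yield of an allocation solution (g biomass / g substrate)."""
    return growth_yield_from_rates(
        solution.growth_rate, solution.carbon_intake_flux, mu_substrate
    )
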