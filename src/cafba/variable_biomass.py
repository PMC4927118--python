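"""Growth-rate-dependent biomass composition and the self-consistent solver.

Cell composition (RNA/protein/lipid ratios, growth-associated ATP)
changes with the growth rate, so the biomass column of the
stoichiometric matrix is in general a function of lambda.  The energy
demand follows v_ATP = v_ATPM + beta_ATP * lambda: the maintenance part
v_ATPM is the lower bound of the ATP-maintenance reaction, while the
growth-associated part beta_ATP is folded into the biomass reaction's
ATP-hydrolysis coefficients (per unit biomass, so the lambda scaling is
automatic).

The self-consistent optimum is found by fixed-point iteration: solve
the LP at the current composition, update the composition to the new
optimal growth rate, repeat until the growth rate stops moving.  The
composition enters the LP only through coefficients, so each iterate is
an ordinary LP and convergence is typically reached in a handful of
steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import CafbaSolution, CafbaWeights, solve_cafba
from .model import MetabolicModel

#: ATP hydrolysis stoichiometry (ATP + H2O -> ADP + Pi + H), cytosolic
#: BiGG identifiers; override for models with other naming schemes.
DEFAULT_ATP_HYDROLYSIS: Dict[str, float] = {
    "atp_c": -1.0,
    "h2o_c": -1.0,
    "adp_c": 1.0,
    "pi_c": 1.0,
    "h_c": 1.0,
}

#: growth-associated ATP demand of the iJR904 reconstruction,
#: mmol ATP per gram dry weight
BETA_ATP_IJR904 = 45.5608


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: List[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class BiomassFunction:
    """lambda-dependent biomass coefficients plus the ATP demand terms.

    ``coefficient_fn`` maps a growth rate to the biomass column
    (mmol per gram dry weight, negative for consumed species).  The
    growth-associated ATP demand ``beta_ATP`` is added on top through
    ``atp_hydrolysis`` stoichiometry; ``v_ATPM`` is applied as the
    maintenance reaction's lower bound.
    """

    coefficient_fn: Callable[[float], Dict[str, float]]
    v_ATPM: float = 0.0
    beta_ATP: float = 0.0
    atp_hydrolysis: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATP_HYDROLYSIS)
    )
    lambda_domain: Tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.v_ATPM < 0 or self.beta_ATP < 0:
            raise ValueError("ATP demands must be non-negative")

    # -- constructors ----------------------------------------------------

    @classmethod
    def constant(
        cls,
        coefficients: Mapping[str, float],
        v_ATPM: float = 0.0,
        beta_ATP: float = 0.0,
        **kwargs,
    ) -> "BiomassFunction":
        coefs = dict(coefficients)
        return cls(
            coefficient_fn=lambda lam: dict(coefs),
            v_ATPM=v_ATPM,
            beta_ATP=beta_ATP,
            **kwargs,
        )

    @classmethod
    def from_model(
        cls,
        model: MetabolicModel,
        beta_ATP: float = 0.0,
        beta_ATP_reference: float = 0.0,
        v_ATPM: Optional[float] = None,
        atp_hydrolysis: Optional[Mapping[str, float]] = None,
    ) -> "BiomassFunction":
        """Constant composition from the model's own biomass column.

        ``beta_ATP - beta_ATP_reference`` is the *extra* growth-associated
        ATP demand added to the column (the model's default demand,
        ``beta_ATP_reference``, is already part of its coefficients), so
        passing equal values reproduces the model untouched.
        """
        coefs = model.biomass_column()
        if v_ATPM is None:
            v_ATPM = 0.0
            if model.maintenance_reaction is not None:
                v_ATPM = float(
                    model.lower_bounds[model.index(model.maintenance_reaction)]
                )
        return cls(
            coefficient_fn=lambda lam, _c=dict(coefs): dict(_c),
            v_ATPM=max(v_ATPM, 0.0),
            beta_ATP=max(beta_ATP - beta_ATP_reference, 0.0),
            atp_hydrolysis=dict(atp_hydrolysis or DEFAULT_ATP_HYDROLYSIS),
        )

    @classmethod
    def piecewise_linear(
        cls,
        knots: Sequence[Tuple[float, Mapping[str, float]]],
        v_ATPM: float = 0.0,
        beta_ATP: float = 0.0,
        **kwargs,
    ) -> "BiomassFunction":
        """Composition interpolated linearly between lambda knots."""
        knots = sorted(((float(l), dict(c)) for l, c in knots), key=lambda t: t[0])
        if not knots:
            raise ValueError("need at least one knot")
        lams = np.array([l for l, _ in knots])
        mets = sorted({m for _, c in knots for m in c})
        table = np.array([[c.get(m, 0.0) for m in mets] for _, c in knots])

        def fn(lam: float) -> Dict[str, float]:
            vals = [
                float(np.interp(lam, lams, table[:, j]))
                for j in range(len(mets))
            ]
            return dict(zip(mets, vals))

        return cls(
            coefficient_fn=fn,
            v_ATPM=v_ATPM,
            beta_ATP=beta_ATP,
            lambda_domain=(float(lams[0]), float(lams[-1])),
            **kwargs,
        )

    @classmethod
    def from_sidecar(cls, path: str | Path) -> "BiomassFunction":
        """Load a knot table from a JSON sidecar.

        Format: ``{"v_ATPM": x, "beta_ATP": y, "knots":
        [{"lambda": l, "coefficients": {met: value}}, ...]}``.
        """
        data = json.loads(Path(path).read_text())
        knots = [
            (k["lambda"], k["coefficients"]) for k in data["knots"]
        ]
        return cls.piecewise_linear(
            knots,
            v_ATPM=float(data.get("v_ATPM", 0.0)),
            beta_ATP=float(data.get("beta_ATP", 0.0)),
        )


def biomass_at(
    lam: float, fn: BiomassFunction
) -> Tuple[Dict[str, float], float]:
    """Biomass coefficients at growth rate ``lam`` and the total ATP demand.

    The returned column includes the growth-associated hydrolysis
    (beta_ATP per unit biomass); the second value is the demand
    v_ATP = v_ATPM + beta_ATP * lam in mmol/gDW/h.
    """
    if lam < 0:
        raise ValueError("growth rate must be non-negative")
    lo, hi = fn.lambda_domain
    if lam < lo - 1e-9 or lam > hi + 1e-9:
        raise ValueError(
            f"lambda {lam:g} outside the composition domain [{lo:g}, {hi:g}]"
        )
    coefs = dict(fn.coefficient_fn(lam))
    if fn.beta_ATP:
        for met, stoich in fn.atp_hydrolysis.items():
            coefs[met] = coefs.get(met, 0.0) + fn.beta_ATP * stoich
    return coefs, fn.v_ATPM + fn.beta_ATP * lam


def solve_variable_biomass(
    model: MetabolicModel,
    weights: CafbaWeights,
    fn: BiomassFunction,
    tol: float = 1e-6,
    max_iter: int = 50,
    lambda0: float = 0.5,
    damping: float = 1.0,
) -> Tuple[CafbaSolution, List[float]]:
    """Self-consistent allocation optimum under lambda-dependent biomass.

    Iterates solve -> composition update from ``lambda0`` until
    ``|lambda_k - lambda_{k-1}| <= tol`` (1/h).  ``damping`` < 1 relaxes
    the composition update (lambda_used = (1-a) previous + a new) if the
    undamped iteration oscillates.  Returns the converged solution and
    the growth-rate trace; raises :class:`ConvergenceError` (carrying
    the trace) if ``max_iter`` is exhausted.
    """
    if not 0 < damping <= 1:
        raise ValueError("damping must be in (0, 1]")
    lam = float(lambda0)
    trace: List[float] = []
    work = model
    if fn.v_ATPM and model.maintenance_reaction is not None:
        work = model.copy()
        j = work.index(work.maintenance_reaction)
        work.lower_bounds[j] = fn.v_ATPM
    solution = None
    for _ in range(max_iter):
        coefs, _demand = biomass_at(lam, fn)
        current = work.with_biomass_column(coefs)
        solution = solve_cafba(current, weights)
        if not solution.optimal:
            raise ConvergenceError(
                f"iterate infeasible at lambda={lam:g} "
                f"(status {solution.status})",
                trace,
            )
        new_lam = solution.growth_rate
        trace.append(new_lam)
        if abs(new_lam - lam) <= tol:
            return solution, trace
        lam = (1.0 - damping) * lam + damping * new_lam
    raise ConvergenceError(
        f"no fixed point within {max_iter} iterations "
        f"(last delta {abs(trace[-1] - lam):g})",
        trace,
    )
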