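"""Homogeneous and heterogeneous E-sector weight sets, and their calibration.

The enzyme weight w_i is the proteome fraction a reaction claims per
unit flux (g h/mmol).  Because genome-wide per-enzyme values are not
known, two schemes are supported:

* homogeneous — every enzymatic reaction gets the same w_E, chosen so
  that the maximal growth rate at w_C = 0 matches an empirical target;
* heterogeneous — each w_i is drawn i.i.d. from a log-uniform density
  p(w) ∝ 1/w on [w_min, w_max], parameterized by its mean <w> and its
  decade width δ = log10(w_max/w_min); the mean is calibrated so that
  the ensemble-average maximal growth rate matches the target.

For the log-uniform density the (mean, δ) -> (w_min, w_max) inversion
is exact: with r = 10**δ, mean = w_min (r - 1)/ln r, hence
w_min = <w> ln r / (r - 1) and w_max = r w_min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .core import CafbaWeights, solve_cafba
from .model import MetabolicModel

#: default tiny weight on transports, suppressing futile transport loops.
#: The value is far below any real enzyme cost (it shifts genome-scale
#: growth rates by < 0.05%) yet large enough that the LP solver resolves
#: the loop fluxes cleanly; weights much smaller than the feasibility
#: tolerance times the flux bounds leave loops, and a sloppy allocation
#: row, behind.
TRANSPORT_EPSILON = 1e-6


class CalibrationError(RuntimeError):
    """Raised when the requested growth-rate target is unreachable."""


@dataclass
class WeightDistributionSpec:
    """Sampling law for heterogeneous enzyme weights.

    ``family`` is one of ``log_uniform`` (density 1/w over ``delta``
    decades), ``log_normal`` (parameterized by the mean and the log10
    standard deviation), or ``homogeneous`` (degenerate).
    """

    family: str = "log_uniform"
    mean_w: float = 8.8e-4
    delta: float = 1.0
    sigma_log: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in {"log_uniform", "log_normal", "homogeneous"}:
            raise ValueError(f"unknown weight family {self.family!r}")
        if self.mean_w <= 0:
            raise ValueError("mean_w must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")

    def bounds(self) -> Tuple[float, float]:
        """(w_min, w_max) of the log-uniform density with mean ``mean_w``."""
        if self.delta == 0:
            return self.mean_w, self.mean_w
        r = 10.0 ** self.delta
        w_min = self.mean_w * np.log(r) / (r - 1.0)
        return w_min, r * w_min

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. weights."""
        if self.family == "homogeneous" or (
            self.family == "log_uniform" and self.delta == 0
        ):
            return np.full(n, self.mean_w)
        if self.family == "log_uniform":
            w_min, w_max = self.bounds()
            u = rng.random(n)
            return w_min * (w_max / w_min) ** u
        # log-normal with matched arithmetic mean:
        # E[w] = exp(mu + s^2/2) with s = sigma_log * ln(10)
        s = self.sigma_log * np.log(10.0)
        mu = np.log(self.mean_w) - 0.5 * s * s
        return np.exp(rng.normal(mu, s, size=n))


def _excluded_weights(
    model: MetabolicModel, transport_epsilon: float
) -> Dict[str, float]:
    w: Dict[str, float] = {}
    if transport_epsilon > 0:
        for rid in model.reactions_in_category("transport"):
            w[rid] = transport_epsilon
    return w


def homogeneous_weights(
    model: MetabolicModel,
    w_E: float,
    w_C: float = 0.0,
    w_R: float = 0.169,
    phi_max: float = 0.484,
    transport_epsilon: float = TRANSPORT_EPSILON,
) -> CafbaWeights:
    """Uniform weight w_E on every enzymatic reaction.

    Transports receive ``transport_epsilon`` (set 0 to disable loop
    suppression); exchanges, the carbon-intake pathway, biomass and
    maintenance carry no weight.
    """
    if w_E < 0:
        raise ValueError("w_E must be non-negative")
    w = _excluded_weights(model, transport_epsilon)
    for rid in model.reactions_in_category("enzymatic"):
        w[rid] = w_E
    return CafbaWeights(
        w_C=w_C,
        w_R=w_R,
        phi_max=phi_max,
        w=w,
        provenance=f"homogeneous w_E={w_E:g}",
    )


def sample_weights(
    model: MetabolicModel,
    spec: WeightDistributionSpec,
    w_C: float = 0.0,
    w_R: float = 0.169,
    phi_max: float = 0.484,
    transport_epsilon: float = TRANSPORT_EPSILON,
    rng: Optional[np.random.Generator] = None,
) -> CafbaWeights:
    """One heterogeneous weight realization (reproducible given the seed).

    Draws are assigned to enzymatic reactions in model order, so the
    same seed always produces the same weight set on the same model.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    enzymatic = model.reactions_in_category("enzymatic")
    draws = spec.sample(len(enzymatic), rng)
    w = _excluded_weights(model, transport_epsilon)
    w.update(zip(enzymatic, draws.tolist()))
    return CafbaWeights(
        w_C=w_C,
        w_R=w_R,
        phi_max=phi_max,
        w=w,
        provenance=(
            f"{spec.family} mean={spec.mean_w:g} delta={spec.delta:g} "
            f"seed={spec.seed}"
        ),
    )


def _bisect(f, lo, hi, tol_x, tol_f, max_iter=60):
    """Bisection for a decreasing function f with f(lo) > 0 > f(hi)."""
    f_lo = f(lo)
    if f_lo <= 0:
        raise CalibrationError(
            "growth-rate target is unreachable even at zero enzyme cost"
        )
    f_hi = f(hi)
    it = 0
    while f_hi > 0:
        lo, f_lo = hi, f_hi
        hi *= 2.0
        f_hi = f(hi)
        it += 1
        if it > 60:
            raise CalibrationError("could not bracket the calibration target")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) <= tol_f:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol_x * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def calibrate_homogeneous(
    model: MetabolicModel,
    lambda_target: float,
    w_C: float = 0.0,
    w_R: float = 0.169,
    phi_max: float = 0.484,
    tol: float = 1e-3,
    initial_w: float = 1e-3,
    transport_epsilon: float = TRANSPORT_EPSILON,
) -> float:
    """Find w_E such that the optimal growth rate equals ``lambda_target``.

    lambda*(w_E) is non-increasing, so bisection on w_E converges; the
    returned value satisfies |lambda* - target| <= tol (in 1/h).
    """

    def gap(w_E: float) -> float:
        sol = solve_cafba(
            model,
            homogeneous_weights(
                model, w_E, w_C, w_R, phi_max, transport_epsilon
            ),
        )
        if not sol.optimal:
            raise CalibrationError(f"solve failed at w_E={w_E:g}: {sol.status}")
        return sol.growth_rate - lambda_target

    return _bisect(gap, 0.0, initial_w, tol_x=1e-12, tol_f=tol)


def calibrate_mean_weight(
    model: MetabolicModel,
    lambda_target: float,
    spec: WeightDistributionSpec,
    n_realizations: int = 500,
    w_C: float = 0.0,
    w_R: float = 0.169,
    phi_max: float = 0.484,
    tol: float = 1e-3,
    initial_w: float = 1e-3,
    transport_epsilon: float = TRANSPORT_EPSILON,
) -> float:
    """Calibrate the mean <w> of the heterogeneous law to a target rate.

    The Monte-Carlo mean growth rate at w_C = 0 is evaluated with
    common random numbers: each realization k keeps the same underlying
    draws across bisection steps (only the scale w_min(<w>) moves), so
    the MC mean is exactly monotone in <w> and bisection terminates.
    """
    enzymatic = model.reactions_in_category("enzymatic")
    n_enz = len(enzymatic)
    base = [
        np.random.default_rng(np.random.SeedSequence([spec.seed, k])).random(
            n_enz
        )
        for k in range(n_realizations)
    ]
    eps = _excluded_weights(model, transport_epsilon)

    def draws_for(mean_w: float, u: np.ndarray) -> np.ndarray:
        if mean_w == 0.0:
            return np.zeros(n_enz)
        if spec.family == "log_uniform" and spec.delta > 0:
            r = 10.0 ** spec.delta
            w_min = mean_w * np.log(r) / (r - 1.0)
            return w_min * r ** u
        if spec.family == "log_normal" and spec.sigma_log > 0:
            from scipy.stats import norm

            sgm = spec.sigma_log * np.log(10.0)
            mu = np.log(mean_w) - 0.5 * sgm * sgm
            return np.exp(mu + sgm * norm.ppf(u))
        return np.full(n_enz, mean_w)

    def mean_lambda(mean_w: float) -> float:
        lams = []
        for u in base:
            draws = draws_for(mean_w, u)
            w = dict(eps)
            w.update(zip(enzymatic, draws.tolist()))
            sol = solve_cafba(
                model,
                CafbaWeights(w_C=w_C, w_R=w_R, phi_max=phi_max, w=w),
            )
            if sol.optimal:
                lams.append(sol.growth_rate)
        if not lams:
            raise CalibrationError("all realizations infeasible")
        return float(np.mean(lams))

    return _bisect(
        lambda m: mean_lambda(m) - lambda_target,
        0.0,
        initial_w,
        tol_x=1e-12,
        tol_f=tol,
    )


def weights_to_frame(model: MetabolicModel, weights: CafbaWeights):
    """Reaction/weight table for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "reaction_id": model.reaction_ids,
            "w": [weights.w.get(r, 0.0) for r in model.reaction_ids],
            "category": [model.category[r] for r in model.reaction_ids],
        }
    )
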