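"""Ensemble averaging over weight realizations and control-parameter sweeps.

Heterogeneous allocation solutions depend on the random weight draw, so
observables are reported as averages over many realizations solved at
the same control parameters (w_C, w_R).  Carbon limitation is swept by
increasing w_C from zero; translational limitation by increasing w_R at
fixed w_C.  Each grid point uses fresh realizations by default, with
per-realization seeds derived deterministically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .analysis import MU_GLUCOSE, growth_yield_from_rates
from .core import CafbaWeights, solve_cafba
from .model import MetabolicModel
from .weights import WeightDistributionSpec, sample_weights

#: conventional reporter reactions for E. coli overflow analyses: TCA flux
#: is represented by alpha-ketoglutarate dehydrogenase, the glyoxylate
#: shunt by malate synthase and the Entner-Doudoroff pathway by
#: 6-phosphogluconate dehydratase, plus the relevant exchanges.
DEFAULT_REPORTERS: Dict[str, str] = {
    "glucose_intake": "EX_glc__D_e",
    "acetate": "EX_ac_e",
    "co2": "EX_co2_e",
    "tca": "AKGDH",
    "glyoxylate_shunt": "MALS",
    "ed_pathway": "EDD",
}

_QUANTITIES = (
    "growth_rate",
    "acetate",
    "co2",
    "glucose_intake",
    "tca",
    "glyoxylate_shunt",
    "ed_pathway",
    "dphi_C",
    "dphi_E",
    "dphi_R",
    "slack",
    "yield",
)


@dataclass
class EnsembleSummary:
    """Mean/dispersion of ensemble observables at one (w_C, w_R) point."""

    w_C: float
    w_R: float
    n: int
    n_failed: int
    mean: Dict[str, float]
    std: Dict[str, float]
    se: Dict[str, float]
    records: Optional["pandas.DataFrame"] = None  # noqa: F821

    def __getitem__(self, key: str) -> float:
        return self.mean[key]


@dataclass
class SweepResult:
    """Ordered ensemble summaries along a control-parameter grid."""

    control: str  # "w_C" or "w_R"
    grid: List[float]
    summaries: List[EnsembleSummary]
    reporters: Dict[str, str] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for g, s in zip(self.grid, self.summaries):
            row = {self.control: g, "n": s.n, "n_failed": s.n_failed}
            for q in _QUANTITIES:
                row[f"{q}_mean"] = s.mean.get(q, np.nan)
                row[f"{q}_se"] = s.se.get(q, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def points(self, quantity: str):
        """(mean growth rate, mean quantity) pairs along the grid."""
        return [
            (s.mean["growth_rate"], s.mean.get(quantity, np.nan))
            for s in self.summaries
            if s.n > 0
        ]


def realization_seed(seed: int, k: int) -> np.random.SeedSequence:
    """Deterministic per-realization seed stream."""
    return np.random.SeedSequence([int(seed), int(k)])


def _record(
    model: MetabolicModel,
    sol,
    reporters: Dict[str, str],
    mu_substrate: float,
) -> Dict[str, float]:
    rec: Dict[str, float] = {"growth_rate": sol.growth_rate}
    for name, rid in reporters.items():
        if rid in sol.fluxes:
            val = sol.fluxes[rid]
            if name == "glucose_intake":
                val = -val  # uptake magnitude
            rec[name] = val
        else:
            rec[name] = np.nan
    rec["dphi_C"] = sol.sector_fractions["C"]
    rec["dphi_E"] = sol.sector_fractions["E"]
    rec["dphi_R"] = sol.sector_fractions["R"]
    rec["slack"] = sol.constraint_slack
    intake = rec.get("glucose_intake")
    if intake is None or not np.isfinite(intake) or intake <= 0:
        intake = sol.carbon_intake_flux
    rec["yield"] = (
        growth_yield_from_rates(sol.growth_rate, intake, mu_substrate)
        if intake and intake > 0
        else np.nan
    )
    return rec


def run_ensemble(
    model: MetabolicModel,
    spec: WeightDistributionSpec,
    w_C: float = 0.0,
    w_R: float = 0.169,
    phi_max: float = 0.484,
    n: int = 1000,
    seed: int = 0,
    reporters: Optional[Dict[str, str]] = None,
    mu_substrate: float = MU_GLUCOSE,
    keep_records: bool = True,
) -> EnsembleSummary:
    """Solve ``n`` weight realizations at fixed control parameters.

    Realization ``k`` uses a seed derived from ``(seed, k)``, so results
    are bit-reproducible and individual realizations can be re-created
    in isolation.  Failed solves are excluded from the averages and
    counted in ``n_failed``.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("need at least one realization")
    reps = dict(DEFAULT_REPORTERS if reporters is None else reporters)
    if model.carbon_source is not None:
        reps.setdefault("glucose_intake", model.carbon_source)
        if reps.get("glucose_intake") not in model.reaction_ids:
            reps["glucose_intake"] = model.carbon_source
    records = []
    n_failed = 0
    for k in range(n):
        rng = np.random.default_rng(realization_seed(seed, k))
        weights = sample_weights(
            model, spec, w_C=w_C, w_R=w_R, phi_max=phi_max, rng=rng
        )
        sol = solve_cafba(model, weights)
        if not sol.optimal:
            n_failed += 1
            continue
        records.append(_record(model, sol, reps, mu_substrate))
    if not records:
        raise RuntimeError(
            f"all {n} realizations failed at w_C={w_C:g}, w_R={w_R:g}"
        )
    frame = pd.DataFrame(records)
    mean = frame.mean().to_dict()
    std = frame.std(ddof=1).fillna(0.0).to_dict() if len(frame) > 1 else {
        c: 0.0 for c in frame.columns
    }
    se = {c: std[c] / np.sqrt(len(frame)) for c in std}
    return EnsembleSummary(
        w_C=w_C,
        w_R=w_R,
        n=len(records),
        n_failed=n_failed,
        mean=mean,
        std=std,
        se=se,
        records=frame if keep_records else None,
    )


def _single_summary(
    model: MetabolicModel,
    weights: CafbaWeights,
    reporters: Dict[str, str],
    mu_substrate: float,
) -> EnsembleSummary:
    sol = solve_cafba(model, weights)
    if not sol.optimal:
        return EnsembleSummary(
            w_C=weights.w_C,
            w_R=weights.w_R,
            n=0,
            n_failed=1,
            mean={},
            std={},
            se={},
        )
    rec = _record(model, sol, reporters, mu_substrate)
    return EnsembleSummary(
        w_C=weights.w_C,
        w_R=weights.w_R,
        n=1,
        n_failed=0,
        mean=rec,
        std={k: 0.0 for k in rec},
        se={k: 0.0 for k in rec},
    )


def sweep_wc(
    model: MetabolicModel,
    spec_or_weights: Union[WeightDistributionSpec, CafbaWeights],
    w_C_grid: Sequence[float],
    w_R: float = 0.169,
    phi_max: float = 0.484,
    n: int = 1000,
    seed: int = 0,
    reporters: Optional[Dict[str, str]] = None,
    mu_substrate: float = MU_GLUCOSE,
    fresh_weights: bool = True,
    keep_records: bool = False,
) -> SweepResult:
    """Carbon-limitation sweep: one ensemble (or single solve) per w_C.

    Passing a :class:`CafbaWeights` runs the deterministic homogeneous
    sweep (n = 1 per point, the given weight set with w_C replaced).
    With a distribution spec, each grid point gets fresh realizations
    seeded from ``(seed, point_index)`` unless ``fresh_weights`` is
    False, in which case the same realization seeds recur across the
    grid (common weights for trajectory studies).
    """
    grid = [float(g) for g in w_C_grid]
    if any(g < 0 for g in grid):
        raise ValueError("w_C grid must be non-negative")
    reps = dict(DEFAULT_REPORTERS if reporters is None else reporters)
    summaries = []
    for idx, w_C in enumerate(grid):
        if isinstance(spec_or_weights, CafbaWeights):
            weights = spec_or_weights.replace(w_C=w_C, w_R=w_R, phi_max=phi_max)
            summaries.append(
                _single_summary(model, weights, reps, mu_substrate)
            )
        else:
            point_seed = seed + idx if fresh_weights else seed
            summaries.append(
                run_ensemble(
                    model,
                    spec_or_weights,
                    w_C=w_C,
                    w_R=w_R,
                    phi_max=phi_max,
                    n=n,
                    seed=point_seed,
                    reporters=reps,
                    mu_substrate=mu_substrate,
                    keep_records=keep_records,
                )
            )
    return SweepResult(
        control="w_C", grid=grid, summaries=summaries, reporters=reps
    )


def sweep_wr(
    model: MetabolicModel,
    spec_or_weights: Union[WeightDistributionSpec, CafbaWeights],
    w_R_grid: Sequence[float],
    w_C: float = 1.4e-3,
    phi_max: float = 0.484,
    n: int = 1000,
    seed: int = 0,
    reporters: Optional[Dict[str, str]] = None,
    mu_substrate: float = MU_GLUCOSE,
    fresh_weights: bool = True,
    keep_records: bool = False,
) -> SweepResult:
    """Translational-limitation sweep: increase w_R at fixed w_C.

    The default w_C corresponds to a carbon source with high
    nutritional capacity, for which overflow persists down to slow
    growth as translation is inhibited.
    """
    import warnings

    grid = [float(g) for g in w_R_grid]
    if any(g < 0.169 - 1e-12 for g in grid):
        warnings.warn(
            "w_R grid extends below the unperturbed ribosomal cost "
            "w_R,0 = 0.169 h",
            stacklevel=2,
        )
    reps = dict(DEFAULT_REPORTERS if reporters is None else reporters)
    summaries = []
    for idx, w_R in enumerate(grid):
        if isinstance(spec_or_weights, CafbaWeights):
            weights = spec_or_weights.replace(w_C=w_C, w_R=w_R, phi_max=phi_max)
            summaries.append(
                _single_summary(model, weights, reps, mu_substrate)
            )
        else:
            point_seed = seed + idx if fresh_weights else seed
            summaries.append(
                run_ensemble(
                    model,
                    spec_or_weights,
                    w_C=w_C,
                    w_R=w_R,
                    phi_max=phi_max,
                    n=n,
                    seed=point_seed,
                    reporters=reps,
                    mu_substrate=mu_substrate,
                    keep_records=keep_records,
                )
            )
    return SweepResult(
        control="w_R", grid=grid, summaries=summaries, reporters=reps
    )


def histogram(values: Sequence[float], bins: int = 30):
    """(bin_center, count) table for exported histograms."""
    import pandas as pd

    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin": centers, "count": counts})
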