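"""Metabolic-model container, sector classification and model patches.

Models are read through cobrapy (SBML L2/L3+FBC, COBRA JSON) into a
lightweight array-based container, and every reaction is assigned to
exactly one proteome-sector category:

``enzymatic``
    intracellular enzyme-catalyzed conversions; these carry E-sector
    weights in the allocation constraint.
``transport``
    reactions that move a species between compartments without chemical
    transformation; excluded from the E-sector (optionally given a tiny
    epsilon weight to suppress futile loops).
``exchange``
    boundary reactions exchanging a species with the environment.
``carbon_intake``
    the intake pathway of the designated carbon source; its proteome
    cost is carried entirely by the C-sector coefficient w_C.
``biomass`` / ``maintenance``
    the growth pseudo-reaction and the ATP-maintenance reaction, both
    excluded from the weighted sum.
``zero_cost``
    reactions deliberately excluded from the constraint by override.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import scipy.sparse as sp

CATEGORIES = (
    "enzymatic",
    "transport",
    "exchange",
    "carbon_intake",
    "biomass",
    "maintenance",
    "zero_cost",
)

#: bound used to replace infinities (COBRA convention, mmol/gDW/h)
DEFAULT_BIG_BOUND = 1000.0

_BIOMASS_PATTERN = re.compile(r"biomass|growth", re.IGNORECASE)
_MAINTENANCE_PATTERN = re.compile(r"^ATPM$|maintenance", re.IGNORECASE)


class ModelError(ValueError):
    """Raised for malformed models or invalid sector configuration."""


@dataclass
class MetabolicModel:
    """Stoichiometry, flux bounds and per-reaction sector categories.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Identifier lists; row/column order of ``S``.
    S
        Sparse stoichiometric matrix (metabolites x reactions).
    lower_bounds, upper_bounds
        Flux bounds in mmol/gDW/h (biomass reaction in 1/h).
    biomass_reaction, maintenance_reaction
        Identifiers of the growth pseudo-reaction and of the
        non-growth-associated ATP maintenance reaction (may be ``None``).
    category
        Per-reaction sector label; defaults to all-``enzymatic`` until
        :func:`classify_reactions` is applied.
    """

    metabolite_ids: List[str]
    reaction_ids: List[str]
    S: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    biomass_reaction: str
    maintenance_reaction: Optional[str] = None
    carbon_source: Optional[str] = None
    category: Dict[str, str] = field(default_factory=dict)
    category_source: Dict[str, str] = field(default_factory=dict)
    metabolite_compartments: Dict[str, Optional[str]] = field(default_factory=dict)
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.S.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise ModelError(
                f"S has shape {self.S.shape}, expected "
                f"({len(self.metabolite_ids)}, {len(self.reaction_ids)})"
            )
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = [
                self.reaction_ids[i]
                for i in np.nonzero(self.lower_bounds > self.upper_bounds)[0]
            ]
            raise ModelError(f"lower bound exceeds upper bound for {bad}")
        if self.biomass_reaction not in self.reaction_ids:
            raise ModelError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )
        counts = np.diff(self.S.tocsc().indptr)
        if np.any(counts == 0):
            empty = [self.reaction_ids[i] for i in np.nonzero(counts == 0)[0]]
            raise ModelError(f"reactions with empty stoichiometry: {empty}")
        if not self.category:
            self.category = {r: "enzymatic" for r in self.reaction_ids}
            self.category_source = {r: "default" for r in self.reaction_ids}
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}

    # -- lookups ---------------------------------------------------------

    def index(self, reaction_id: str) -> int:
        try:
            return self._index[reaction_id]
        except KeyError:
            raise ModelError(f"unknown reaction {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self._met_index[metabolite_id]
        except KeyError:
            raise ModelError(f"unknown metabolite {metabolite_id!r}") from None

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def reactions_in_category(self, cat: str) -> List[str]:
        return [r for r in self.reaction_ids if self.category[r] == cat]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            biomass_reaction=self.biomass_reaction,
            maintenance_reaction=self.maintenance_reaction,
            carbon_source=self.carbon_source,
            category=dict(self.category),
            category_source=dict(self.category_source),
            metabolite_compartments=dict(self.metabolite_compartments),
            provenance=list(self.provenance),
        )

    def with_biomass_column(
        self, coefficients: Mapping[str, float]
    ) -> "MetabolicModel":
        """Return a copy whose biomass column is replaced by ``coefficients``."""
        new = self.copy()
        j = new.index(new.biomass_reaction)
        S = new.S.tolil()
        S[:, j] = 0.0
        for met, coef in coefficients.items():
            S[new.metabolite_index(met), j] = coef
        new.S = S.tocsc()
        new.provenance.append("biomass column replaced")
        return new

    def biomass_column(self) -> Dict[str, float]:
        j = self.index(self.biomass_reaction)
        col = self.S.getcol(j).tocoo()
        return {self.metabolite_ids[i]: v for i, v in zip(col.row, col.data)}


@dataclass
class SectorConfig:
    """Sector-classification configuration for one growth condition.

    ``carbon_source`` is the exchange reaction of the limiting carbon
    source; ``carbon_intake_reactions`` list the intake pathway whose
    proteome cost is attributed to w_C (and therefore carry no E-sector
    weight).  ``patches`` are reactions to shut off (bounds set to 0).
    """

    carbon_source: str
    carbon_intake_reactions: List[str] = field(default_factory=list)
    category_overrides: Dict[str, str] = field(default_factory=dict)
    patches: List[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "SectorConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(
            carbon_source=data["carbon_source"],
            carbon_intake_reactions=list(data.get("carbon_intake_reactions", [])),
            category_overrides=dict(data.get("category_overrides", {})),
            patches=list(data.get("patches", [])),
        )


#: Default glucose sector configurations for the shipped/published
#: E. coli reconstructions.  The carbon-intake lists cover the PTS,
#: permease and ABC routes plus hexokinase; the patch shuts off glucose
#: dehydrogenase, which is only active when its PQQ cofactor is supplied.
BUILTIN_SECTOR_CONFIGS: Dict[str, SectorConfig] = {
    "e_coli_core": SectorConfig(
        carbon_source="EX_glc__D_e",
        carbon_intake_reactions=["GLCpts"],
    ),
    "iJO1366": SectorConfig(
        carbon_source="EX_glc__D_e",
        carbon_intake_reactions=["GLCptspp", "GLCabcpp", "GLCt2pp", "HEX1"],
        patches=["GLCDpp"],
    ),
    "iAF1260": SectorConfig(
        carbon_source="EX_glc__D_e",
        carbon_intake_reactions=["GLCptspp", "GLCabcpp", "GLCt2pp", "HEX1"],
        patches=["GLCDpp"],
    ),
    "iJR904": SectorConfig(
        carbon_source="EX_glc__D_e",
        carbon_intake_reactions=["GLCpts", "GLCabc", "GLCt2", "HEX1"],
        patches=["GLCD"],
    ),
}


# -- loading -------------------------------------------------------------


def _from_cobra(cobra_model, big_bound: float) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    biomass = None
    for rxn in cobra_model.reactions:
        if rxn.objective_coefficient:
            biomass = rxn.id
            break
    if biomass is None:
        for rxn in cobra_model.reactions:
            if _BIOMASS_PATTERN.search(rxn.id) or _BIOMASS_PATTERN.search(
                rxn.name or ""
            ):
                biomass = rxn.id
                break
    if biomass is None:
        raise ModelError(
            "model has no biomass reaction (no objective flag and no "
            "identifier matching 'biomass'/'growth')"
        )
    maintenance = None
    for rxn in cobra_model.reactions:
        if _MAINTENANCE_PATTERN.search(rxn.id):
            maintenance = rxn.id
            break

    S = sp.csc_matrix(create_stoichiometric_matrix(cobra_model, array_type="lil"))
    lb = np.array([r.lower_bound for r in cobra_model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cobra_model.reactions], dtype=float)
    lb = np.clip(np.nan_to_num(lb, neginf=-big_bound), -big_bound, big_bound)
    ub = np.clip(np.nan_to_num(ub, posinf=big_bound), -big_bound, big_bound)

    compartments = {m.id: (m.compartment or None) for m in cobra_model.metabolites}
    return MetabolicModel(
        metabolite_ids=[m.id for m in cobra_model.metabolites],
        reaction_ids=[r.id for r in cobra_model.reactions],
        S=S,
        lower_bounds=lb,
        upper_bounds=ub,
        biomass_reaction=biomass,
        maintenance_reaction=maintenance,
        metabolite_compartments=compartments,
        provenance=[f"loaded from cobra model {cobra_model.id or '<unnamed>'}"],
    )


def load_model(
    path: str | Path,
    format: Optional[str] = None,
    big_bound: float = DEFAULT_BIG_BOUND,
) -> MetabolicModel:
    """Read an SBML (L2/L3, with or without FBC) or COBRA-JSON model.

    All reactions start in category ``enzymatic``; run
    :func:`classify_reactions` to assign sectors.  Infinite bounds are
    replaced by ``+/- big_bound``.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise ModelError(f"model file not found: {path}")
    fmt = format
    if fmt is None:
        fmt = "json" if path.suffix == ".json" else "sbml"
    try:
        if fmt == "json":
            cm = cobra.io.load_json_model(str(path))
        elif fmt == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelError(f"unknown model format {fmt!r}")
    except ModelError:
        raise
    except Exception as exc:  # pragma: no cover - error text varies by parser
        raise ModelError(f"could not parse {path} as {fmt}: {exc}") from exc
    model = _from_cobra(cm, big_bound)
    model.provenance[0] = f"loaded {path} ({fmt})"
    return model


def load_builtin(name: str, big_bound: float = DEFAULT_BIG_BOUND) -> MetabolicModel:
    """Load one of the SBML models shipped with cobrapy by name.

    ``"e_coli_core"`` (alias ``"textbook"``) and ``"iJO1366"`` are the
    ones of interest here; both load without any network access.
    """
    import cobra

    fname = {"e_coli_core": "textbook"}.get(name, name)
    path = Path(cobra.__file__).parent / "data" / f"{fname}.xml.gz"
    if not path.exists():
        raise ModelError(f"no bundled model named {name!r} ({path} missing)")
    import cobra.io

    model = _from_cobra(cobra.io.read_sbml_model(str(path)), big_bound)
    model.provenance[0] = f"loaded bundled model {name}"
    return model


def to_cobra(model: MetabolicModel):
    """Convert back to a cobrapy model (for writing standard formats)."""
    import cobra

    cm = cobra.Model("cafba_model")
    mets = {}
    for mid in model.metabolite_ids:
        met = cobra.Metabolite(
            mid, compartment=model.metabolite_compartments.get(mid) or "c"
        )
        mets[mid] = met
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bounds[j])
        rxn.upper_bound = float(model.upper_bounds[j])
        rxns.append(rxn)
    cm.add_reactions(rxns)
    Scoo = model.S.tocoo()
    for i, j, v in zip(Scoo.row, Scoo.col, Scoo.data):
        cm.reactions[j].add_metabolites(
            {mets[model.metabolite_ids[i]]: float(v)}
        )
    cm.objective = cm.reactions.get_by_id(model.biomass_reaction)
    return cm


def write_json(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as COBRA-style JSON (categories in a sidecar key)."""
    import cobra.io

    cobra.io.save_json_model(to_cobra(model), str(path))


# -- classification ------------------------------------------------------


def _base_species(model: MetabolicModel, metabolite_id: str) -> str:
    comp = model.metabolite_compartments.get(metabolite_id)
    if comp and metabolite_id.endswith("_" + comp):
        return metabolite_id[: -(len(comp) + 1)]
    # fall back to stripping a short trailing compartment tag
    return re.sub(r"_[a-z][a-z0-9]?$", "", metabolite_id)


def _is_transport(model: MetabolicModel, j: int) -> bool:
    col = model.S.getcol(j).tocoo()
    if len(col.row) < 2:
        return False
    comps = {
        model.metabolite_compartments.get(model.metabolite_ids[i])
        for i in col.row
    }
    if len(comps) < 2:
        return False
    lhs = {
        _base_species(model, model.metabolite_ids[i])
        for i, v in zip(col.row, col.data)
        if v < 0
    }
    rhs = {
        _base_species(model, model.metabolite_ids[i])
        for i, v in zip(col.row, col.data)
        if v > 0
    }
    # pure translocation: same base species on both sides (protons and
    # co-transported ions included); chemical transformation otherwise
    return lhs == rhs


def classify_reactions(
    model: MetabolicModel, config: SectorConfig
) -> MetabolicModel:
    """Assign every reaction to exactly one sector category.

    Exchanges are single-metabolite (boundary) columns; transports move
    the same base species across compartments; the configured carbon
    intake pathway, biomass and maintenance reactions are excluded from
    the E-sector; everything else is ``enzymatic``.  Explicit overrides
    are applied last.  The operation is idempotent.
    """
    for rid in list(config.category_overrides) + list(
        config.carbon_intake_reactions
    ):
        if rid not in model._index:
            raise ModelError(f"sector config references unknown reaction {rid!r}")
    if config.carbon_source not in model._index:
        raise ModelError(
            f"carbon source {config.carbon_source!r} not in model"
        )
    for cat in config.category_overrides.values():
        if cat not in CATEGORIES:
            raise ModelError(f"unknown category {cat!r} in overrides")

    new = model.copy()
    nnz = np.diff(new.S.indptr)
    intake = set(config.carbon_intake_reactions)
    for j, rid in enumerate(new.reaction_ids):
        if rid == new.biomass_reaction:
            cat = "biomass"
        elif rid == new.maintenance_reaction:
            cat = "maintenance"
        elif rid in intake:
            cat = "carbon_intake"
        elif nnz[j] == 1:
            cat = "exchange"
        elif _is_transport(new, j):
            cat = "transport"
        else:
            cat = "enzymatic"
        new.category[rid] = cat
        new.category_source[rid] = "default"
    if new.category[config.carbon_source] != "exchange":
        raise ModelError(
            f"carbon source {config.carbon_source!r} is not an exchange reaction"
        )
    for rid, cat in config.category_overrides.items():
        new.category[rid] = cat
        new.category_source[rid] = "override"
        new.provenance.append(f"category override: {rid} -> {cat}")
    new.carbon_source = config.carbon_source
    new.provenance.append(
        f"classified with carbon source {config.carbon_source}"
    )
    return new


def apply_patches(model: MetabolicModel, config: SectorConfig) -> MetabolicModel:
    """Shut off the configured patch reactions (bounds set to 0, 0)."""
    new = model.copy()
    for rid in config.patches:
        j = new.index(rid)
        new.lower_bounds[j] = 0.0
        new.upper_bounds[j] = 0.0
        new.category_source[rid] = "patch"
        new.provenance.append(f"patched off reaction {rid}")
    return new


def prepare_model(
    model: MetabolicModel,
    config: SectorConfig,
    open_carbon_exchange: bool = True,
    big_bound: float = DEFAULT_BIG_BOUND,
) -> MetabolicModel:
    """Classify, patch, and open the carbon-source exchange for uptake.

    With w_C as the control parameter the intake flux must not be capped
    by the exchange bound, so the designated carbon exchange is opened to
    ``-big_bound`` unless ``open_carbon_exchange`` is False.
    """
    new = apply_patches(classify_reactions(model, config), config)
    if open_carbon_exchange:
        j = new.index(config.carbon_source)
        new.lower_bounds[j] = -big_bound
        new.provenance.append(
            f"opened carbon exchange {config.carbon_source} to {-big_bound}"
        )
    return new


def category_report(model: MetabolicModel) -> "pandas.DataFrame":  # noqa: F821
    """Per-reaction category table (reaction_id, category, source)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "reaction_id": model.reaction_ids,
            "category": [model.category[r] for r in model.reaction_ids],
            "source": [
                model.category_source.get(r, "default")
                for r in model.reaction_ids
            ],
        }
    )


def write_category_report(model: MetabolicModel, path: str | Path) -> None:
    category_report(model).to_csv(path, sep="\t", index=False)
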