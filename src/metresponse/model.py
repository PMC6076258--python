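"""Constraint-based metabolic models with gene-protein-reaction rules.

The in-memory containers here are deliberately small: a model is a list of
metabolites, a list of reactions with stoichiometry/bounds/GPR, and a gene
namespace.  SBML Level 3 + FBC interchange is delegated to cobrapy; the
native on-disk dialect is a pair of TSV files (reactions, metabolites)
standing in for spreadsheet model distributions.

Sign convention for exchange reactions: each is written ``M ->`` so that
positive flux secretes the metabolite into the environment (plasma) and
negative flux takes it up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

from .gpr import GprTree, parse_gpr, serialize_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelFormatError",
    "ModelValidationError",
    "ValidationReport",
    "load_model_tabular",
    "write_model_tabular",
    "load_model_sbml",
    "write_model_sbml",
    "build_stoichiometric_matrix",
    "add_exchange_reaction",
    "validate_model",
    "DEFAULT_UB",
]

DEFAULT_UB = 1000.0


class ModelFormatError(ValueError):
    """Malformed model file: missing columns, bad stoichiometry strings."""


class ModelValidationError(ValueError):
    """Model violates a structural invariant (duplicate ids, lb > ub, ...)."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    kegg_id: Optional[str] = None


@dataclass(frozen=True)
class Reaction:
    """A reaction: signed stoichiometry over metabolite ids, flux bounds,
    optional GPR tree and subsystem label."""

    id: str
    stoich: dict[str, float]
    lb: float = -DEFAULT_UB
    ub: float = DEFAULT_UB
    gpr: Optional[GprTree] = None
    subsystem: Optional[str] = None
    is_exchange: bool = False

    def __post_init__(self):
        if self.lb > self.ub:
            raise ModelValidationError(
                f"reaction {self.id!r}: lb={self.lb} > ub={self.ub}"
            )
        if self.is_exchange and len(self.stoich) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id!r} must touch exactly one "
                f"metabolite, got {len(self.stoich)}"
            )

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub


@dataclass
class MetabolicModel:
    """A stoichiometric model: metabolites, reactions, genes, compartments."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    compartments: set[str] = field(default_factory=set)
    id: str = "model"

    def __post_init__(self):
        self._index()

    def _index(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_for(self, met_id: str) -> Optional[Reaction]:
        """The exchange reaction moving ``met_id`` across the boundary."""
        for r in self.reactions:
            if r.is_exchange and met_id in r.stoich:
                return r
        return None

    def with_reaction_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with the given reactions' bounds replaced."""
        new_reactions = []
        for r in self.reactions:
            if r.id in bounds:
                lb, ub = bounds[r.id]
                new_reactions.append(replace(r, lb=lb, ub=ub))
            else:
                new_reactions.append(r)
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=new_reactions,
            genes=list(self.genes),
            compartments=set(self.compartments),
            id=self.id,
        )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            genes=list(self.genes),
            compartments=set(self.compartments),
            id=self.id,
        )


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = ["reaction_id", "stoichiometry", "lb", "ub", "gpr", "subsystem"]
_METABOLITE_COLUMNS = ["metabolite_id", "name", "compartment", "kegg_id"]


def _parse_stoich(text: str, rxn_id: str) -> dict[str, float]:
    """Parse ``"-1 A_c; 1 B_c"`` into {"A_c": -1.0, "B_c": 1.0}."""
    stoich: dict[str, float] = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        pieces = part.split()
        if len(pieces) != 2:
            raise ModelFormatError(
                f"reaction {rxn_id!r}: cannot parse stoichiometry term {part!r} "
                "(expected '<coefficient> <metabolite_id>')"
            )
        coef_text, met_id = pieces
        try:
            coef = float(coef_text)
        except ValueError as exc:
            raise ModelFormatError(
                f"reaction {rxn_id!r}: non-numeric coefficient {coef_text!r}"
            ) from exc
        stoich[met_id] = stoich.get(met_id, 0.0) + coef
    if not stoich:
        raise ModelFormatError(f"reaction {rxn_id!r}: empty stoichiometry")
    return stoich


def _format_stoich(stoich: dict[str, float]) -> str:
    return "; ".join(f"{coef:g} {met}" for met, coef in stoich.items())


def load_model_tabular(reactions_path, metabolites_path) -> MetabolicModel:
    """Load a model from the TSV dialect (reactions.tsv + metabolites.tsv).

    Required reaction columns: reaction_id, stoichiometry, lb, ub, gpr,
    subsystem.  Required metabolite columns: metabolite_id, name,
    compartment, kegg_id.  Row order is preserved.  Exchange status is
    inferred: a reaction touching exactly one metabolite is an exchange.
    """
    rxn_df = pd.read_csv(reactions_path, sep="\t", dtype=str, keep_default_na=False)
    met_df = pd.read_csv(metabolites_path, sep="\t", dtype=str, keep_default_na=False)

    for col in _REACTION_COLUMNS:
        if col not in rxn_df.columns:
            raise ModelFormatError(f"reactions table missing column {col!r}")
    for col in _METABOLITE_COLUMNS:
        if col not in met_df.columns:
            raise ModelFormatError(f"metabolites table missing column {col!r}")

    metabolites = []
    for _, row in met_df.iterrows():
        metabolites.append(
            Metabolite(
                id=row["metabolite_id"],
                name=row["name"],
                compartment=row["compartment"],
                kegg_id=row["kegg_id"] or None,
            )
        )

    reactions = []
    genes: list[str] = []
    seen_genes: set[str] = set()
    for idx, row in rxn_df.iterrows():
        rxn_id = row["reaction_id"]
        stoich = _parse_stoich(row["stoichiometry"], rxn_id)
        try:
            gpr = parse_gpr(row["gpr"])
        except ValueError as exc:
            raise ModelFormatError(
                f"reactions table row {idx} ({rxn_id!r}): bad GPR: {exc}"
            ) from exc
        try:
            lb, ub = float(row["lb"]), float(row["ub"])
        except ValueError as exc:
            raise ModelFormatError(
                f"reactions table row {idx} ({rxn_id!r}): non-numeric bounds"
            ) from exc
        reactions.append(
            Reaction(
                id=rxn_id,
                stoich=stoich,
                lb=lb,
                ub=ub,
                gpr=gpr,
                subsystem=row["subsystem"] or None,
                is_exchange=len(stoich) == 1,
            )
        )
        if gpr is not None:
            for g in sorted(gpr.genes()):
                if g not in seen_genes:
                    seen_genes.add(g)
                    genes.append(g)

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        compartments={m.compartment for m in metabolites},
    )
    report = validate_model(model)
    if report.issues:
        raise ModelValidationError(
            "model failed validation: " + "; ".join(report.issues)
        )
    return model


def write_model_tabular(model: MetabolicModel, reactions_path, metabolites_path) -> None:
    """Write the TSV dialect read back by :func:`load_model_tabular`."""
    rxn_rows = [
        {
            "reaction_id": r.id,
            "stoichiometry": _format_stoich(r.stoich),
            "lb": repr(r.lb),
            "ub": repr(r.ub),
            "gpr": serialize_gpr(r.gpr),
            "subsystem": r.subsystem or "",
        }
        for r in model.reactions
    ]
    met_rows = [
        {
            "metabolite_id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "kegg_id": m.kegg_id or "",
        }
        for m in model.metabolites
    ]
    pd.DataFrame(rxn_rows, columns=_REACTION_COLUMNS).to_csv(
        reactions_path, sep="\t", index=False
    )
    pd.DataFrame(met_rows, columns=_METABOLITE_COLUMNS).to_csv(
        metabolites_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment
        )
        for m in model.metabolites
    }
    for m in model.metabolites:
        if m.kegg_id:
            mets[m.id].annotation["kegg.compound"] = m.kegg_id
    cm.add_metabolites(list(mets.values()))
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cr.subsystem = r.subsystem or ""
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
        rule = serialize_gpr(r.gpr)
        if rule:
            cr.gene_reaction_rule = rule
    return cm


def _from_cobra(cm) -> MetabolicModel:
    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            kegg_id=(
                m.annotation.get("kegg.compound")
                if isinstance(m.annotation.get("kegg.compound"), str)
                else None
            ),
        )
        for m in cm.metabolites
    ]
    reactions = []
    genes: list[str] = []
    seen: set[str] = set()
    for cr in cm.reactions:
        gpr = parse_gpr(cr.gene_reaction_rule)
        stoich = {m.id: c for m, c in cr.metabolites.items()}
        reactions.append(
            Reaction(
                id=cr.id,
                stoich=stoich,
                lb=cr.lower_bound,
                ub=cr.upper_bound,
                gpr=gpr,
                subsystem=cr.subsystem or None,
                is_exchange=len(stoich) == 1,
            )
        )
        if gpr is not None:
            for g in sorted(gpr.genes()):
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        compartments={m.compartment for m in metabolites},
        id=cm.id or "model",
    )


def load_model_sbml(path) -> MetabolicModel:
    """Read an SBML Level 3 + FBC model (bounds and gene associations)."""
    import logging

    from cobra.io import read_sbml_model

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    logger = logging.getLogger("cobra")
    previous = logger.level
    logger.setLevel(logging.ERROR)  # models need no objective for our use
    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"cannot read SBML from {path}: {exc}") from exc
    finally:
        logger.setLevel(previous)
    return _from_cobra(cm)


def write_model_sbml(model: MetabolicModel, path) -> None:
    """Write SBML Level 3 + FBC readable by :func:`load_model_sbml`."""
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(model: MetabolicModel):
    """Sparse stoichiometric matrix S with index maps.

    Returns ``(S, met_index, rxn_index)`` where ``S[m, r]`` is the signed
    coefficient of metabolite ``m`` in reaction ``r`` (CSR, shape
    n_metabolites x n_reactions).
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    rows, cols, vals = [], [], []
    for r in model.reactions:
        j = rxn_index[r.id]
        for met_id, coef in r.stoich.items():
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(coef)
    S = sparse.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
        dtype=float,
    )
    return S, met_index, rxn_index


def add_exchange_reaction(
    model: MetabolicModel,
    metabolite_id: str,
    lb: float = 0.0,
    ub: float = DEFAULT_UB,
    extracellular_compartments: tuple[str, ...] = ("e", "extracellular", "plasma"),
) -> MetabolicModel:
    """Return a model with an ``EX_<metabolite_id>`` boundary reaction.

    The new reaction is written ``metabolite ->`` (coefficient -1), so
    positive flux secretes.  Idempotent: if the exchange already exists the
    model is returned unchanged.  The metabolite must live in an
    extracellular/plasma compartment; intracellular metabolites need a
    transport step first.
    """
    if not model.has_metabolite(metabolite_id):
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    ex_id = f"EX_{metabolite_id}"
    if model.has_reaction(ex_id):
        return model
    met = model.metabolite(metabolite_id)
    if met.compartment not in extracellular_compartments:
        raise ModelValidationError(
            f"metabolite {metabolite_id!r} is in compartment "
            f"{met.compartment!r}, not extracellular; add a transport "
            "reaction to an extracellular compartment first"
        )
    new = model.copy()
    new.reactions.append(
        Reaction(id=ex_id, stoich={metabolite_id: -1.0}, lb=lb, ub=ub, is_exchange=True)
    )
    new._index()
    return new


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)
    n_exchange_reactions: int = 0

    @property
    def valid(self) -> bool:
        return not self.issues


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Structural checks: duplicate ids, orphan metabolites, GPR genes
    missing from the gene list, inverted bounds, exchange count.

    Report-only: an empty issue list means the model is valid.
    """
    issues: list[str] = []

    met_ids = [m.id for m in model.metabolites]
    if len(set(met_ids)) != len(met_ids):
        issues.append("duplicate metabolite ids")
    rxn_ids = [r.id for r in model.reactions]
    if len(set(rxn_ids)) != len(rxn_ids):
        issues.append("duplicate reaction ids")

    used_mets: set[str] = set()
    gene_set = set(model.genes)
    n_exchange = 0
    for r in model.reactions:
        used_mets |= set(r.stoich)
        if r.lb > r.ub:
            issues.append(f"reaction {r.id}: lb > ub")
        for met_id in r.stoich:
            if met_id not in set(met_ids):
                issues.append(f"reaction {r.id}: unknown metabolite {met_id}")
        if r.gpr is not None:
            missing = r.gpr.genes() - gene_set
            if missing:
                issues.append(
                    f"reaction {r.id}: GPR genes not in gene list: "
                    + ", ".join(sorted(missing))
                )
        if r.is_exchange:
            n_exchange += 1

    for met_id in met_ids:
        if met_id not in used_mets:
            issues.append(f"orphan metabolite {met_id}")

    if n_exchange == 0:
        issues.append("model has no exchange reactions")

    return ValidationReport(issues=issues, n_exchange_reactions=n_exchange)
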