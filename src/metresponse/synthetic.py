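"""Synthetic study generator with known ground truth.

Emulates the statistical shape of an in-vivo liver toxicity study at desk
scale: a small hepatocyte-like network (one substrate uptake hub feeding
several gene-gated linear production routes that share a cofactor loop),
a differential-expression table with planted pathway-level up/down
regulation, replicate-level plasma metabolite abundances whose group
differences either agree or deliberately disagree with the
expression-implied directions, fasting boundary conditions, and a
measured-flux set consistent with the network's true throughput.

Every output is deterministic given the scenario seed, so the full
pipeline (weights -> constraints -> scoring -> concordance) can be tested
end to end with no external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .constraints import BoundaryConditions, MFAFluxSet
from .evaluation import PathwayAnnotation
from .gpr import parse_gpr
from .model import (
    DEFAULT_UB,
    MetabolicModel,
    Metabolite,
    Reaction,
    validate_model,
    write_model_sbml,
    write_model_tabular,
)
from .weights import ExpressionTable

__all__ = [
    "SyntheticScenario",
    "generate_toy_network",
    "default_boundary_conditions",
    "default_mfa_fluxes",
    "pathway_annotation",
    "plant_expression",
    "simulate_abundances",
    "make_fixture_bundle",
]

SUBSTRATE_UPTAKE = 10.0
BASE_LOG2_ABUNDANCE = 10.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth parameters of a synthetic study.

    planted_effects maps pathway name (P1, P2, ...) to a log2
    expression effect applied to all of the pathway's genes;
    metabolite_effect_size is the log2 abundance shift of each perturbed
    pathway's product; concordant_fraction is the fraction of perturbed
    products whose abundance shift agrees in sign with the expression
    effect (the rest are deliberately flipped).  n_replicates is per
    treatment x time cell.
    """

    seed: int = 7
    n_pathways: int = 6
    pathway_size: int = 3
    planted_effects: dict = field(
        default_factory=lambda: {"P1": 2.0, "P2": 2.0, "P3": -2.0, "P4": -2.0}
    )
    metabolite_effect_size: float = 2.0
    concordant_fraction: float = 1.0
    noise_sd_expr: float = 0.2
    noise_sd_abund: float = 0.25
    n_replicates: int = 8
    times: tuple[str, ...] = ("5h", "10h")

    def __post_init__(self):
        if self.n_pathways < 1:
            raise ValueError("scenario needs at least one pathway")
        if self.pathway_size < 1:
            raise ValueError("pathway_size must be >= 1")
        if not (0.0 <= self.concordant_fraction <= 1.0):
            raise ValueError("concordant_fraction must lie in [0, 1]")
        if self.noise_sd_expr < 0 or self.noise_sd_abund < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        unknown = [p for p in self.planted_effects if p not in self.pathway_names]
        if unknown:
            raise ValueError(f"planted effects for unknown pathways: {unknown}")

    @property
    def pathway_names(self) -> list[str]:
        return [f"P{i}" for i in range(1, self.n_pathways + 1)]

    def pathway_genes(self, pathway: str) -> list[str]:
        return [f"g_{pathway}_{j}" for j in range(1, self.pathway_size + 1)]

    def product_id(self, pathway: str) -> str:
        return f"prod_{pathway}_e"

    def product_name(self, pathway: str) -> str:
        return f"product {pathway}"

    def product_kegg(self, pathway: str) -> str:
        return f"C9{int(pathway[1:]):04d}"

    def expression_direction(self, pathway: str) -> str:
        effect = self.planted_effects.get(pathway, 0.0)
        if effect > 0:
            return "increased"
        if effect < 0:
            return "decreased"
        return "unchanged"

    def concordant_products(self) -> dict[str, bool]:
        """Which perturbed pathways' products agree with expression.

        Exactly round(concordant_fraction * n_perturbed) products are
        concordant; the selection is drawn reproducibly from the seed.
        """
        perturbed = sorted(p for p, e in self.planted_effects.items() if e != 0)
        n_conc = int(round(self.concordant_fraction * len(perturbed)))
        rng = np.random.default_rng(self.seed + 1)
        chosen = set(
            rng.choice(perturbed, size=n_conc, replace=False).tolist()
        ) if perturbed else set()
        return {p: (p in chosen) for p in perturbed}


def generate_toy_network(scenario: SyntheticScenario) -> MetabolicModel:
    """Build the hepatocyte-like toy network for a scenario.

    One substrate exchange + transport, a reversible cofactor
    regeneration reaction coupling all routes, and per pathway a chain of
    gene-gated steps ending in a product with its own transport and
    exchange.  Construction is deterministic.
    """
    metabolites = [
        Metabolite("sub_e", name="substrate", compartment="e", kegg_id="C90000"),
        Metabolite("sub_c", name="substrate", compartment="c"),
        Metabolite("cof_red", name="reduced cofactor", compartment="c"),
        Metabolite("cof_ox", name="oxidized cofactor", compartment="c"),
    ]
    reactions = [
        Reaction("EX_sub_e", {"sub_e": -1.0}, lb=-DEFAULT_UB, ub=DEFAULT_UB, is_exchange=True),
        Reaction("T_sub", {"sub_e": -1.0, "sub_c": 1.0}, lb=0.0, ub=DEFAULT_UB),
        Reaction("COF_regen", {"cof_ox": -1.0, "cof_red": 1.0}, lb=-DEFAULT_UB, ub=DEFAULT_UB),
    ]
    genes: list[str] = []

    for pathway in scenario.pathway_names:
        pathway_genes = scenario.pathway_genes(pathway)
        genes.extend(pathway_genes)
        size = scenario.pathway_size
        chain = [f"m_{pathway}_{j}" for j in range(1, size)] + [f"prod_{pathway}_c"]
        for met_id in chain:
            metabolites.append(Metabolite(met_id, name="", compartment="c"))
        metabolites.append(
            Metabolite(
                scenario.product_id(pathway),
                name=scenario.product_name(pathway),
                compartment="e",
                kegg_id=scenario.product_kegg(pathway),
            )
        )
        prev = "sub_c"
        for j, gene in enumerate(pathway_genes, start=1):
            target = chain[j - 1]
            stoich = {prev: -1.0, target: 1.0}
            if j == 1:  # first step consumes the shared cofactor
                stoich.update({"cof_red": -1.0, "cof_ox": 1.0})
            reactions.append(
                Reaction(
                    f"R_{pathway}_{j}",
                    stoich,
                    lb=0.0,
                    ub=DEFAULT_UB,
                    gpr=parse_gpr(gene),
                    subsystem=pathway,
                )
            )
            prev = target
        reactions.append(
            Reaction(
                f"T_prod_{pathway}",
                {f"prod_{pathway}_c": -1.0, scenario.product_id(pathway): 1.0},
                lb=0.0,
                ub=DEFAULT_UB,
            )
        )
        reactions.append(
            Reaction(
                f"EX_{scenario.product_id(pathway)}",
                {scenario.product_id(pathway): -1.0},
                lb=0.0,
                ub=DEFAULT_UB,
                is_exchange=True,
            )
        )

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        compartments={m.compartment for m in metabolites},
        id=f"toy_liver_seed{scenario.seed}",
    )
    report = validate_model(model)
    assert report.valid, report.issues
    return model


def default_boundary_conditions(scenario: SyntheticScenario) -> BoundaryConditions:
    """Fasting-style conditions: fixed substrate uptake, products free to
    be secreted but not taken up."""
    return BoundaryConditions(uptake={"sub_e": SUBSTRATE_UPTAKE}, units="mmol/h")


def default_mfa_fluxes(scenario: SyntheticScenario, rel_sd: float = 0.1) -> tuple[MFAFluxSet, dict[str, str]]:
    """Measured-flux fixture consistent with the network's true throughput.

    With uptake fixed at SUBSTRATE_UPTAKE, the substrate transport and the
    cofactor regeneration loop must both carry exactly that flux; the
    fixture reports those two as MFA means with ``rel_sd`` relative SD.
    Returns the flux set and the reaction-name map.
    """
    total = SUBSTRATE_UPTAKE
    mfa = MFAFluxSet(
        fluxes={
            "substrate_transport": (total, rel_sd * total),
            "cofactor_turnover": (total, rel_sd * total),
        },
        units="absolute",
    )
    reaction_map = {"substrate_transport": "T_sub", "cofactor_turnover": "COF_regen"}
    return mfa, reaction_map


def pathway_annotation(scenario: SyntheticScenario) -> PathwayAnnotation:
    """Pathway membership matching the generated network: each pathway's
    genes plus its product metabolite."""
    return PathwayAnnotation(
        gene_members={p: set(scenario.pathway_genes(p)) for p in scenario.pathway_names},
        metabolite_members={
            p: {scenario.product_id(p)} for p in scenario.pathway_names
        },
    )


def plant_expression(
    scenario: SyntheticScenario, model: MetabolicModel
) -> ExpressionTable:
    """Expression table with the scenario's pathway effects planted.

    Genes of perturbed pathways: log2fc = planted effect +
    Normal(0, noise_sd_expr), FDR ~ Uniform(0, 0.01).  Background genes:
    log2fc ~ Normal(0, noise_sd_expr), FDR ~ Uniform(0.2, 1).
    """
    rng = np.random.default_rng(scenario.seed + 2)
    gene_pathway = {
        g: p for p in scenario.pathway_names for g in scenario.pathway_genes(p)
    }
    rows = []
    for gene in model.genes:
        pathway = gene_pathway.get(gene)
        effect = scenario.planted_effects.get(pathway, 0.0) if pathway else 0.0
        noise = rng.normal(0.0, scenario.noise_sd_expr) if scenario.noise_sd_expr else 0.0
        if effect != 0.0:
            fdr = rng.uniform(0.0, 0.01)
            log2fc = effect + noise
        else:
            fdr = rng.uniform(0.2, 1.0)
            log2fc = noise
        rows.append({"gene_id": gene, "log2fc": log2fc, "fdr": fdr})
    return ExpressionTable(
        pd.DataFrame(rows), contrast=f"treated_vs_control_seed{scenario.seed}"
    )


def simulate_abundances(scenario: SyntheticScenario, model: MetabolicModel):
    """Replicate-level plasma abundance matrix with planted shifts.

    Log-normal abundances: log2 abundance = base + shift (treated samples
    of perturbed products) + Normal(0, noise_sd_abund).  The shift's sign
    follows the expression-implied direction for the scenario's
    concordant products and is flipped for the rest; it applies at every
    time point.  Also includes a few bystander metabolites absent from
    the model (they exercise the unmapped path downstream).
    """
    from .metabolomics import AbundanceMatrix

    rng = np.random.default_rng(scenario.seed + 3)
    concordant = scenario.concordant_products()

    met_rows = []
    shifts = {}
    for pathway in scenario.pathway_names:
        name = scenario.product_name(pathway)
        met_rows.append({"metabolite": name, "kegg_id": scenario.product_kegg(pathway)})
        effect = scenario.planted_effects.get(pathway, 0.0)
        if effect != 0.0:
            magnitude = scenario.metabolite_effect_size
            sign = np.sign(effect) if concordant.get(pathway, True) else -np.sign(effect)
            shifts[name] = sign * magnitude
        else:
            shifts[name] = 0.0
    for k in range(1, 4):
        name = f"bystander {k}"
        met_rows.append({"metabolite": name, "kegg_id": f"C99{k:03d}"})
        shifts[name] = 0.0

    samples, annotations = [], []
    for treatment in ("control", "treated"):
        for time in scenario.times:
            for rep in range(1, scenario.n_replicates + 1):
                samples.append(f"{treatment}_{time}_r{rep}")
                annotations.append({"treatment": treatment, "time": time})

    met_names = [r["metabolite"] for r in met_rows]
    values = np.empty((len(met_names), len(samples)))
    for i, name in enumerate(met_names):
        for j, (sample, ann) in enumerate(zip(samples, annotations)):
            shift = shifts[name] if ann["treatment"] == "treated" else 0.0
            log2_abund = (
                BASE_LOG2_ABUNDANCE
                + shift
                + rng.normal(0.0, scenario.noise_sd_abund)
            )
            values[i, j] = 2.0 ** log2_abund

    return AbundanceMatrix(
        values=pd.DataFrame(values, index=met_names, columns=samples),
        sample_info=pd.DataFrame(annotations, index=samples),
        metabolite_info=pd.DataFrame(met_rows).set_index("metabolite"),
    )


def ground_truth(scenario: SyntheticScenario) -> dict:
    """Planted directions per product: expression-implied, abundance, and
    whether they agree."""
    concordant = scenario.concordant_products()
    products = {}
    for pathway in scenario.pathway_names:
        expr_dir = scenario.expression_direction(pathway)
        if expr_dir == "unchanged":
            abund_dir = "unchanged"
        elif concordant.get(pathway, True):
            abund_dir = expr_dir
        else:
            abund_dir = "decreased" if expr_dir == "increased" else "increased"
        products[scenario.product_id(pathway)] = {
            "pathway": pathway,
            "expression_direction": expr_dir,
            "abundance_direction": abund_dir,
            "concordant": concordant.get(pathway, None),
        }
    return {
        "seed": scenario.seed,
        "concordant_fraction": scenario.concordant_fraction,
        "products": products,
    }


def make_fixture_bundle(scenario: SyntheticScenario, out_dir) -> dict:
    """Write every pipeline input to ``out_dir`` and return a manifest.

    Files: model (TSV pair + SBML), expression TSV, abundance TSV +
    sample annotation TSV, boundary-conditions YAML, MFA TSV + reaction
    map TSV, pathway GMT, ground-truth JSON.  The manifest maps file
    names to SHA-256 checksums and is itself written as manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = generate_toy_network(scenario)
    write_model_tabular(model, out / "reactions.tsv", out / "metabolites.tsv")
    write_model_sbml(model, out / "model.xml")

    plant_expression(scenario, model).to_tsv(out / "expression.tsv")

    matrix = simulate_abundances(scenario, model)
    matrix.values.to_csv(out / "abundances.tsv", sep="\t", index_label="metabolite")
    matrix.sample_info.to_csv(out / "samples.tsv", sep="\t", index_label="sample")

    default_boundary_conditions(scenario).to_yaml(out / "boundary_conditions.yaml")

    mfa, reaction_map = default_mfa_fluxes(scenario)
    mfa.to_tsv(out / "mfa.tsv")
    pd.DataFrame(
        [{"reaction_name": k, "reaction_id": v} for k, v in reaction_map.items()]
    ).to_csv(out / "mfa_reaction_map.tsv", sep="\t", index=False)

    pathway_annotation(scenario).to_gmt(out / "pathways.gmt")

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ground_truth(scenario), fh, indent=2, sort_keys=True)

    manifest = {}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or not path.is_file():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
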