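"""Concordance of predicted vs. measured metabolite changes.

The headline question: among metabolites whose plasma level changed
significantly, for what fraction does the model's directional call
(increased/decreased) match the sign of the measured log2 fold change?
Also here: the random-expression baseline that measures how much of that
concordance is forced by network structure alone, hypergeometric pathway
over-representation, and the potential-marker selection that intersects
enriched pathways with significant, scored metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .constraints import BoundaryConditions, apply_boundary_conditions
from .metabolomics import MetabolomicsTable, bh_fdr
from .model import MetabolicModel
from .timbr import ProductionScoreTable, TimbrConfig, run_timbr
from .weights import compute_reaction_weights, randomize_expression

__all__ = [
    "ConcordanceReport",
    "PathwayAnnotation",
    "concordance",
    "random_baseline",
    "pathway_enrichment",
    "select_potential_markers",
    "export_heatmap_table",
]


@dataclass
class ConcordanceReport:
    """Directional agreement between calls and measured changes."""

    n_evaluated: int
    n_correct: int
    breakdown: pd.DataFrame  # counts by measured direction x call
    rows: pd.DataFrame  # per-metabolite detail

    @property
    def fraction_correct(self) -> Optional[float]:
        if self.n_evaluated == 0:
            return None
        return self.n_correct / self.n_evaluated


@dataclass
class PathwayAnnotation:
    """Pathway -> member genes and metabolites (KEGG-style grouping)."""

    gene_members: dict[str, set[str]] = field(default_factory=dict)
    metabolite_members: dict[str, set[str]] = field(default_factory=dict)

    @property
    def pathways(self) -> list[str]:
        return sorted(set(self.gene_members) | set(self.metabolite_members))

    @classmethod
    def from_gmt(cls, path) -> "PathwayAnnotation":
        """GMT-style text: pathway <tab> description <tab> member...
        Members prefixed ``met:`` are metabolites, the rest genes."""
        genes: dict[str, set[str]] = {}
        mets: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                pathway = parts[0]
                genes.setdefault(pathway, set())
                mets.setdefault(pathway, set())
                for member in parts[2:]:
                    if member.startswith("met:"):
                        mets[pathway].add(member[4:])
                    elif member:
                        genes[pathway].add(member)
        return cls(gene_members=genes, metabolite_members=mets)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for pathway in self.pathways:
                members = sorted(self.gene_members.get(pathway, set())) + [
                    f"met:{m}"
                    for m in sorted(self.metabolite_members.get(pathway, set()))
                ]
                fh.write("\t".join([pathway, pathway] + members) + "\n")


def _measured_key_column(measured: MetabolomicsTable) -> str:
    if "mapped_model_metabolite" in measured.data.columns:
        return "mapped_model_metabolite"
    return "metabolite"


def concordance(
    scores: ProductionScoreTable,
    measured: MetabolomicsTable,
    fdr_cut: float = 0.10,
    count_unchanged_as_incorrect: bool = True,
) -> ConcordanceReport:
    """Fraction of measured-significant metabolites whose call matches the
    measured direction.

    Evaluation set: metabolites with q < fdr_cut (strict) that have a
    scored model row.  Correct iff (call increased and log2fc > 0) or
    (call decreased and log2fc < 0).  'Unchanged' calls count as
    incorrect by default; set ``count_unchanged_as_incorrect=False`` to
    drop them from the denominator instead (sensitivity mode).
    """
    key = _measured_key_column(measured)
    sig = measured.data[measured.data["q"] < fdr_cut]
    score_df = scores.scored().set_index("metabolite_id")

    rows = []
    for _, m in sig.iterrows():
        met = str(m[key])
        if not met or met not in score_df.index:
            continue
        call = str(score_df.loc[met, "call"])
        log2fc = float(m["log2fc"])
        correct = (call == "increased" and log2fc > 0) or (
            call == "decreased" and log2fc < 0
        )
        rows.append(
            {
                "metabolite": met,
                "measured_log2fc": log2fc,
                "q": float(m["q"]),
                "X_s": float(score_df.loc[met, "X_s"]),
                "call": call,
                "correct": correct,
            }
        )
    detail = pd.DataFrame(
        rows,
        columns=["metabolite", "measured_log2fc", "q", "X_s", "call", "correct"],
    )

    if not count_unchanged_as_incorrect and len(detail):
        detail = detail[detail["call"] != "unchanged"].reset_index(drop=True)

    if len(detail):
        detail["measured_direction"] = np.where(
            detail["measured_log2fc"] > 0, "increased", "decreased"
        )
        breakdown = (
            detail.groupby(["measured_direction", "call"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        breakdown = pd.DataFrame(columns=["measured_direction", "call", "count"])

    return ConcordanceReport(
        n_evaluated=len(detail),
        n_correct=int(detail["correct"].sum()) if len(detail) else 0,
        breakdown=breakdown,
        rows=detail,
    )


def random_baseline(
    model: MetabolicModel,
    bc: BoundaryConditions,
    metabolite_ids: list[str],
    measured: MetabolomicsTable,
    n_reps: int = 20,
    sigma: float = 1.0,
    seed: int = 0,
    config: TimbrConfig = TimbrConfig(),
    fdr_cut: float = 0.10,
) -> pd.DataFrame:
    """Concordance distribution under random expression input.

    Each replicate draws Normal(0, sigma) log2 fold changes (uniform
    FDRs), converts them to weights, scores, and evaluates against the
    measured table.  The mean of the returned fractions is the
    structure-plus-boundary-conditions floor any informative expression
    signal must beat.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    constrained = apply_boundary_conditions(model, bc)
    rng = np.random.default_rng(seed)
    fractions = []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        try:
            expr = randomize_expression(model.genes, sigma=sigma, seed=rep_seed)
            weights = compute_reaction_weights(model, expr)
            scores = run_timbr(constrained, weights, metabolite_ids, config)
            report = concordance(scores, measured, fdr_cut=fdr_cut)
            frac = report.fraction_correct
        except Exception:
            frac = None  # replicate dropped; recorded as NaN
        fractions.append(
            {"replicate": rep, "seed": rep_seed, "fraction_correct": frac}
        )
    return pd.DataFrame(fractions)


def pathway_enrichment(
    sig_genes: set[str],
    background: set[str],
    annotation: PathwayAnnotation,
    fdr_cut: float = 0.10,
) -> pd.DataFrame:
    """Hypergeometric over-representation of significant genes per pathway.

    For a pathway with K background members, an upper-tail test of
    observing >= k of them among the n significant genes drawn from the
    N-gene background; BH-adjusted across pathways.  ``enriched`` marks
    q < fdr_cut.
    """
    if not sig_genes <= background:
        raise ValueError("sig_genes must be a subset of background")
    N, n = len(background), len(sig_genes)
    rows = []
    for pathway in annotation.pathways:
        members = annotation.gene_members.get(pathway, set()) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & sig_genes)
        # upper tail P(X >= k); k = 0 gives p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"pathway": pathway, "n_members": K, "n_overlap": k, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=["pathway", "n_members", "n_overlap", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["enriched"] = df["q"] < fdr_cut
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


def select_potential_markers(
    enriched: pd.DataFrame,
    measured: MetabolomicsTable,
    scores: ProductionScoreTable,
    annotation: PathwayAnnotation,
    fdr_cut: float = 0.10,
) -> pd.DataFrame:
    """Intersect enriched pathways with significant, model-scored metabolites.

    A potential marker is measured-significant (q < fdr_cut), belongs to
    an enriched pathway, and has a scored model prediction; each row
    carries the pathway, measured direction, the model call and an
    agreement flag.  Unscored members are listed with reason 'unscored'
    for transparency but excluded from markers.
    """
    key = _measured_key_column(measured)
    enriched_names = (
        set(enriched.loc[enriched.get("enriched", False) == True, "pathway"])  # noqa: E712
        if len(enriched)
        else set()
    )
    sig = measured.data[measured.data["q"] < fdr_cut]
    score_df = scores.data.set_index("metabolite_id")

    rows = []
    for pathway in sorted(enriched_names):
        members = annotation.metabolite_members.get(pathway, set())
        for _, m in sig.iterrows():
            met = str(m[key])
            if not met or met not in members:
                continue
            measured_dir = "increased" if float(m["log2fc"]) > 0 else "decreased"
            if met in score_df.index and score_df.loc[met, "call"] != "unscored":
                call = str(score_df.loc[met, "call"])
                rows.append(
                    {
                        "pathway": pathway,
                        "metabolite": met,
                        "measured_log2fc": float(m["log2fc"]),
                        "measured_direction": measured_dir,
                        "call": call,
                        "agreement": call == measured_dir,
                        "reason": "marker",
                    }
                )
            else:
                rows.append(
                    {
                        "pathway": pathway,
                        "metabolite": met,
                        "measured_log2fc": float(m["log2fc"]),
                        "measured_direction": measured_dir,
                        "call": "unscored",
                        "agreement": False,
                        "reason": "unscored",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "metabolite",
            "measured_log2fc",
            "measured_direction",
            "call",
            "agreement",
            "reason",
        ],
    )


def export_heatmap_table(
    measured: MetabolomicsTable,
    scores_no_mfa: ProductionScoreTable,
    scores_mfa: ProductionScoreTable,
    fdr_cut: float = 0.10,
) -> pd.DataFrame:
    """Three-column comparison: measured log2fc, X_s without MFA
    constraints, X_s with them; one row per evaluated metabolite, sorted
    by measured log2fc descending.  Missing scores are NA."""
    key = _measured_key_column(measured)
    sig = measured.data[measured.data["q"] < fdr_cut]
    no_mfa = scores_no_mfa.scored().set_index("metabolite_id")["X_s"]
    mfa = scores_mfa.scored().set_index("metabolite_id")["X_s"]

    rows = []
    for _, m in sig.iterrows():
        met = str(m[key])
        if not met:
            continue
        if met not in no_mfa.index and met not in mfa.index:
            continue
        rows.append(
            {
                "metabolite": met,
                "measured_log2fc": float(m["log2fc"]),
                "X_s_no_mfa": float(no_mfa[met]) if met in no_mfa.index else np.nan,
                "X_s_mfa": float(mfa[met]) if met in mfa.index else np.nan,
            }
        )
    df = pd.DataFrame(
        rows, columns=["metabolite", "measured_log2fc", "X_s_no_mfa", "X_s_mfa"]
    )
    return df.sort_values(
        "measured_log2fc", ascending=False, kind="stable"
    ).reset_index(drop=True)
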