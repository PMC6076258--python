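"""Gene expression to reaction weights.

Differential expression (log2 fold change + FDR per gene) is shrunk for
significance, aggregated over each reaction's GPR tree, and mapped to a
pair of positive multiplicative weights per reaction — one for the control
condition, one for the treatment — that the weighted flux-minimization
engine consumes.  Up-regulation makes flux cheap under treatment and
expensive under control, and vice versa; the weight pair always multiplies
to 1 before clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .gpr import GprTree
from .model import MetabolicModel

__all__ = [
    "ExpressionTable",
    "ReactionWeightSet",
    "DEFAULT_CLIP",
    "shrink_fold_change",
    "reaction_expression",
    "compute_reaction_weights",
    "randomize_expression",
    "add_noise",
]

DEFAULT_CLIP = (0.125, 8.0)


@dataclass
class ExpressionTable:
    """Per-gene differential expression for one contrast.

    ``data`` has columns gene_id, log2fc, fdr; gene ids are unique,
    fdr in [0, 1], log2fc finite.
    """

    data: pd.DataFrame
    contrast: str = ""

    def __post_init__(self):
        required = {"gene_id", "log2fc", "fdr"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"expression table missing columns: {sorted(missing)}")
        if self.data["gene_id"].duplicated().any():
            dupes = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids: {sorted(set(dupes))[:5]}")
        fdr = self.data["fdr"].to_numpy(dtype=float)
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValueError("fdr values must lie in [0, 1]")
        if not np.isfinite(self.data["log2fc"].to_numpy(dtype=float)).all():
            raise ValueError("log2fc values must be finite")

    @classmethod
    def from_tsv(cls, path, contrast: str = "") -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t"), contrast=contrast)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def gene_values(self) -> dict[str, float]:
        """Shrunken per-gene values r_g = log2fc * (1 - fdr)."""
        out = {}
        for gene, fc, fdr in zip(
            self.data["gene_id"], self.data["log2fc"], self.data["fdr"]
        ):
            out[str(gene)] = shrink_fold_change(float(fc), float(fdr))
        return out


@dataclass
class ReactionWeightSet:
    """Per-reaction (w_control, w_treatment) weight pairs with provenance."""

    weights: dict[str, tuple[float, float]]
    clip: tuple[float, float] = DEFAULT_CLIP
    contrast: str = ""
    shrinkage: str = "multiplicative (1 - fdr)"

    def control(self, order: list[str]) -> np.ndarray:
        return np.array([self.weights[r][0] for r in order])

    def treatment(self, order: list[str]) -> np.ndarray:
        return np.array([self.weights[r][1] for r in order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"reaction_id": r, "w_control": wc, "w_treatment": wt}
                for r, (wc, wt) in self.weights.items()
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def uniform(cls, model: MetabolicModel) -> "ReactionWeightSet":
        """All-ones weights: both conditions cost every reaction equally."""
        return cls(weights={r.id: (1.0, 1.0) for r in model.reactions})


def shrink_fold_change(log2fc: float, fdr: float) -> float:
    """Significance-shrunk expression change r_g = log2fc * (1 - fdr).

    A certain change (fdr = 0) passes through; a worthless one (fdr = 1)
    is zeroed.  Magnitude is non-increasing in fdr and the sign is
    preserved, so no hard significance cut-off is needed.
    """
    if not (0.0 <= fdr <= 1.0):
        raise ValueError(f"fdr must lie in [0, 1], got {fdr}")
    return log2fc * (1.0 - fdr)


def reaction_expression(gpr: Optional[GprTree], gene_values: dict[str, float]) -> float:
    """Aggregate per-gene values over a GPR tree to a reaction value r_j.

    AND nodes (enzyme complexes) take the child of minimum magnitude — the
    limiting subunit; OR nodes (isozymes) take the child of maximum
    magnitude — the dominant isozyme.  Genes missing from ``gene_values``
    count as unchanged (0); a reaction without GPR returns 0.
    """
    if gpr is None:
        return 0.0
    if gpr.kind == "GENE":
        return float(gene_values.get(gpr.gene, 0.0))
    child_values = [reaction_expression(c, gene_values) for c in gpr.children]
    if gpr.kind == "AND":
        return min(child_values, key=abs)
    return max(child_values, key=abs)


def compute_reaction_weights(
    model: MetabolicModel,
    expr: ExpressionTable,
    clip: tuple[float, float] = DEFAULT_CLIP,
    base: float = 2.0,
    scale: float = 0.5,
) -> ReactionWeightSet:
    """Convert an expression table into per-reaction weight pairs.

    For each reaction with GPR-aggregated value ``r_j``::

        w_control   = clip(base ** (+scale * r_j))
        w_treatment = clip(base ** (-scale * r_j))

    so up-regulated reactions are cheap under treatment and expensive under
    control (w_control * w_treatment = 1 before clipping).  Reactions
    without a GPR get (1, 1).  Expression genes absent from the model are
    ignored; model genes absent from the table count as unchanged.
    """
    w_min, w_max = clip
    if w_min <= 0 or w_max <= 0 or w_min > w_max:
        raise ValueError(f"clip bounds must be positive with w_min <= w_max, got {clip}")

    gene_values = expr.gene_values()
    model_genes = set(model.genes)
    n_unmapped = sum(1 for g in gene_values if g not in model_genes)

    weights: dict[str, tuple[float, float]] = {}
    for r in model.reactions:
        r_j = reaction_expression(r.gpr, gene_values)
        w_control = float(np.clip(base ** (scale * r_j), w_min, w_max))
        w_treatment = float(np.clip(base ** (-scale * r_j), w_min, w_max))
        weights[r.id] = (w_control, w_treatment)

    ws = ReactionWeightSet(weights=weights, clip=clip, contrast=expr.contrast)
    ws.n_unmapped_genes = n_unmapped
    return ws


def randomize_expression(
    gene_ids: list[str], sigma: float, seed: int
) -> ExpressionTable:
    """Random expression table: log2fc ~ Normal(0, sigma), fdr ~ Uniform(0,1).

    The no-information baseline: weights derived from it reflect only
    network structure plus boundary conditions, never biology.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log2fc": rng.normal(0.0, sigma, size=len(gene_ids)),
            "fdr": rng.uniform(0.0, 1.0, size=len(gene_ids)),
        }
    )
    return ExpressionTable(data, contrast=f"random(sigma={sigma},seed={seed})")


def add_noise(expr: ExpressionTable, sigma: float, seed: int) -> ExpressionTable:
    """Perturb log2 fold changes with Normal(0, sigma) noise; fdr unchanged."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    data = expr.data.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        data["log2fc"] = data["log2fc"].to_numpy(dtype=float) + rng.normal(
            0.0, sigma, size=len(data)
        )
    return ExpressionTable(data, contrast=f"{expr.contrast}+noise(sigma={sigma})")
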