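"""Plasma metabolomics differential statistics.

Replicate-level abundance matrices (metabolites x samples, each sample
annotated with treatment and time) are log-transformed after
minimum-value imputation of missing entries; group contrasts use Welch's
two-sample t-test with Benjamini-Hochberg FDR, and a per-metabolite
two-way ANOVA (treatment x time, between-subject factors) screens for
overall treatment effects.  Results map onto model metabolites by KEGG
id, then by case-insensitive name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import MetabolicModel

__all__ = [
    "AbundanceMatrix",
    "MetabolomicsTable",
    "impute_min",
    "welch_test",
    "bh_fdr",
    "two_way_anova",
    "differential_contrast",
    "map_metabolites",
    "differential_metabolites",
]


@dataclass
class AbundanceMatrix:
    """Metabolites x samples abundance data with a two-factor design.

    ``values``: DataFrame indexed by metabolite, one column per sample
    (non-negative or NaN for missing).  ``sample_info``: DataFrame indexed
    by sample with columns treatment (control/treated) and time (e.g. 5h,
    10h).  ``metabolite_info``: optional name/kegg_id annotations.
    """

    values: pd.DataFrame
    sample_info: pd.DataFrame
    metabolite_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        for col in ("treatment", "time"):
            if col not in self.sample_info.columns:
                raise ValueError(f"sample_info missing column {col!r}")
        missing = set(self.values.columns) - set(self.sample_info.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():  # NaN compares False: missing entries pass
            raise ValueError("abundances must be non-negative or missing")

    def samples_where(self, treatment: str = None, time: str = None) -> list[str]:
        info = self.sample_info
        mask = pd.Series(True, index=info.index)
        if treatment is not None:
            mask &= info["treatment"] == treatment
        if time is not None:
            mask &= info["time"] == time
        return [s for s in self.values.columns if s in info.index[mask]]


@dataclass
class MetabolomicsTable:
    """Per-metabolite differential results for one contrast.

    ``data`` columns: metabolite, kegg_id, log2fc, p, q and (after
    mapping) mapped_model_metabolite.
    """

    data: pd.DataFrame
    contrast: str = ""

    def __post_init__(self):
        required = {"metabolite", "log2fc", "p", "q"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"metabolomics table missing columns: {sorted(missing)}")
        if self.data["metabolite"].duplicated().any():
            raise ValueError("duplicate metabolite keys")

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, contrast: str = "") -> "MetabolomicsTable":
        return cls(pd.read_csv(path, sep="\t"), contrast=contrast)


def impute_min(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace each metabolite's missing entries with its minimum observed
    value; all-missing metabolites are an error."""
    values = matrix.values.copy()
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            "metabolites with no observed values: "
            + ", ".join(map(str, values.index[all_missing][:5]))
        )
    row_min = values.min(axis=1, skipna=True)
    values = values.apply(lambda row: row.fillna(row_min[row.name]), axis=1)
    return AbundanceMatrix(
        values=values,
        sample_info=matrix.sample_info,
        metabolite_info=matrix.metabolite_info,
    )


def welch_test(group_a, group_b) -> tuple[float, float]:
    """Welch's two-sample t-test on (already log-transformed) abundances.

    Unequal-variance t statistic with Satterthwaite degrees of freedom,
    two-sided p.  Each group needs n >= 2; two identical constant groups
    return (0, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def two_way_anova(matrix: AbundanceMatrix, log: bool = True) -> pd.DataFrame:
    """Per-metabolite 2x2 between-subject ANOVA (treatment x time).

    Fits log(abundance) ~ treatment * time per metabolite and returns F
    statistics and p-values for both main effects and the interaction
    (type II sums of squares; identical to type I/III for this balanced
    design).  Zero-variance metabolites get p = 1 by convention.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    info = matrix.sample_info.loc[list(matrix.values.columns)]
    cells = info.groupby(["treatment", "time"], observed=True).size()
    if len(cells) < 4 or (cells < 2).any():
        raise ValueError(
            "two-way ANOVA needs >= 2 samples in every treatment x time cell"
        )

    vals = matrix.values.to_numpy(dtype=float)
    if log:
        if (vals <= 0).any():
            raise ValueError("log transform requires strictly positive abundances")
        vals = np.log(vals)

    base = pd.DataFrame(
        {
            "treatment": info["treatment"].to_numpy(),
            "time": info["time"].to_numpy(),
        }
    )
    rows = []
    for i, met in enumerate(matrix.values.index):
        y = vals[i]
        if np.ptp(y) == 0.0:
            rows.append(
                {
                    "metabolite": met,
                    "F_treatment": 0.0,
                    "p_treatment": 1.0,
                    "F_time": 0.0,
                    "p_time": 1.0,
                    "F_interaction": 0.0,
                    "p_interaction": 1.0,
                }
            )
            continue
        frame = base.assign(y=y)
        fit = ols("y ~ C(treatment) * C(time)", data=frame).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        rows.append(
            {
                "metabolite": met,
                "F_treatment": float(table.loc["C(treatment)", "F"]),
                "p_treatment": float(table.loc["C(treatment)", "PR(>F)"]),
                "F_time": float(table.loc["C(time)", "F"]),
                "p_time": float(table.loc["C(time)", "PR(>F)"]),
                "F_interaction": float(table.loc["C(treatment):C(time)", "F"]),
                "p_interaction": float(table.loc["C(treatment):C(time)", "PR(>F)"]),
            }
        )
    return pd.DataFrame(rows)


def differential_contrast(
    matrix: AbundanceMatrix,
    time: str,
    control: str = "control",
    treated: str = "treated",
) -> MetabolomicsTable:
    """Treated-vs-control contrast at one time point.

    Missing values are min-imputed, abundances log-transformed, each
    metabolite Welch-tested, p-values BH-adjusted; log2 fold changes are
    differences of group mean log2 abundances after imputation.
    """
    matrix = impute_min(matrix)
    ctrl_cols = matrix.samples_where(treatment=control, time=time)
    trt_cols = matrix.samples_where(treatment=treated, time=time)
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError(f"need >= 2 samples per group at time {time!r}")

    ctrl = matrix.values[ctrl_cols].to_numpy(dtype=float)
    trt = matrix.values[trt_cols].to_numpy(dtype=float)
    if (ctrl <= 0).any() or (trt <= 0).any():
        raise ValueError("log transform requires strictly positive abundances")

    log_ctrl, log_trt = np.log(ctrl), np.log(trt)
    results = [welch_test(log_trt[i], log_ctrl[i]) for i in range(len(matrix.values))]
    t_stats = np.array([r[0] for r in results])
    p_vals = np.array([r[1] for r in results])
    q_vals = bh_fdr(p_vals)
    log2fc = np.log2(trt).mean(axis=1) - np.log2(ctrl).mean(axis=1)

    info = matrix.metabolite_info
    kegg = (
        info["kegg_id"].reindex(matrix.values.index)
        if "kegg_id" in info.columns
        else pd.Series(None, index=matrix.values.index, dtype=object)
    )
    data = pd.DataFrame(
        {
            "metabolite": matrix.values.index,
            "kegg_id": kegg.to_numpy(),
            "log2fc": log2fc,
            "t": t_stats,
            "p": p_vals,
            "q": q_vals,
        }
    ).reset_index(drop=True)
    return MetabolomicsTable(data, contrast=f"{treated}_vs_{control}_{time}")


def map_metabolites(
    table: MetabolomicsTable,
    model: MetabolicModel,
    exclusion_list: Optional[set[str]] = None,
    alias_table: Optional[dict[str, str]] = None,
) -> MetabolomicsTable:
    """Attach model metabolite ids: exact KEGG id first, then exact
    case-insensitive name, then the optional alias table.

    Measured metabolites on the ``exclusion_list`` (e.g. drug-metabolism
    conjugates outside the model's scope) are marked 'excluded';
    unmatched rows are marked unmapped (empty id).
    """
    exclusion_list = {e.lower() for e in (exclusion_list or set())}
    alias_table = {k.lower(): v for k, v in (alias_table or {}).items()}

    # plasma measurements match the extracellular species when a name or
    # KEGG id exists in several compartments
    extracellular = ("e", "extracellular", "plasma")
    ordered = sorted(
        model.metabolites, key=lambda m: m.compartment not in extracellular
    )
    by_kegg: dict[str, str] = {}
    by_name: dict[str, str] = {}
    for m in ordered:
        if m.kegg_id and m.kegg_id not in by_kegg:
            by_kegg[m.kegg_id] = m.id
        if m.name and m.name.lower() not in by_name:
            by_name[m.name.lower()] = m.id

    mapped, status = [], []
    for _, row in table.data.iterrows():
        name = str(row["metabolite"])
        kegg = row.get("kegg_id")
        if name.lower() in exclusion_list:
            mapped.append("")
            status.append("excluded")
            continue
        target = ""
        if isinstance(kegg, str) and kegg in by_kegg:
            target = by_kegg[kegg]
        elif name.lower() in by_name:
            target = by_name[name.lower()]
        elif name.lower() in alias_table:
            target = alias_table[name.lower()]
        mapped.append(target)
        status.append("mapped" if target else "unmapped")

    data = table.data.copy()
    data["mapped_model_metabolite"] = mapped
    data["mapping_status"] = status
    return MetabolomicsTable(data, contrast=table.contrast)


def differential_metabolites(
    table: MetabolomicsTable, fdr_cut: float = 0.10
) -> pd.DataFrame:
    """Rows with q strictly below the FDR cut, with direction from the
    sign of log2fc."""
    subset = table.data[table.data["q"] < fdr_cut].copy()
    subset["direction"] = np.where(subset["log2fc"] > 0, "increased", "decreased")
    subset.loc[subset["log2fc"] == 0, "direction"] = "unchanged"
    return subset.reset_index(drop=True)
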