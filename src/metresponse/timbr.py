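"""Weighted flux-minimization production scores.

For each plasma metabolite the engine asks: how much total (weighted)
flux must the whole network carry to sustain near-maximal production of
that metabolite?  Formally, with stoichiometric matrix S, flux bounds
lb <= v <= ub, a demand (exchange) flux v_X and positive per-reaction
weights W::

    X_met = min sum_j W_j |v_j|
            s.t.  S v = 0,  v_X >= v_opt,  lb <= v <= ub

where v_opt = alpha * v_max and v_max is the maximum feasible demand.
Solving once with control weights and once with treatment weights gives
the raw score

    X_raw = (X_control - X_treatment) / (X_control + X_treatment)

which is positive when production is cheaper under treatment (predicted
plasma increase).  Raw scores are z-transformed across all scored
metabolites and classified against a +/- threshold.

The |v| objective is linearized exactly with auxiliary variables
t_j >= |v_j| (LP, no integer variables); all solves use HiGHS through
scipy for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoichiometric_matrix
from .weights import ReactionWeightSet

__all__ = [
    "TimbrConfig",
    "ProductionScoreTable",
    "InfeasibleProblemError",
    "max_production_capability",
    "production_cost",
    "raw_score",
    "z_transform",
    "classify",
    "run_timbr",
]

UNSCORED = "unscored"


class InfeasibleProblemError(RuntimeError):
    """LP infeasible or solver failure; carries the solver status message."""


@dataclass(frozen=True)
class TimbrConfig:
    """Scoring parameters.

    alpha: fraction of maximum production capability the demand must
    sustain (v_opt = alpha * v_max).  call_threshold: half-width of the
    'unchanged' band on the z-scored scale.  z_mode: 'sample_sd' (n-1
    denominator) or 'population_sd'.
    """

    alpha: float = 0.9
    call_threshold: float = 0.1
    solver_tolerance: float = 1e-9
    z_mode: str = "sample_sd"
    capability_floor: float = 1e-6  # v_max below this -> unscored

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.call_threshold < 0:
            raise ValueError("call_threshold must be >= 0")
        if self.z_mode not in ("sample_sd", "population_sd"):
            raise ValueError(f"unknown z_mode {self.z_mode!r}")


@dataclass
class ProductionScoreTable:
    """Per-metabolite production scores and directional calls.

    ``data`` columns: metabolite_id, v_max, v_opt, X_control, X_treatment,
    X_raw, X_s, call.  ``mu``/``sigma`` are the z-transform statistics
    over scored rows.
    """

    data: pd.DataFrame
    mu: float
    sigma: float
    config: TimbrConfig = field(default_factory=TimbrConfig)

    def call_for(self, metabolite_id: str) -> str:
        rows = self.data.loc[self.data["metabolite_id"] == metabolite_id, "call"]
        if rows.empty:
            raise KeyError(f"no score row for metabolite {metabolite_id!r}")
        return str(rows.iloc[0])

    def scored(self) -> pd.DataFrame:
        return self.data[self.data["call"] != UNSCORED]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LP building blocks
# ---------------------------------------------------------------------------

def _exchange_index(model: MetabolicModel, metabolite_id: str) -> int:
    ex = model.exchange_for(metabolite_id)
    if ex is None:
        raise KeyError(f"metabolite {metabolite_id!r} has no exchange reaction")
    return model.reaction_ids.index(ex.id)


def max_production_capability(model: MetabolicModel, metabolite_id: str) -> float:
    """Maximum feasible secretion flux of a metabolite's exchange reaction.

    Solves max v_ex s.t. S v = 0 and bounds.  Returns a non-negative
    capability (clamped at 0: a network that can only take the metabolite
    up has no production capability).
    """
    S, _, _ = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    j = _exchange_index(model, metabolite_id)
    c = np.zeros(n)
    c[j] = -1.0  # maximize v_ex
    bounds = [(r.lb, r.ub) for r in model.reactions]
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleProblemError(
            f"model infeasible while maximizing production of {metabolite_id!r}: "
            f"{res.message}"
        )
    if not res.success:
        raise InfeasibleProblemError(
            f"solver failure for {metabolite_id!r}: {res.message}"
        )
    return max(0.0, float(-res.fun))


def production_cost(
    model: MetabolicModel,
    weights: np.ndarray,
    metabolite_id: str,
    v_opt: float,
    return_fluxes: bool = False,
):
    """Minimum weighted total flux sustaining demand >= v_opt.

    Variables are (v, t) with t_j >= |v_j| enforced by the rows
    v_j - t_j <= 0 and -v_j - t_j <= 0; the objective sum_j W_j t_j then
    prices absolute flux.  The demand constraint is v_ex >= v_opt.

    Returns the optimal objective X_met >= 0 (and the flux vector if
    ``return_fluxes``).  Raises :class:`InfeasibleProblemError` when
    v_opt exceeds the network's capability.
    """
    weights = np.asarray(weights, dtype=float)
    n = len(model.reactions)
    if weights.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {weights.shape}")
    if (weights <= 0).any():
        raise ValueError("weights must be strictly positive")

    S, _, _ = build_stoichiometric_matrix(model)
    j = _exchange_index(model, metabolite_id)

    # columns: v_1..v_n, t_1..t_n
    c = np.concatenate([np.zeros(n), weights])
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], n))]).tocsr()
    b_eq = np.zeros(S.shape[0])

    eye = sparse.identity(n, format="csr")
    A_ub = sparse.vstack(
        [
            sparse.hstack([eye, -eye]),    # v - t <= 0
            sparse.hstack([-eye, -eye]),   # -v - t <= 0
        ]
    ).tocsr()
    b_ub = np.zeros(2 * n)

    # demand: v_ex >= v_opt  ->  -v_ex <= -v_opt
    demand = sparse.csr_matrix(([-1.0], ([0], [j])), shape=(1, 2 * n))
    A_ub = sparse.vstack([A_ub, demand]).tocsr()
    b_ub = np.concatenate([b_ub, [-v_opt]])

    t_caps = [max(abs(r.lb), abs(r.ub)) for r in model.reactions]
    bounds = [(r.lb, r.ub) for r in model.reactions] + [(0.0, cap) for cap in t_caps]

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleProblemError(
            f"production of {metabolite_id!r} at v_opt={v_opt} is infeasible: "
            f"{res.message}"
        )
    if not res.success:
        raise InfeasibleProblemError(
            f"solver failure for {metabolite_id!r}: {res.message}"
        )
    cost = float(res.fun)
    if return_fluxes:
        return cost, res.x[:n]
    return cost


def raw_score(x_control: float, x_treatment: float) -> Optional[float]:
    """Normalized cost contrast (X_control - X_treatment)/(X_control + X_treatment).

    Lies in [-1, 1]; positive when treatment production is cheaper
    (predicted plasma increase).  Returns ``None`` (unscored) when both
    costs are zero.
    """
    if x_control < 0 or x_treatment < 0:
        raise ValueError("production costs must be non-negative")
    total = x_control + x_treatment
    if total <= 0:
        return None
    return (x_control - x_treatment) / total


def z_transform(
    raw_scores: list[float], mode: str = "sample_sd"
) -> tuple[np.ndarray, float, float]:
    """Z-score raw production scores across the scored metabolite population.

    Returns (scores, mu, sigma).  Sample SD (n-1) by default; when all
    inputs coincide (sigma = 0) every score is 0 by convention.
    """
    arr = np.asarray(raw_scores, dtype=float)
    if arr.size == 0:
        raise ValueError("z_transform requires at least one scored metabolite")
    mu = float(arr.mean())
    ddof = 1 if (mode == "sample_sd" and arr.size > 1) else 0
    sigma = float(arr.std(ddof=ddof))
    if sigma == 0.0 or not np.isfinite(sigma):
        return np.zeros_like(arr), mu, 0.0
    return (arr - mu) / sigma, mu, sigma


def classify(x_s: float, threshold: float = 0.1) -> str:
    """Directional call: 'increased' above +threshold, 'decreased' below
    -threshold, 'unchanged' on the closed interval between."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if x_s > threshold:
        return "increased"
    if x_s < -threshold:
        return "decreased"
    return "unchanged"


def _assert_globally_feasible(model: MetabolicModel) -> None:
    """Abort early if S v = 0 has no solution within the bounds at all
    (conflicting boundary/flux constraints)."""
    S, _, _ = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    res = linprog(
        np.zeros(n),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=[(r.lb, r.ub) for r in model.reactions],
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleProblemError(
            f"model is globally infeasible under its constraints: {res.message}"
        )


def run_timbr(
    model: MetabolicModel,
    weights: ReactionWeightSet,
    metabolite_ids: list[str],
    config: TimbrConfig = TimbrConfig(),
) -> ProductionScoreTable:
    """Score every requested metabolite under control vs. treatment weights.

    Per metabolite: compute v_max; if at/below the capability floor the
    row is unscored; otherwise solve the two weighted flux-minimization
    LPs at v_opt = alpha * v_max, form X_raw, and finally z-transform
    over all scored rows and classify.  Per-metabolite solver failures
    mark that row unscored and the run continues; a globally infeasible
    model (conflicting boundary constraints) aborts up front.
    Deterministic given model, weights and config.
    """
    _assert_globally_feasible(model)
    order = model.reaction_ids
    w_control = weights.control(order)
    w_treatment = weights.treatment(order)

    rows = []
    for met_id in metabolite_ids:
        row = {
            "metabolite_id": met_id,
            "v_max": np.nan,
            "v_opt": np.nan,
            "X_control": np.nan,
            "X_treatment": np.nan,
            "X_raw": np.nan,
            "X_s": np.nan,
            "call": UNSCORED,
        }
        try:
            v_max = max_production_capability(model, met_id)
            row["v_max"] = v_max
            if v_max > config.capability_floor:
                v_opt = config.alpha * v_max
                row["v_opt"] = v_opt
                x_c = production_cost(model, w_control, met_id, v_opt)
                x_t = production_cost(model, w_treatment, met_id, v_opt)
                row["X_control"], row["X_treatment"] = x_c, x_t
                x_raw = raw_score(x_c, x_t)
                if x_raw is not None:
                    row["X_raw"] = x_raw
                    row["call"] = "pending"
        except (InfeasibleProblemError, KeyError):
            pass  # row stays unscored; global infeasibility was ruled out above
        rows.append(row)

    df = pd.DataFrame(rows)
    scored_mask = df["call"] == "pending"
    if scored_mask.any():
        z, mu, sigma = z_transform(
            df.loc[scored_mask, "X_raw"].tolist(), mode=config.z_mode
        )
        df.loc[scored_mask, "X_s"] = z
        df.loc[scored_mask, "call"] = [
            classify(x, config.call_threshold) for x in z
        ]
    else:
        mu, sigma = float("nan"), float("nan")
    return ProductionScoreTable(data=df, mu=mu, sigma=sigma, config=config)
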