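"""Independent brute-force oracles used only by the test suite.

The weighted-absolute-flux minimum is recomputed here by exhaustive
vertex enumeration: the minimum of a convex piecewise-linear objective
over a polytope is attained at a vertex of the polytope sliced by the
kink hyperplanes v_i = 0, so enumerating all candidate active sets and
keeping the feasible minimum is an exact (if slow) solution that shares
no code with the LP path it checks.
"""

import itertools
import math

import numpy as np


def min_weighted_abs_flux_bruteforce(
    model, weights, metabolite_id: str, v_opt: float, tol: float = 1e-7
) -> float:
    """Exhaustive minimum of sum_j W_j |v_j| over
    {S v = 0, lb <= v <= ub, v_demand >= v_opt}."""
    weights = np.asarray(weights, dtype=float)
    n = len(model.reactions)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), n))
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoich.items():
            S[met_index[met], j] = coef
    demand_j = next(
        j
        for j, r in enumerate(model.reactions)
        if r.is_exchange and metabolite_id in r.stoich
    )
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])

    # candidate active hyperplanes: bounds, sign kinks, the demand floor
    candidates: list[tuple[np.ndarray, float]] = []
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        for val in {lb[j], ub[j], 0.0}:
            candidates.append((e, val))
    e = np.zeros(n)
    e[demand_j] = 1.0
    candidates.append((e, v_opt))

    rank_S = np.linalg.matrix_rank(S)
    k = n - rank_S
    best = math.inf
    for combo in itertools.combinations(range(len(candidates)), k):
        rows = [candidates[i][0] for i in combo]
        rhs = [candidates[i][1] for i in combo]
        A = np.vstack([S] + [r[None, :] for r in rows])
        b = np.concatenate([np.zeros(S.shape[0]), rhs])
        if np.linalg.matrix_rank(A) < n:
            continue
        v, residuals, _, _ = np.linalg.lstsq(A, b, rcond=None)
        if np.abs(A @ v - b).max() > tol:
            continue
        if (v < lb - tol).any() or (v > ub + tol).any():
            continue
        if v[demand_j] < v_opt - tol:
            continue
        best = min(best, float(weights @ np.abs(v)))
    return best


def bh_stepup(pvalues) -> np.ndarray:
    """Direct Benjamini-Hochberg step-up arithmetic."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return q


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct pmf summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return total
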