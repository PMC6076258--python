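import numpy as np
import pandas as pd
import pytest

from metresponse.model import MetabolicModel, Metabolite, Reaction
from metresponse.timbr import (
    InfeasibleProblemError,
    TimbrConfig,
    classify,
    max_production_capability,
    production_cost,
    raw_score,
    run_timbr,
    z_transform,
)
from metresponse.weights import ExpressionTable, ReactionWeightSet, compute_reaction_weights

from conftest import make_toy1, make_toy_parallel
from oracles import min_weighted_abs_flux_bruteforce


class TestMaxProductionCapability:
    def test_linear_chain_limited_by_uptake(self, toy1):
        assert max_production_capability(toy1, "B_e") == pytest.approx(10.0)

    def test_closed_uptake_blocks_production(self, toy1):
        closed = toy1.with_reaction_bounds({"EX_A": (0.0, 0.0)})
        assert max_production_capability(closed, "B_e") == pytest.approx(0.0)

    def test_missing_exchange_is_key_error(self, toy1):
        with pytest.raises(KeyError):
            max_production_capability(toy1, "A_c")


class TestProductionCost:
    def test_uniform_weights_chain(self, toy1, uniform_weights5):
        """Demand 9 on the chain forces |v| = 9 on all five reactions:
        cost 5 * 9 = 45."""
        assert production_cost(toy1, uniform_weights5, "B_e", 9.0) == pytest.approx(45.0)

    def test_reweighted_chain(self, toy1, uniform_weights5):
        w = uniform_weights5.copy()
        w[2] = 0.5  # R1
        assert production_cost(toy1, w, "B_e", 9.0) == pytest.approx(40.5)

    def test_infeasible_demand(self, toy1, uniform_weights5):
        with pytest.raises(InfeasibleProblemError):
            production_cost(toy1, uniform_weights5, "B_e", 11.0)

    def test_nonpositive_weights_rejected(self, toy1, uniform_weights5):
        w = uniform_weights5.copy()
        w[0] = 0.0
        with pytest.raises(ValueError):
            production_cost(toy1, w, "B_e", 1.0)

    def test_returned_fluxes_mass_balanced(self, toy_parallel):
        from metresponse.model import build_stoichiometric_matrix

        n = len(toy_parallel.reactions)
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2.0, size=n)
        cost, fluxes = production_cost(
            toy_parallel, w, "B_e", 4.0, return_fluxes=True
        )
        S, _, rxn_index = build_stoichiometric_matrix(toy_parallel)
        assert np.abs(S @ fluxes).max() <= 1e-6
        assert fluxes[rxn_index["EX_B"]] >= 4.0 - 1e-6
        assert cost == pytest.approx(float(w @ np.abs(fluxes)), abs=1e-6)


def _random_oracle_network(seed: int):
    """Small random LP instance on one of three fixed topologies with
    randomized weights, uptake cap and demand level."""
    rng = np.random.default_rng(seed)
    uptake = float(rng.uniform(2.0, 10.0))
    topology = seed % 3
    if topology == 0:
        model = make_toy1(uptake_limit=uptake)
        target = "B_e"
    elif topology == 1:
        # parallel isozyme routes to the same product
        model = MetabolicModel(
            metabolites=[
                Metabolite("A_e", compartment="e"),
                Metabolite("A_c"),
                Metabolite("B_c"),
                Metabolite("B_e", compartment="e"),
            ],
            reactions=[
                Reaction("EX_A", {"A_e": -1.0}, lb=-uptake, ub=0.0, is_exchange=True),
                Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, lb=0.0, ub=1000.0),
                Reaction("R1a", {"A_c": -1.0, "B_c": 1.0}, lb=0.0, ub=1000.0),
                Reaction("R1b", {"A_c": -1.0, "B_c": 1.0}, lb=0.0, ub=1000.0),
                Reaction("T_B", {"B_c": -1.0, "B_e": 1.0}, lb=0.0, ub=1000.0),
                Reaction("EX_B", {"B_e": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
            ],
            genes=[],
        )
        target = "B_e"
    else:
        # chain with a reversible internal shunt
        model = MetabolicModel(
            metabolites=[
                Metabolite("A_e", compartment="e"),
                Metabolite("A_c"),
                Metabolite("B_c"),
                Metabolite("B_e", compartment="e"),
            ],
            reactions=[
                Reaction("EX_A", {"A_e": -1.0}, lb=-uptake, ub=0.0, is_exchange=True),
                Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, lb=0.0, ub=1000.0),
                Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, lb=0.0, ub=1000.0),
                Reaction("R_shunt", {"A_c": -1.0, "B_c": 1.0}, lb=-5.0, ub=5.0),
                Reaction("T_B", {"B_c": -1.0, "B_e": 1.0}, lb=0.0, ub=1000.0),
                Reaction("EX_B", {"B_e": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
            ],
            genes=[],
        )
        target = "B_e"
    n = len(model.reactions)
    weights = rng.uniform(0.125, 8.0, size=n)
    v_max = max_production_capability(model, target)
    v_opt = float(rng.uniform(0.3, 1.0)) * v_max
    return model, weights, target, v_opt


@pytest.mark.parametrize("seed", range(25))
def test_production_cost_matches_vertex_enumeration(seed):
    """On small networks the LP minimum equals the exhaustive minimum over
    all candidate vertices of the sliced feasible polytope."""
    model, weights, target, v_opt = _random_oracle_network(seed)
    lp = production_cost(model, weights, target, v_opt)
    brute = min_weighted_abs_flux_bruteforce(model, weights, target, v_opt)
    assert lp == pytest.approx(brute, abs=1e-6)


class TestRawScore:
    def test_toy_worked_case(self):
        assert raw_score(54.0, 40.5) == pytest.approx(1.0 / 7.0)

    @pytest.mark.parametrize("c", [0.5, 45.0, 1e6])
    def test_symmetry_gives_zero(self, c):
        assert raw_score(c, c) == 0.0

    def test_degenerate_case_unscored(self):
        assert raw_score(0.0, 0.0) is None

    def test_bounded_in_unit_interval(self):
        assert raw_score(100.0, 0.0) == 1.0
        assert raw_score(0.0, 100.0) == -1.0

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            raw_score(-1.0, 2.0)


class TestZTransform:
    def test_three_point_example(self):
        z, mu, sigma = z_transform([0.2, 0.0, -0.2])
        assert list(z) == pytest.approx([1.0, 0.0, -1.0])
        assert mu == pytest.approx(0.0)
        assert sigma == pytest.approx(0.2)

    def test_all_equal_inputs_give_zeros(self):
        z, _, sigma = z_transform([0.3, 0.3, 0.3])
        assert sigma == 0.0
        assert list(z) == [0.0, 0.0, 0.0]

    def test_population_stats_after_transform(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(-1, 1, size=40).tolist()
        z, _, _ = z_transform(raw)
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            z_transform([])


class TestClassify:
    @pytest.mark.parametrize(
        "x_s, expected",
        [
            (0.05, "unchanged"),
            (1.3, "increased"),
            (-0.1, "unchanged"),
            (0.1, "unchanged"),
            (-0.100001, "decreased"),
        ],
    )
    def test_cutoffs_with_closed_interval(self, x_s, expected):
        assert classify(x_s, 0.1) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify(0.0, -0.1)


def _weights_for(model, gene_changes: dict[str, float]) -> ReactionWeightSet:
    rows = [
        {"gene_id": g, "log2fc": gene_changes.get(g, 0.0), "fdr": 0.0}
        for g in model.genes
    ]
    return compute_reaction_weights(model, ExpressionTable(pd.DataFrame(rows)))


class TestRunTimbr:
    def test_uniform_weights_give_zero_scores(self, toy_parallel):
        scores = run_timbr(
            toy_parallel,
            ReactionWeightSet.uniform(toy_parallel),
            ["B_e", "C_e"],
        )
        scored = scores.scored()
        assert (scored["X_raw"].abs() < 1e-9).all()
        assert (scored["call"] == "unchanged").all()

    def test_upregulated_route_scores_above_untouched(self, toy_parallel):
        weights = _weights_for(toy_parallel, {"g1": 2.0})
        scores = run_timbr(toy_parallel, weights, ["B_e", "C_e"])
        df = scores.data.set_index("metabolite_id")
        assert df.loc["B_e", "X_s"] > df.loc["C_e", "X_s"]
        assert df.loc["B_e", "call"] == "increased"

    def test_weight_scale_invariance(self, toy_parallel):
        weights = _weights_for(toy_parallel, {"g1": 1.5, "g2": -0.5})
        scaled = ReactionWeightSet(
            weights={
                r: (3.0 * wc, 3.0 * wt) for r, (wc, wt) in weights.weights.items()
            }
        )
        a = run_timbr(toy_parallel, weights, ["B_e", "C_e"])
        b = run_timbr(toy_parallel, scaled, ["B_e", "C_e"])
        assert a.data["X_raw"].to_numpy() == pytest.approx(
            b.data["X_raw"].to_numpy(), abs=1e-9
        )

    def test_monotone_response_in_planted_fold_change(self, toy_parallel):
        """X_raw for the gated product is non-decreasing in the gene's
        planted log2 fold change."""
        raws = []
        for fc in [-4, -2, 0, 2, 4]:
            weights = _weights_for(toy_parallel, {"g1": float(fc)})
            scores = run_timbr(toy_parallel, weights, ["B_e", "C_e"])
            raws.append(
                float(
                    scores.data.set_index("metabolite_id").loc["B_e", "X_raw"]
                )
            )
        assert all(a <= b + 1e-12 for a, b in zip(raws, raws[1:]))

    @pytest.mark.parametrize("alpha", [0.5, 0.9, 1.0])
    def test_sign_robust_to_alpha(self, toy_parallel, alpha):
        weights = _weights_for(toy_parallel, {"g1": 2.0})
        scores = run_timbr(
            toy_parallel, weights, ["B_e", "C_e"], TimbrConfig(alpha=alpha)
        )
        df = scores.data.set_index("metabolite_id")
        assert df.loc["B_e", "X_raw"] > 0

    def test_blocked_metabolite_is_unscored(self, toy_parallel):
        blocked = toy_parallel.with_reaction_bounds({"R2": (0.0, 0.0)})
        scores = run_timbr(
            blocked, ReactionWeightSet.uniform(blocked), ["B_e", "C_e"]
        )
        df = scores.data.set_index("metabolite_id")
        assert df.loc["C_e", "call"] == "unscored"
        assert df.loc["B_e", "call"] != "unscored"

    def test_globally_infeasible_model_aborts(self, toy1):
        # forced secretion of B with uptake of A closed: no balanced flux
        broken = toy1.with_reaction_bounds(
            {"EX_A": (0.0, 0.0), "EX_B": (5.0, 1000.0)}
        )
        with pytest.raises(InfeasibleProblemError):
            run_timbr(broken, ReactionWeightSet.uniform(broken), ["B_e"])

    def test_row_count_matches_request_and_determinism(self, toy_parallel):
        weights = _weights_for(toy_parallel, {"g1": 1.0})
        a = run_timbr(toy_parallel, weights, ["B_e", "C_e", "A_e"])
        b = run_timbr(toy_parallel, weights, ["B_e", "C_e", "A_e"])
        assert len(a.data) == 3
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_z_population_stats_over_scored_rows(self, toy_parallel):
        weights = _weights_for(toy_parallel, {"g1": 2.0, "g2": -1.0})
        scores = run_timbr(toy_parallel, weights, ["B_e", "C_e"])
        scored = scores.scored()
        assert scored["X_s"].mean() == pytest.approx(0.0, abs=1e-9)
        assert scored["X_s"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestTimbrConfig:
    @pytest.mark.parametrize("alpha", [0.0, 1.1, -0.5])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ValueError):
            TimbrConfig(alpha=alpha)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            TimbrConfig(call_threshold=-0.1)
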