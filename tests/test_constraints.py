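import numpy as np
import pytest
from scipy import integrate, optimize, stats

from metresponse.constraints import (
    BoundaryConditions,
    ConstraintConflictError,
    MFAFluxSet,
    apply_boundary_conditions,
    apply_mfa_constraints,
    chi2_ssr_acceptance,
    derive_5h_fluxes,
    perturb_constraints,
)
from metresponse.timbr import max_production_capability


class TestBoundaryConditions:
    def test_uptake_fixes_both_bounds(self, toy1):
        bc = BoundaryConditions(uptake={"A_e": 5.0})
        out = apply_boundary_conditions(toy1, bc, tolerance_frac=0.0)
        ex = out.reaction("EX_A")
        assert (ex.lb, ex.ub) == (-5.0, -5.0)

    def test_uptake_tolerance_widens_symmetrically(self, toy1):
        bc = BoundaryConditions(uptake={"A_e": 10.0})
        out = apply_boundary_conditions(toy1, bc, tolerance_frac=0.1)
        ex = out.reaction("EX_A")
        assert (ex.lb, ex.ub) == (-11.0, -9.0)

    def test_secretion_sets_lower_bound_only(self, toy1):
        bc = BoundaryConditions(uptake={"A_e": 5.0}, secretion_min={"B_e": 3.0})
        out = apply_boundary_conditions(toy1, bc)
        ex = out.reaction("EX_B")
        assert ex.lb == 3.0
        assert ex.ub == toy1.reaction("EX_B").ub

    def test_unlisted_exchanges_closed_to_uptake(self, toy1):
        bc = BoundaryConditions(uptake={"A_e": 5.0})
        out = apply_boundary_conditions(toy1, bc)
        assert out.reaction("EX_B").lb == 0.0

    def test_unconstrained_fully_open(self, toy1):
        bc = BoundaryConditions(uptake={"A_e": 5.0}, unconstrained=["B_e"])
        out = apply_boundary_conditions(toy1, bc)
        ex = out.reaction("EX_B")
        assert ex.lb < 0 < ex.ub

    def test_flux_balance_caps_secretion(self, toy1):
        """Fixing uptake of A at 10 forces max B secretion to exactly 10 on
        the linear chain."""
        bc = BoundaryConditions(uptake={"A_e": 10.0})
        out = apply_boundary_conditions(toy1, bc)
        assert max_production_capability(out, "B_e") == pytest.approx(10.0)

    def test_missing_exchange_is_lookup_error(self, toy1):
        bc = BoundaryConditions(uptake={"A_c": 5.0})
        with pytest.raises(KeyError, match="A_c"):
            apply_boundary_conditions(toy1, bc)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            BoundaryConditions(uptake={"A_e": -1.0})

    def test_uptake_secretion_overlap_rejected(self):
        with pytest.raises(ValueError):
            BoundaryConditions(uptake={"A_e": 1.0}, secretion_min={"A_e": 1.0})

    def test_yaml_round_trip(self, tmp_path):
        bc = BoundaryConditions(
            uptake={"A_e": 5.0}, secretion_min={"B_e": 1.0}, unconstrained=["O2_e"]
        )
        path = tmp_path / "bc.yaml"
        bc.to_yaml(path)
        back = BoundaryConditions.from_yaml(path)
        assert back.uptake == bc.uptake
        assert back.secretion_min == bc.secretion_min
        assert back.unconstrained == bc.unconstrained

    def test_zero_flux_feasible_iff_no_secretion_min(self, toy1):
        """With all-zero secretion minima the constrained chain admits the
        zero flux vector only when uptake is not forced."""
        bc = BoundaryConditions(secretion_min={"B_e": 0.0})
        out = apply_boundary_conditions(toy1, bc)
        for r in out.reactions:
            assert r.lb <= 0.0 <= r.ub
        bc2 = BoundaryConditions(secretion_min={"B_e": 2.0})
        out2 = apply_boundary_conditions(toy1, bc2)
        assert not all(r.lb <= 0.0 <= r.ub for r in out2.reactions)


class TestMfaConstraints:
    def test_mean_pm_sd_interval(self, toy1):
        mfa = MFAFluxSet(fluxes={"transport": (100.0, 10.0)})
        widened = toy1.with_reaction_bounds({"T_A": (0.0, 1000.0)})
        out = apply_mfa_constraints(widened, mfa, {"transport": "T_A"})
        assert (out.reaction("T_A").lb, out.reaction("T_A").ub) == (90.0, 110.0)

    def test_degenerate_sd_pins_flux(self, toy1):
        mfa = MFAFluxSet(fluxes={"transport": (50.0, 0.0)})
        out = apply_mfa_constraints(toy1, mfa, {"transport": "T_A"})
        assert (out.reaction("T_A").lb, out.reaction("T_A").ub) == (50.0, 50.0)

    def test_empty_intersection_conflict(self, toy1):
        mfa = MFAFluxSet(fluxes={"transport": (-20.0, 5.0)})
        with pytest.raises(ConstraintConflictError, match="T_A"):
            apply_mfa_constraints(toy1, mfa, {"transport": "T_A"})

    def test_sd_multiplier_scales_interval(self, toy1):
        mfa = MFAFluxSet(fluxes={"transport": (100.0, 10.0)})
        out = apply_mfa_constraints(toy1, mfa, {"transport": "T_A"}, sd_multiplier=2.0)
        assert (out.reaction("T_A").lb, out.reaction("T_A").ub) == (80.0, 120.0)

    def test_relative_units_must_be_converted(self, toy1):
        mfa = MFAFluxSet(fluxes={"transport": (100.0, 10.0)}, units="relative_cs100")
        with pytest.raises(ValueError, match="absolute"):
            apply_mfa_constraints(toy1, mfa, {"transport": "T_A"})
        absolute = mfa.to_absolute(scale=0.1)
        assert absolute.fluxes["transport"] == (10.0, 1.0)

    def test_commutes_with_boundary_conditions_on_disjoint_sets(self, toy1):
        bc = BoundaryConditions(uptake={"A_e": 10.0})
        mfa = MFAFluxSet(fluxes={"transport": (8.0, 1.0)})
        rmap = {"transport": "T_A"}
        ab = apply_mfa_constraints(apply_boundary_conditions(toy1, bc), mfa, rmap)
        ba = apply_boundary_conditions(apply_mfa_constraints(toy1, mfa, rmap), bc)
        for r1, r2 in zip(ab.reactions, ba.reactions):
            assert (r1.lb, r1.ub) == (r2.lb, r2.ub)


class TestDerive5hFluxes:
    def test_twenty_percent_uplift(self):
        out = derive_5h_fluxes({"glycogenolysis": 1.0}, glucose_output_10h=100.0)
        assert out.fluxes["glucose_output"][0] == pytest.approx(120.0)

    def test_fraction_split(self):
        out = derive_5h_fluxes(
            {"glycogenolysis": 0.5, "gluconeogenesis": 0.5}, glucose_output_10h=100.0
        )
        assert out.fluxes["glycogenolysis"][0] == pytest.approx(60.0)
        assert out.fluxes["gluconeogenesis"][0] == pytest.approx(60.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            derive_5h_fluxes({"a": 0.5, "b": 0.3}, glucose_output_10h=100.0)

    def test_relative_sd_width(self):
        out = derive_5h_fluxes({"a": 1.0}, glucose_output_10h=50.0, rel_sd=0.2)
        mean, sd = out.fluxes["a"]
        assert sd == pytest.approx(0.2 * mean)


class TestChiSquareAcceptance:
    def test_published_interval_22_dof(self):
        """The 99% SSR acceptance region at 22 degrees of freedom is
        [8.6, 42.8] to one decimal."""
        lower, upper = chi2_ssr_acceptance(22, 0.99)
        assert round(lower, 1) == 8.6
        assert round(upper, 1) == 42.8

    def test_single_dof_95(self):
        lower, upper = chi2_ssr_acceptance(1, 0.95)
        assert lower == pytest.approx(0.000982, rel=1e-2)
        assert upper == pytest.approx(5.02, rel=1e-2)

    def test_quantile_ordering_across_levels(self):
        l99, u99 = chi2_ssr_acceptance(22, 0.99)
        l95, u95 = chi2_ssr_acceptance(22, 0.95)
        assert l99 < l95 and u95 < u99

    @pytest.mark.parametrize("dof", [1, 5, 22])
    def test_agrees_with_numerical_integration(self, dof):
        """Quantiles recovered by integrating the chi-square density agree
        with the implementation to 1e-6."""
        lower, upper = chi2_ssr_acceptance(dof, 0.99)
        for q, target in ((lower, 0.005), (upper, 0.995)):
            root = optimize.brentq(
                lambda x: integrate.quad(
                    lambda t: stats.chi2.pdf(t, dof), 0, x, limit=200
                )[0]
                - target,
                1e-12,
                120,
                xtol=1e-10,
            )
            assert root == pytest.approx(q, abs=1e-6)

    @pytest.mark.parametrize("dof, level", [(0, 0.99), (2.5, 0.99), (5, 0.0), (5, 1.0)])
    def test_domain_errors(self, dof, level):
        with pytest.raises(ValueError):
            chi2_ssr_acceptance(dof, level)


class TestPerturbConstraints:
    def test_global_identity_at_scale_one(self):
        bc = BoundaryConditions(uptake={"a": 1.0, "b": 2.0})
        out = perturb_constraints(bc, mode="global", scale=1.0, seed=5)
        assert out.uptake == pytest.approx(bc.uptake)

    def test_local_doubles_single_metabolite(self):
        bc = BoundaryConditions(uptake={"lactate": 3.0, "glycerol": 1.0})
        out = perturb_constraints(bc, mode="local", scale=2.0, seed=0, metabolite="lactate")
        assert out.uptake["lactate"] == 6.0
        assert out.uptake["glycerol"] == 1.0

    def test_global_deterministic_under_seed(self):
        bc = BoundaryConditions(uptake={"a": 1.0, "b": 2.0, "c": 3.0})
        a = perturb_constraints(bc, mode="global", scale=2.0, seed=7)
        b = perturb_constraints(bc, mode="global", scale=2.0, seed=7)
        assert a.uptake == b.uptake

    def test_scale_domain(self):
        bc = BoundaryConditions(uptake={"a": 1.0})
        with pytest.raises(ValueError):
            perturb_constraints(bc, mode="global", scale=0.0, seed=1)
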