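"""FBA engine: optimality vs an independent dense-LP oracle, ratio coupling,
canonical flux selection, flux variability, photon bounding."""

import math

import pytest

from leafcbm.fba import (
    FBAProblem,
    ObjectiveSpec,
    RatioConstraint,
    set_photon_constraint,
    solve_fba,
    steady_state_residual,
)
from leafcbm.model import Metabolite, Reaction

from conftest import chain_model, make_model, oracle_min_total_flux, oracle_solve, random_model


class TestSolveFba:
    def test_bottleneck_chain(self, toy_chain):
        sol = solve_fba(toy_chain)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_closed_exchanges_force_zero(self, toy_chain):
        toy_chain.reactions["EX_A"].lower_bound = 0.0
        sol = solve_fba(toy_chain)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_models(self, seed):
        """GLPK objective equals the dense scipy/HiGHS LP to 1e-6."""
        model = random_model(seed)
        sol = solve_fba(model)
        assert sol.optimal
        expected, _ = oracle_solve(model)
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_steady_state_residual(self, toy_chain):
        sol = solve_fba(toy_chain, canonical=True)
        assert steady_state_residual(toy_chain, sol) <= 1e-6

    def test_infeasible_status_reported(self, toy_chain):
        toy_chain.reactions["BIO"].lower_bound = 50.0  # above the uptake cap
        sol = solve_fba(toy_chain)
        assert sol.status == "infeasible"
        assert not sol.fluxes

    def test_objective_spec_guards(self):
        with pytest.raises(ValueError):
            ObjectiveSpec({})
        with pytest.raises(ValueError):
            ObjectiveSpec({"r": 1.0}, "sideways")


class TestRatioConstraint:
    @staticmethod
    def branched():
        """Two irreversible branches from one substrate, joint drain."""
        return make_model(
            {
                "EX_A": ({"A_e": -1.0}, -10.0, 0.0),
                "T_A": ({"A_e": -1.0, "A": 1.0}, -1000.0, 1000.0),
                "VC": ({"A": -1.0, "P": 1.0}, 0.0, 1000.0),
                "VO": ({"A": -1.0, "P": 1.0}, 0.0, 1000.0),
                "BIO": ({"P": -1.0}, 0.0, 1000.0),
            },
            externals=["A_e"],
            objective={"BIO": 1.0},
        )

    @pytest.mark.parametrize("ratio", [1.0, 2.0, 3.0, 4.0, 5.0])
    def test_equality_holds_and_matches_augmented_oracle(self, ratio):
        model = self.branched()
        rc = RatioConstraint("VC", "VO", ratio)
        sol = solve_fba(model, ratio_constraints=[rc], canonical=True)
        assert sol.optimal
        assert sol["VC"] == pytest.approx(ratio * sol["VO"], abs=1e-6)
        expected, _ = oracle_solve(model, ratio_constraints=[rc])
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_zero_denominator_forces_zero_numerator(self):
        model = self.branched()
        model.reactions["VO"].upper_bound = 0.0
        sol = solve_fba(model, ratio_constraints=[RatioConstraint("VC", "VO", 7.0)])
        assert sol["VC"] == pytest.approx(0.0, abs=1e-9)

    def test_reversible_operand_rejected(self):
        model = self.branched()
        model.reactions["VC"].lower_bound = -5.0
        with pytest.raises(ValueError, match="reversible"):
            solve_fba(model, ratio_constraints=[RatioConstraint("VC", "VO", 2.0)])

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            RatioConstraint("VC", "VO", 0.0)


class TestCanonicalize:
    def test_unique_optimum_unchanged(self, toy_chain):
        plain = solve_fba(toy_chain, canonical=False)
        canon = solve_fba(toy_chain, canonical=True)
        for rid in plain.fluxes:
            assert canon[rid] == pytest.approx(plain[rid], abs=1e-6)
        assert canon.canonicalized

    def test_futile_loop_driven_to_zero(self):
        model = chain_model()
        # a reversible two-reaction loop that can carry arbitrary flux
        model.add_metabolite(Metabolite(id="X", compartment="c"))
        model.add_reaction(Reaction(id="LOOP1", stoichiometry={"A": -1.0, "X": 1.0},
                                    lower_bound=-1000, upper_bound=1000))
        model.add_reaction(Reaction(id="LOOP2", stoichiometry={"X": -1.0, "A": 1.0},
                                    lower_bound=-1000, upper_bound=1000))
        sol = solve_fba(model, canonical=True)
        # objective preserved to the documented 1e-9 relative slack
        assert sol.objective_value == pytest.approx(10.0, rel=2e-9)
        assert sol["LOOP1"] == pytest.approx(0.0, abs=1e-8)
        assert sol["LOOP2"] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_min_total_flux_matches_split_lp_oracle(self, seed):
        model = random_model(seed, n_mets=6, n_rxns=12)
        sol = solve_fba(model, canonical=True)
        assert sol.optimal
        expected = oracle_min_total_flux(model, sol.objective_value)
        assert sol.total_flux() == pytest.approx(expected, rel=1e-5, abs=1e-6)

    def test_objective_preserved_to_relative_tolerance(self):
        for seed in range(8):
            model = random_model(seed)
            plain = solve_fba(model, canonical=False)
            canon = solve_fba(model, canonical=True)
            scale = max(1.0, abs(plain.objective_value))
            assert abs(canon.objective_value - plain.objective_value) <= 1e-8 * scale


class TestFluxVariability:
    def test_bottleneck_chain_is_point_determined(self, toy_chain):
        prob = FBAProblem(toy_chain)
        ranges = prob.flux_variability(fraction_of_optimum=1.0)
        for rid, (lo, hi) in ranges.items():
            assert hi - lo <= 1e-6, rid

    def test_fraction_zero_contains_zero(self, toy_chain):
        ranges = FBAProblem(toy_chain).flux_variability(fraction_of_optimum=0.0)
        for rid, (lo, hi) in ranges.items():
            assert lo <= 1e-9 and hi >= -1e-9

    def test_parallel_pathways_show_alternates(self):
        model = TestRatioConstraint.branched()
        ranges = FBAProblem(model).flux_variability(fraction_of_optimum=1.0)
        # either branch can carry the full 10 units
        assert ranges["VC"] == (pytest.approx(0.0, abs=1e-6),
                                pytest.approx(10.0, abs=1e-6))
        assert ranges["VO"] == (pytest.approx(0.0, abs=1e-6),
                                pytest.approx(10.0, abs=1e-6))
        assert ranges["BIO"] == (pytest.approx(10.0, abs=1e-6),
                                 pytest.approx(10.0, abs=1e-6))

    def test_bad_fraction_rejected(self, toy_chain):
        with pytest.raises(ValueError):
            FBAProblem(toy_chain).flux_variability(fraction_of_optimum=1.5)


class TestScalingHomogeneity:
    @pytest.mark.parametrize("k", [0.5, 2.0])
    def test_exchange_scaling_scales_objective(self, k, leaf_model):
        """LP positive homogeneity: scaling all exchange bounds and the
        maintenance demand by k scales the optimum by k."""
        base = solve_fba(leaf_model,
                         ratio_constraints=[RatioConstraint("RBC_carb", "RBC_oxy", 3.0)])
        scaled_model = leaf_model.copy()
        for rxn in scaled_model.reactions.values():
            if rxn.pathway == "exchange":
                rxn.lower_bound *= k
                rxn.upper_bound *= k
        maint = scaled_model.reactions["MAINT_m"]
        maint.lower_bound *= k
        maint.upper_bound *= k
        # capacity-type internal bounds are part of the condition; scale them too
        for rid in ("MDH_NADP_h", "T_co2_ch"):
            scaled_model.reactions[rid].lower_bound *= k
            scaled_model.reactions[rid].upper_bound *= k
        scaled = solve_fba(scaled_model,
                           ratio_constraints=[RatioConstraint("RBC_carb", "RBC_oxy", 3.0)])
        assert scaled.objective_value == pytest.approx(k * base.objective_value,
                                                       rel=1e-6)


class TestPhotonConstraint:
    def test_bound_is_pn_over_lue(self, leaf_model):
        model = leaf_model.copy()
        set_photon_constraint(model, net_photosynthesis=10.0, lue=0.05)
        assert model.reactions["EX_photon"].lower_bound == pytest.approx(-200.0)
        assert model.reactions["EX_photon"].upper_bound == 0.0

    def test_zero_lue_rejected(self, leaf_model):
        with pytest.raises(ValueError):
            set_photon_constraint(leaf_model.copy(), 10.0, 0.0)

    def test_missing_photon_exchange_raises(self, toy_chain):
        with pytest.raises(KeyError):
            set_photon_constraint(toy_chain, 10.0, 0.05)

    def test_halving_photons_halves_growth_when_light_limited(self, leaf_model):
        """On a light-limited variant (CO2 unconstrained), biomass scales
        linearly with the photon bound."""
        model = leaf_model.copy()
        model.set_uptake_bound("EX_co2", 1000.0)          # carbon no longer limiting
        model.reactions["T_co2_ch"].upper_bound = 1000.0
        model.reactions["MAINT_m"].lower_bound = 0.0      # pure light limitation
        model.reactions["MAINT_m"].upper_bound = 0.0
        model.reactions["MDH_NADP_h"].lower_bound = -1000.0  # no fixed-capacity bounds
        model.reactions["MDH_NADP_h"].upper_bound = 1000.0
        rc = [RatioConstraint("RBC_carb", "RBC_oxy", 3.0)]
        set_photon_constraint(model, 10.0, 0.05)
        full = solve_fba(model, ratio_constraints=rc)
        set_photon_constraint(model, 5.0, 0.05)
        half = solve_fba(model, ratio_constraints=rc)
        assert full.objective_value > 0
        assert half.objective_value == pytest.approx(full.objective_value / 2,
                                                     rel=1e-6)
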