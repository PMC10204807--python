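"""Flux-sum turnover, CO2 attribution, energy budgets, concordance."""

import math

import numpy as np
import pandas as pd
import pytest

from leafcbm.analysis import (
    ExpressionRecord,
    co2_source_attribution,
    concordance,
    energy_turnover_report,
    flux_sum,
    pooled_flux_sum,
)
from leafcbm.fba import FluxSolution, solve_fba
from leafcbm.model import Metabolite, Reaction, StoichiometricModel
from leafcbm.scenarios import fold_change_table, run_drought, run_pepc_elevation

from conftest import make_model


class TestFluxSum:
    def test_one_in_one_out(self, toy_chain):
        sol = solve_fba(toy_chain, canonical=True)
        phi = flux_sum(toy_chain, sol, "B")
        # one producer at 10 and one consumer at 10 -> phi = 0.5*(10+10)
        assert phi.value == pytest.approx(10.0, abs=1e-6)
        assert phi.producer_breakdown == pytest.approx({"R1": 10.0}, abs=1e-6)
        assert phi.consumer_breakdown == pytest.approx({"BIO": 10.0}, abs=1e-6)

    def test_untouched_metabolite_zero(self, toy_chain):
        toy_chain.add_metabolite(Metabolite(id="idle", compartment="c"))
        toy_chain.add_reaction(
            Reaction(id="R_idle", stoichiometry={"A": -1.0, "idle": 1.0},
                     lower_bound=0.0, upper_bound=0.0)
        )
        sol = solve_fba(toy_chain, canonical=True)
        assert flux_sum(toy_chain, sol, "idle").value == 0.0

    def test_unknown_metabolite_raises(self, toy_chain):
        sol = solve_fba(toy_chain)
        with pytest.raises(KeyError):
            flux_sum(toy_chain, sol, "nope")

    def test_steady_state_bookkeeping_all_internal_species(
        self, leaf_model, leaf_baseline
    ):
        """phi equals both the producer-only and consumer-only sums for every
        internal metabolite of the canonical solution."""
        for met in leaf_model.metabolites.values():
            if leaf_model.is_external(met):
                continue
            phi = flux_sum(leaf_model, leaf_baseline.solution, met.id)
            assert phi.production == pytest.approx(phi.value, abs=1e-6), met.id
            assert phi.consumption == pytest.approx(phi.value, abs=1e-6), met.id

    def test_pooled_ignores_intra_pool_transfers(self, leaf_model, leaf_baseline):
        """Moving CO2 between compartments must not inflate the pool turnover:
        the pooled value is at most the sum of single-species values and the
        stomatal supply appears as a producer."""
        ids = [m.id for m in leaf_model.metabolites_by_role("co2")]
        pool = pooled_flux_sum(leaf_model, leaf_baseline.solution, ids)
        singles = sum(
            flux_sum(leaf_model, leaf_baseline.solution, i).value for i in ids
        )
        assert pool.value < singles
        assert "T_co2_ec" in pool.producer_breakdown


class TestCo2Attribution:
    def test_fractions_sum_to_one(self, leaf_model, leaf_baseline):
        att = co2_source_attribution(leaf_model, leaf_baseline.solution)
        assert sum(att.pathway_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_sole_producer_gets_fraction_one(self):
        model = make_model(
            {
                "EX_glc": ({"glc_e": -1.0}, -10.0, 0.0),
                "T_glc": ({"glc_e": -1.0, "glc": 1.0}, 0.0, 1000.0),
                "DECARB": ({"glc": -1.0, "co2": 6.0, "p": 1.0}, 0.0, 1000.0),
                "EX_co2": ({"co2": -1.0}, 0.0, 1000.0),
                "BIO": ({"p": -1.0}, 0.0, 1000.0),
            },
            externals=["glc_e"],
            objective={"BIO": 1.0},
        )
        model.reactions["DECARB"].pathway = "pentose_phosphate"
        model.metabolites["co2"].annotations["role"] = "co2"
        sol = solve_fba(model, canonical=True)
        att = co2_source_attribution(model, sol)
        assert att.pathway_fractions == pytest.approx({"pentose_phosphate": 1.0})

    def test_scaling_invariance(self, leaf_model, leaf_baseline):
        """Attribution fractions are invariant to uniform flux rescaling."""
        scaled = FluxSolution(
            fluxes={r: 3.0 * v for r, v in leaf_baseline.solution.fluxes.items()},
            objective_value=3.0 * leaf_baseline.solution.objective_value,
            status="optimal",
        )
        a = co2_source_attribution(leaf_model, leaf_baseline.solution)
        b = co2_source_attribution(leaf_model, scaled)
        assert b.pathway_fractions == pytest.approx(a.pathway_fractions, abs=1e-9)
        assert b.total_flux_sum == pytest.approx(3.0 * a.total_flux_sum, rel=1e-9)

    def test_missing_annotation_raises(self, toy_chain):
        sol = solve_fba(toy_chain)
        with pytest.raises(ValueError, match="role=co2"):
            co2_source_attribution(toy_chain, sol)


class TestEnergyTurnover:
    def test_self_consistency_with_flux_sum(self, leaf_model, leaf_baseline):
        report = energy_turnover_report(leaf_model, leaf_baseline.solution)
        for _, row in report.turnover.iterrows():
            ids = [
                m.id
                for m in leaf_model.metabolites_by_role(row["currency"])
                if m.compartment == row["compartment"]
            ]
            expected = sum(
                flux_sum(leaf_model, leaf_baseline.solution, i).value for i in ids
            )
            assert row["flux_sum"] == pytest.approx(expected, abs=1e-9)

    def test_compartment_without_currency_is_zero(self, leaf_model, leaf_baseline):
        report = energy_turnover_report(leaf_model, leaf_baseline.solution)
        # peroxisome has NADH but no ATP species at all
        atp_comps = set(
            report.turnover[report.turnover["currency"] == "atp"]["compartment"]
        )
        assert "x" not in atp_comps

    def test_fold_changes_against_baseline(self, leaf_model, leaf_baseline):
        pepc = run_pepc_elevation(leaf_model, 10.0, leaf_baseline)
        report = energy_turnover_report(
            leaf_model, pepc.solution, baseline=leaf_baseline.solution
        )
        assert {"baseline", "fold_change"} <= set(report.turnover.columns)
        shuttles = report.shuttles.set_index("role")
        assert "nadh_shuttle_hc" in shuttles.index
        assert "atp_shuttle_mc" in shuttles.index


def planted_setup(n, p, seed, magnitude=1.0):
    """A synthetic n-reaction model with single-gene GPRs, a +/- fold-change
    table, and expression whose sign agrees with probability p."""
    model = StoichiometricModel(id="synthetic_concordance")
    model.add_compartment("c")
    model.add_metabolite(Metabolite(id="x", compartment="c"))
    rng = np.random.default_rng(seed)
    rows, records = [], []
    for i in range(n):
        rid, gene = f"r{i}", f"g{i}"
        model.add_reaction(
            Reaction(id=rid, stoichiometry={"x": 1.0 if i % 2 else -1.0},
                     lower_bound=0, upper_bound=10, gpr=gene)
        )
        direction = 1 if rng.random() < 0.5 else -1
        rows.append({"reaction": rid, "flux": float(direction),
                     "baseline_flux": 1.0, "log2": float(direction),
                     "category": "up" if direction > 0 else "down"})
        agree = rng.random() < p
        sign = direction if agree else -direction
        records.append(ExpressionRecord(gene=gene, log2fc=sign * magnitude))
    return model, pd.DataFrame(rows), records


class TestConcordance:
    def test_perfect_agreement(self):
        model, fc, records = planted_setup(50, 1.0, seed=1)
        report = concordance(fc, records, model)
        assert report.agreement_fraction == 1.0
        assert report.n_comparable == 50

    def test_perfect_disagreement(self):
        model, fc, records = planted_setup(50, 0.0, seed=2)
        assert concordance(fc, records, model).agreement_fraction == 0.0

    @pytest.mark.parametrize("p", [0.5, 0.8])
    def test_planted_probability_recovered(self, p):
        model, fc, records = planted_setup(200, p, seed=7)
        report = concordance(fc, records, model)
        half_width = 1.96 * math.sqrt(p * (1 - p) / 200)
        assert abs(report.agreement_fraction - p) <= half_width

    def test_gene_order_invariance(self):
        model, fc, records = planted_setup(30, 0.8, seed=3)
        forward = concordance(fc, records, model)
        backward = concordance(fc, list(reversed(records)), model)
        assert forward.agreement_fraction == backward.agreement_fraction

    def test_duplicate_records_invariance(self):
        model, fc, records = planted_setup(30, 0.8, seed=4)
        single = concordance(fc, records, model)
        doubled = concordance(fc, records + records, model)
        assert doubled.agreement_fraction == single.agreement_fraction

    def test_unchanged_band_and_undetected_are_not_comparable(self):
        model, fc, records = planted_setup(10, 1.0, seed=5)
        records[0] = ExpressionRecord(gene="g0", log2fc=0.05)   # inside band
        records[1] = ExpressionRecord(gene="g1", log2fc=None, detected=False)
        report = concordance(fc, records, model)
        assert report.n_comparable == 8
        rows = report.rows.set_index("reaction")
        assert not rows.loc["r0", "comparable"]
        assert not rows.loc["r1", "comparable"]

    def test_undetected_gene_cannot_carry_value(self):
        with pytest.raises(ValueError):
            ExpressionRecord(gene="g", log2fc=1.0, detected=False)

    def test_drought_concordance_on_leaf_fixture(self, leaf_model, leaf_baseline):
        """End-to-end: drought fold changes vs planted perfectly-agreeing
        expression on the real GPRs gives full agreement."""
        from leafcbm.fixtures import synth_expression

        drought = run_drought(leaf_model, 0.5, leaf_baseline)
        fc = fold_change_table(drought, leaf_baseline)
        records = synth_expression(leaf_model, fc, agreement_p=1.0, seed=11)
        report = concordance(fc, records, leaf_model)
        assert report.n_comparable > 20
        # genes shared between reactions whose fluxes move in opposite
        # directions (e.g. the two electron-transport entry points) cannot
        # agree with both, so full agreement is capped just below 1
        assert report.agreement_fraction >= 0.95
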