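"""Post-solution analytics.

* **Flux-sum** — the turnover of a metabolite pool in a steady-state flux
  distribution, ``phi_i = 0.5 * sum_j |S_ij v_j|``.  At steady state the
  producing half equals the consuming half, so phi is both.
* **CO2 source attribution** — which pathways feed the intracellular CO2
  pool (all compartmental CO2 species combined), and how large that pool's
  turnover is.
* **Energy/redox turnover** — per-compartment flux-sums of ATP, NADH and
  NADPH plus the inter-compartment shuttle fluxes that move them.
* **Concordance** — sign agreement between predicted flux changes and
  measured gene-expression log2 fold changes, mapped through GPR rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fba import FluxSolution
from .model import StoichiometricModel

__all__ = [
    "FluxSumResult",
    "ExpressionRecord",
    "ConcordanceReport",
    "AttributionResult",
    "EnergyTurnoverReport",
    "flux_sum",
    "co2_source_attribution",
    "energy_turnover_report",
    "concordance",
    "read_expression_table",
]

FLUX_ATOL = 1e-9

#: inter-compartment carriers reported alongside currency turnover
SHUTTLE_ROLES = (
    "nadh_shuttle_hc",
    "nadh_shuttle_cm",
    "nadh_shuttle_cx",
    "atp_shuttle_mc",
)


# ---------------------------------------------------------------------------
# flux-sum
# ---------------------------------------------------------------------------

@dataclass
class FluxSumResult:
    """Turnover of one metabolite: phi = 0.5 * sum_j |S_ij v_j|."""

    metabolite: str
    value: float
    producer_breakdown: Dict[str, float] = field(default_factory=dict)
    consumer_breakdown: Dict[str, float] = field(default_factory=dict)

    @property
    def production(self) -> float:
        return sum(self.producer_breakdown.values())

    @property
    def consumption(self) -> float:
        return sum(self.consumer_breakdown.values())


def flux_sum(
    model: StoichiometricModel,
    solution: FluxSolution,
    metabolite: str,
) -> FluxSumResult:
    """Flux-sum of one species with producer/consumer breakdowns."""
    if metabolite not in model.metabolites:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    producers: Dict[str, float] = {}
    consumers: Dict[str, float] = {}
    total = 0.0
    for rxn in model.reactions.values():
        coef = rxn.stoichiometry.get(metabolite)
        if coef is None:
            continue
        term = coef * solution.fluxes[rxn.id]
        if abs(term) <= FLUX_ATOL:
            continue
        total += abs(term)
        if term > 0:
            producers[rxn.id] = term
        else:
            consumers[rxn.id] = -term
    return FluxSumResult(metabolite, 0.5 * total, producers, consumers)


def pooled_flux_sum(
    model: StoichiometricModel,
    solution: FluxSolution,
    metabolite_ids: Sequence[str],
) -> FluxSumResult:
    """Flux-sum of several species treated as one pool.

    Reactions are judged by their *net* coefficient over the pool, so
    transfers between pool members (e.g. CO2 diffusing between compartments)
    do not inflate the turnover.
    """
    pool = set(metabolite_ids)
    producers: Dict[str, float] = {}
    consumers: Dict[str, float] = {}
    total = 0.0
    for rxn in model.reactions.values():
        net = sum(c for m, c in rxn.stoichiometry.items() if m in pool)
        term = net * solution.fluxes[rxn.id]
        if abs(term) <= FLUX_ATOL:
            continue
        total += abs(term)
        if term > 0:
            producers[rxn.id] = term
        else:
            consumers[rxn.id] = -term
    return FluxSumResult("+".join(sorted(pool)), 0.5 * total, producers, consumers)


# ---------------------------------------------------------------------------
# CO2 source attribution
# ---------------------------------------------------------------------------

@dataclass
class AttributionResult:
    """Pathway shares of CO2 production plus the pool's total flux-sum."""

    total_flux_sum: float
    pathway_fractions: Dict[str, float]
    reaction_contributions: Dict[str, float]
    per_compartment: Dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.pathway_fractions.items()),
            columns=["pathway", "fraction"],
        )


def co2_source_attribution(
    model: StoichiometricModel,
    solution: FluxSolution,
) -> AttributionResult:
    """Attribute intracellular CO2 production to pathways.

    CO2 species are identified by metabolite annotation ``role=co2`` (one per
    compartment); atmospheric supply shows up under the ``transport``
    pathway of the stomatal diffusion step.
    """
    co2_ids = [m.id for m in model.metabolites_by_role("co2")]
    if not co2_ids:
        raise ValueError("model has no metabolites annotated role=co2")
    pool = pooled_flux_sum(model, solution, co2_ids)
    by_pathway: Dict[str, float] = {}
    for rid, contribution in pool.producer_breakdown.items():
        pathway = model.reactions[rid].pathway or "unassigned"
        by_pathway[pathway] = by_pathway.get(pathway, 0.0) + contribution
    production = sum(by_pathway.values())
    fractions = (
        {p: v / production for p, v in by_pathway.items()} if production > 0 else {}
    )
    per_compartment = {
        model.metabolites[mid].compartment: flux_sum(model, solution, mid).value
        for mid in co2_ids
    }
    return AttributionResult(
        total_flux_sum=pool.value,
        pathway_fractions=fractions,
        reaction_contributions=dict(pool.producer_breakdown),
        per_compartment=per_compartment,
    )


# ---------------------------------------------------------------------------
# energy / redox turnover
# ---------------------------------------------------------------------------

@dataclass
class EnergyTurnoverReport:
    turnover: pd.DataFrame  # currency, compartment, flux_sum [, baseline, fold_change]
    shuttles: pd.DataFrame  # role, reaction, flux [, baseline, fold_change]


def energy_turnover_report(
    model: StoichiometricModel,
    solution: FluxSolution,
    currencies: Sequence[str] = ("atp", "nadh", "nadph"),
    by_compartment: bool = True,
    baseline: Optional[FluxSolution] = None,
) -> EnergyTurnoverReport:
    """Per-compartment currency turnover (flux-sum) and shuttle fluxes.

    Currency species are found by metabolite annotation (``role=atp`` etc. on
    the energized form).  ``fold_change`` columns appear when a baseline
    solution is supplied; ratios use NaN where the baseline term is zero.
    """
    rows = []
    for currency in currencies:
        species = model.metabolites_by_role(currency)
        if not species:
            raise ValueError(f"model has no metabolites annotated role={currency}")
        compartments = sorted({m.compartment for m in species}) if by_compartment else [None]
        for comp in compartments:
            ids = [m.id for m in species if comp is None or m.compartment == comp]
            phi = sum(flux_sum(model, solution, i).value for i in ids)
            row = {
                "currency": currency,
                "compartment": comp or "all",
                "flux_sum": phi,
            }
            if baseline is not None:
                phi0 = sum(flux_sum(model, baseline, i).value for i in ids)
                row["baseline"] = phi0
                row["fold_change"] = phi / phi0 if phi0 > FLUX_ATOL else math.nan
            rows.append(row)
    turnover = pd.DataFrame(rows)

    srows = []
    for role in SHUTTLE_ROLES:
        for rxn in model.reactions_by_role(role):
            row = {"role": role, "reaction": rxn.id, "flux": solution.fluxes[rxn.id]}
            if baseline is not None:
                v0 = baseline.fluxes[rxn.id]
                row["baseline"] = v0
                row["fold_change"] = (
                    solution.fluxes[rxn.id] / v0 if abs(v0) > FLUX_ATOL else math.nan
                )
            srows.append(row)
    shuttles = pd.DataFrame(srows)
    return EnergyTurnoverReport(turnover=turnover, shuttles=shuttles)


# ---------------------------------------------------------------------------
# flux / expression concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's measured response (log2 fold change stress vs control)."""

    gene: str
    log2fc: Optional[float]
    detected: bool = True

    def __post_init__(self) -> None:
        if not self.detected and self.log2fc is not None:
            raise ValueError("undetected genes carry no log2fc")


@dataclass
class ConcordanceReport:
    rows: pd.DataFrame
    agreement_fraction: float

    @property
    def n_comparable(self) -> int:
        return int(self.rows["comparable"].sum())


def _direction(value: float, band: float) -> int:
    if value > band:
        return 1
    if value < -band:
        return -1
    return 0


def read_expression_table(path) -> List[ExpressionRecord]:
    """Read a gene/log2fc/detected TSV into expression records."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "log2fc" not in df.columns:
        raise ValueError("expression table needs columns: gene, log2fc[, detected]")
    records = []
    for _, row in df.iterrows():
        detected = bool(row["detected"]) if "detected" in df.columns else True
        detected = detected and not pd.isna(row["log2fc"])
        records.append(
            ExpressionRecord(
                gene=str(row["gene"]),
                log2fc=float(row["log2fc"]) if detected else None,
                detected=detected,
            )
        )
    return records


def concordance(
    fold_changes: pd.DataFrame,
    expression: Iterable[ExpressionRecord],
    model: StoichiometricModel,
    unchanged_band: float = 0.1,
) -> ConcordanceReport:
    """Compare predicted flux-change signs with expression signs per reaction.

    ``fold_changes`` is the table from
    :func:`leafcbm.scenarios.fold_change_table` (columns ``reaction``,
    ``log2``, ``category``).  A reaction's expression direction is the sign
    of the mean log2FC over its detected GPR genes, with ``|mean| <=
    unchanged_band`` treated as unchanged.  Reactions without a GPR, without
    any detected gene, or with an unchanged side are not comparable; the
    agreement fraction is computed over comparable rows only.
    """
    expr: Dict[str, float] = {}
    detected: Dict[str, bool] = {}
    for rec in expression:
        # duplicates of identical records collapse; conflicting duplicates average
        if rec.gene in expr and rec.detected:
            expr[rec.gene] = (expr[rec.gene] + rec.log2fc) / 2.0
        elif rec.detected:
            expr[rec.gene] = rec.log2fc
        detected[rec.gene] = detected.get(rec.gene, False) or rec.detected

    categories = {"up": 1, "down": -1, "unchanged": 0, "inactive-both": 0}
    rows = []
    for _, fc in fold_changes.iterrows():
        rid = fc["reaction"]
        rxn = model.reactions.get(rid)
        if rxn is None:
            continue
        genes = rxn.genes()
        gene_fcs = [expr[g] for g in genes if detected.get(g, False)]
        predicted = categories.get(str(fc["category"]), _direction(fc["log2"], 0.0))
        if not genes or not gene_fcs:
            expression_dir: Optional[int] = None
            mean_fc = math.nan
        else:
            mean_fc = float(np.mean(gene_fcs))
            expression_dir = _direction(mean_fc, unchanged_band)
        comparable = (
            expression_dir is not None and expression_dir != 0 and predicted != 0
        )
        agrees = (predicted == expression_dir) if comparable else None
        rows.append(
            {
                "reaction": rid,
                "predicted_direction": predicted,
                "expression_mean_log2fc": mean_fc,
                "expression_direction": expression_dir,
                "comparable": comparable,
                "agrees": agrees,
            }
        )
    frame = pd.DataFrame(rows)
    comp = frame[frame["comparable"]]
    fraction = float(comp["agrees"].mean()) if len(comp) else math.nan
    return ConcordanceReport(rows=frame, agreement_fraction=fraction)
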