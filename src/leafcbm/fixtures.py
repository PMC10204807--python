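"""The packaged core leaf model and synthetic expression data.

:func:`build_fixture_leaf_model` assembles a curated mesophyll-cell network
(:mod:`leafcbm._leaf_network`) into a ready-to-solve
:class:`~leafcbm.model.StoichiometricModel`:

* four internal compartments (cytosol, chloroplast, mitochondrion,
  peroxisome) plus the external pool, all ten core pathway tags, and the
  C4-module reactions (carbonic anhydrase, PEPC, PEPCK, NADP-/NAD-malic
  enzyme, PPDK) present in a C3 leaf;
* RuBisCO as separate carboxylase/oxygenase steps with the full glycolate
  route through peroxisome and mitochondrion, GDC releasing CO2 and NH3, and
  GS/GOGAT refixation (free NH3 export is closed by default);
* photon uptake bounded by net photosynthesis / light-use efficiency, net
  CO2 uptake fixed at the measured rate, a fixed cytosolic maintenance ATP
  drain, and a biomass reaction assembled from the configured carbohydrate /
  protein / fiber / lipid mass fractions.

Model generation itself is fully deterministic; the only randomness in this
module is :func:`synth_expression`, which plants a known flux/expression
agreement probability for testing the concordance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

from . import _leaf_network as net
from .analysis import ExpressionRecord
from .model import Metabolite, Reaction, StoichiometricModel, parse_formula
from .io import parse_equation

__all__ = ["FixtureConfig", "build_fixture_leaf_model", "synth_expression"]

ATOMIC_WEIGHTS = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06,
}

#: biomass precursor pools: component -> metabolite id
BIOMASS_POOLS = {
    "carbohydrate": "carbpool_c",
    "protein": "protpool_c",
    "fiber": "cellulose_c",
    "lipid": "palm_c",
}


def molecular_weight(formula: str) -> float:
    return sum(ATOMIC_WEIGHTS[e] * n for e, n in parse_formula(formula).items())


@dataclass
class FixtureConfig:
    """Study conditions of the core leaf model.

    Units: ``net_photosynthesis`` in mmol CO2/gDW/day, ``lue`` in mol CO2
    fixed per mol photons absorbed, ``maintenance_atp`` in mmol/gDW/day.
    The default biomass composition (carbohydrate 0.55, protein 0.20, fiber
    0.17, lipid 0.08 by mass) is a curator's stand-in for a measured leaf
    composition, overridable per study.
    """

    biomass_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "carbohydrate": 0.55,
            "protein": 0.20,
            "fiber": 0.17,
            "lipid": 0.08,
        }
    )
    lue: float = 0.05
    net_photosynthesis: float = 10.0
    maintenance_atp: float = 7.5
    vc_vo_default: float = 3.0
    malate_valve_capacity: float = 0.5
    co2_transfer_capacity: Optional[float] = None  # default: 1.4 * P_N
    seed: int = 2023

    def validate(self) -> None:
        missing = set(BIOMASS_POOLS) - set(self.biomass_fractions)
        if missing:
            raise ValueError(f"biomass fractions missing components: {sorted(missing)}")
        total = sum(self.biomass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biomass fractions must sum to 1 (got {total})")
        for name, value in [
            ("lue", self.lue),
            ("net_photosynthesis", self.net_photosynthesis),
            ("maintenance_atp", self.maintenance_atp),
            ("vc_vo_default", self.vc_vo_default),
            ("malate_valve_capacity", self.malate_valve_capacity),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")


def build_fixture_leaf_model(config: Optional[FixtureConfig] = None) -> StoichiometricModel:
    """Assemble the core leaf model under the configured study conditions."""
    config = config or FixtureConfig()
    config.validate()

    model = StoichiometricModel(id="leaf_core", name="core C3 leaf carbon metabolism")
    for cid, cname in net.COMPARTMENTS.items():
        model.add_compartment(cid, cname)
    for mid, name, comp, formula, role in net.METABOLITES:
        ann = {"role": role} if role else {}
        model.add_metabolite(
            Metabolite(id=mid, name=name, compartment=comp, formula=formula,
                       annotations=ann)
        )
    for rid, name, equation, lb, ub, gpr, pathway, ec, role in net.REACTIONS:
        stoich, reversible = parse_equation(equation)
        lb = lb if lb is not None else (-1000.0 if reversible else 0.0)
        ub = ub if ub is not None else 1000.0
        ann = {"role": role} if role else {}
        model.add_reaction(
            Reaction(id=rid, name=name, stoichiometry=stoich, lower_bound=lb,
                     upper_bound=ub, gpr=gpr, pathway=pathway, ec_number=ec,
                     annotations=ann)
        )

    # biomass: mass fractions -> mmol precursor per g biomass
    stoich: Dict[str, float] = {}
    for component, met_id in BIOMASS_POOLS.items():
        fraction = config.biomass_fractions[component]
        mw = molecular_weight(model.metabolites[met_id].formula)
        stoich[met_id] = -1000.0 * fraction / mw
    model.add_reaction(
        Reaction(
            id="BIOMASS_leaf",
            name="leaf biomass synthesis (g biomass per gDW)",
            stoichiometry=stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
            pathway="biomass",
            annotations={"role": "biomass"},
        )
    )
    model.objective = {"BIOMASS_leaf": 1.0}

    # study conditions
    model.set_uptake_bound("EX_co2", config.net_photosynthesis, fix=True)
    model.set_uptake_bound("EX_photon", config.net_photosynthesis / config.lue)
    maint = model.reactions["MAINT_m"]
    maint.lower_bound = maint.upper_bound = config.maintenance_atp
    # the NADP-MDH malate valve is light/thioredoxin-modulated; give it a
    # finite capacity so photosynthetic reductant cannot substitute freely
    # for dark respiration
    valve = model.reactions["MDH_NADP_h"]
    valve.lower_bound = -config.malate_valve_capacity
    valve.upper_bound = config.malate_valve_capacity
    # finite mesophyll conductance: gas-phase CO2 delivery into the stroma
    # has a ceiling even with stomata fully open
    transfer = model.reactions["T_co2_ch"]
    transfer.upper_bound = (
        config.co2_transfer_capacity
        if config.co2_transfer_capacity is not None
        else 1.4 * config.net_photosynthesis
    )

    model.annotations.update(
        {
            "lue": repr(config.lue),
            "net_photosynthesis": repr(config.net_photosynthesis),
            "maintenance_atp": repr(config.maintenance_atp),
            "vc_vo_default": repr(config.vc_vo_default),
        }
    )
    return model


def synth_expression(
    model: StoichiometricModel,
    flux_fold_changes: pd.DataFrame,
    agreement_p: float,
    seed: int,
    magnitude_mu: float = -0.35,
    magnitude_sigma: float = 0.6,
    unchanged_band: float = 0.1,
) -> List[ExpressionRecord]:
    """Synthesize per-gene expression with a planted agreement probability.

    For every gene in a reaction's GPR, the emitted log2FC sign matches the
    reaction's flux-change sign with probability ``agreement_p`` (flipped
    otherwise); magnitudes are log-normal (parameters in natural-log space)
    shifted outside the unchanged band so the sign is always classifiable.
    Genes of reactions with an unchanged/inactive flux get magnitudes inside
    the band.  Deterministic for a fixed seed.
    """
    if not 0.0 <= agreement_p <= 1.0:
        raise ValueError("agreement_p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    categories = {"up": 1, "down": -1}
    records: List[ExpressionRecord] = []
    seen: set = set()
    for _, row in flux_fold_changes.iterrows():
        rxn = model.reactions.get(row["reaction"])
        if rxn is None:
            continue
        direction = categories.get(str(row["category"]), 0)
        for gene in rxn.genes():
            if gene in seen:
                continue
            seen.add(gene)
            magnitude = float(rng.lognormal(magnitude_mu, magnitude_sigma))
            if direction == 0:
                records.append(
                    ExpressionRecord(
                        gene=gene,
                        log2fc=float(rng.uniform(-0.5, 0.5)) * unchanged_band,
                    )
                )
                continue
            sign = direction if rng.random() < agreement_p else -direction
            records.append(
                ExpressionRecord(gene=gene,
                                 log2fc=sign * (unchanged_band + magnitude))
            )
    return records
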