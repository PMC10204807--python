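"""Core domain types for compartmentalized stoichiometric models.

A :class:`StoichiometricModel` is a plain in-memory description of a metabolic
network: compartments, metabolites, reactions with bounds and gene-protein-
reaction (GPR) rules, and a linear objective.  It is deliberately independent
of any solver; :mod:`leafcbm.fba` converts it to a COBRApy model when a linear
program has to be solved.

Sign conventions
----------------
Consumed metabolites carry negative stoichiometric coefficients.  Exchange
reactions are written export-positive: a positive flux moves the species out
of the system, so uptake lives in the negative flux range of the exchange
(``set_uptake_bound`` is the helper that sets it).  Fluxes are expressed in
mmol/gDW/day throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "Diagnostic",
    "validate_model",
    "parse_formula",
    "DEFAULT_BOUND",
    "PATHWAY_TAGS",
]

#: Default magnitude used for "freely exchanged" species.  Effectively
#: unbounded at leaf-flux scale while keeping every LP bounded.
DEFAULT_BOUND = 1000.0

#: The ten core pathway tags of the leaf model, plus structural categories.
PATHWAY_TAGS = frozenset(
    {
        "light_reactions",
        "calvin_cycle",
        "photorespiration",
        "respiration",
        "pentose_phosphate",
        "nitrogen_assimilation",
        "starch_sucrose",
        "amino_acid",
        "cell_wall",
        "fatty_acid",
        # structural / auxiliary categories
        "c4_cycle",
        "transport",
        "exchange",
        "biomass",
        "maintenance",
    }
)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*(?:\.\d+)?)")


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse an elemental formula string (e.g. ``C6H12O6``) into counts."""
    if not formula:
        return {}
    counts: Dict[str, float] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at {pos}")
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0.0) + (float(num) if num else 1.0)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at {pos}")
    return counts


@dataclass
class Metabolite:
    """A chemical species located in one compartment.

    ``annotations`` carries free-form role tags (e.g. ``role="co2"`` or
    ``role="atp"``) used by the analysis layer to identify gas and currency
    species without relying on identifier spelling.
    """

    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None
    is_boundary: bool = False
    annotations: Dict[str, str] = field(default_factory=dict)

    def elements(self) -> Dict[str, float]:
        return parse_formula(self.formula or "")

    @property
    def role(self) -> Optional[str]:
        return self.annotations.get("role")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional GPR."""

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    pathway: str = ""
    ec_number: str = ""
    annotations: Dict[str, str] = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound

    @property
    def role(self) -> Optional[str]:
        return self.annotations.get("role")

    def genes(self) -> List[str]:
        """Gene identifiers mentioned in the GPR rule, in rule order."""
        if not self.gpr:
            return []
        tokens = re.split(r"[()\s]+", self.gpr)
        seen: List[str] = []
        for tok in tokens:
            if tok and tok.lower() not in {"and", "or"} and tok not in seen:
                seen.append(tok)
        return seen

    def equation(self, arrow_rev: str = "<->", arrow_irr: str = "->") -> str:
        """Render the reaction as a human-readable equation string."""

        def side(items: Iterable[Tuple[str, float]]) -> str:
            parts = []
            for met, coef in items:
                coef = abs(coef)
                if math.isclose(coef, 1.0):
                    parts.append(met)
                else:
                    num = f"{coef:g}"
                    parts.append(f"{num} {met}")
            return " + ".join(parts)

        subs = sorted((m, c) for m, c in self.stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)
        arrow = arrow_rev if self.lower_bound < 0 else arrow_irr
        return f"{side(subs)} {arrow} {side(prods)}".strip()


@dataclass(frozen=True)
class Diagnostic:
    """One structural problem found by :func:`validate_model`."""

    entity: str
    rule: str
    message: str

    def to_json(self) -> Dict[str, str]:
        return {"entity": self.entity, "rule": self.rule, "message": self.message}


class StoichiometricModel:
    """A compartmentalized metabolic network with bounds and an objective."""

    def __init__(
        self,
        id: str = "model",
        name: str = "",
        external_compartment: str = "e",
    ) -> None:
        self.id = id
        self.name = name or id
        self.compartments: Dict[str, str] = {}
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.objective: Dict[str, float] = {}
        self.annotations: Dict[str, str] = {}
        self.external_compartment = external_compartment

    # -- construction -----------------------------------------------------
    def add_compartment(self, cid: str, name: str = "") -> None:
        self.compartments[cid] = name or cid

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn
        return rxn

    def copy(self) -> "StoichiometricModel":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- queries ----------------------------------------------------------
    def is_external(self, met: Metabolite) -> bool:
        return met.compartment == self.external_compartment

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.pathway == "exchange"]

    def reactions_by_role(self, role: str) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.role == role]

    def reaction_by_role(self, role: str) -> Reaction:
        hits = self.reactions_by_role(role)
        if not hits:
            raise KeyError(f"no reaction annotated with role={role!r}")
        if len(hits) > 1:
            raise KeyError(f"role {role!r} is ambiguous: {[r.id for r in hits]}")
        return hits[0]

    def metabolites_by_role(self, role: str) -> List[Metabolite]:
        return [m for m in self.metabolites.values() if m.role == role]

    def genes(self) -> List[str]:
        out: List[str] = []
        for rxn in self.reactions.values():
            for g in rxn.genes():
                if g not in out:
                    out.append(g)
        return out

    # -- numeric views ----------------------------------------------------
    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S with one row per non-boundary metabolite, one column per
        reaction.  Returns ``(S, metabolite_ids, reaction_ids)``."""
        met_ids = [m.id for m in self.metabolites.values() if not m.is_boundary]
        rxn_ids = list(self.reactions)
        index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met, coef in self.reactions[rid].stoichiometry.items():
                if met in index:
                    S[index[met], j] = coef
        return S, met_ids, rxn_ids

    def bounds_arrays(self, rxn_ids: Optional[List[str]] = None):
        rxn_ids = rxn_ids or list(self.reactions)
        lb = np.array([self.reactions[r].lower_bound for r in rxn_ids])
        ub = np.array([self.reactions[r].upper_bound for r in rxn_ids])
        return lb, ub

    # -- bound helpers -----------------------------------------------------
    def set_uptake_bound(self, reaction_id: str, rate: float, fix: bool = False) -> None:
        """Allow uptake of at most ``rate`` through an export-positive
        exchange; with ``fix=True`` the net uptake is pinned to ``rate``."""
        if rate < 0:
            raise ValueError("uptake rate must be non-negative")
        rxn = self.reactions[reaction_id]
        rxn.lower_bound = -rate
        if fix:
            rxn.upper_bound = -rate
        elif rxn.upper_bound < 0:  # clear a stale uptake demand
            rxn.upper_bound = 0.0

    def reaction_balance(self, rxn: Reaction, elements: Iterable[str]) -> Dict[str, float]:
        """Net elemental balance of a reaction (products minus substrates)."""
        net: Dict[str, float] = {e: 0.0 for e in elements}
        for met_id, coef in rxn.stoichiometry.items():
            counts = self.metabolites[met_id].elements()
            for e in net:
                net[e] += coef * counts.get(e, 0.0)
        return net

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StoichiometricModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.compartments)} compartments>"
        )


#: Elements checked for balance.  Hydrogen and oxygen are left unchecked
#: because protons and water are omitted from several lumped reactions.
BALANCED_ELEMENTS = ("C", "N", "P", "S")


def validate_model(
    model: StoichiometricModel,
    elements: Iterable[str] = BALANCED_ELEMENTS,
    tol: float = 1e-6,
) -> List[Diagnostic]:
    """Structural validation.  Returns an empty list iff all invariants hold.

    Checks: compartment membership, bound ordering, non-empty stoichiometry,
    dangling metabolite references, exchange shape (exactly one non-boundary
    species), objective references, and — where elemental formulas are present
    — per-reaction elemental balance for internal (non-exchange, non-pseudo)
    reactions.
    """
    diags: List[Diagnostic] = []

    for met in model.metabolites.values():
        if met.compartment not in model.compartments:
            diags.append(
                Diagnostic(met.id, "compartment-exists",
                           f"metabolite {met.id} in unknown compartment {met.compartment!r}")
            )

    for rxn in model.reactions.values():
        if rxn.lower_bound > rxn.upper_bound:
            diags.append(
                Diagnostic(rxn.id, "bound-order",
                           f"lower bound {rxn.lower_bound} > upper bound {rxn.upper_bound}")
            )
        if not rxn.stoichiometry:
            diags.append(Diagnostic(rxn.id, "stoichiometry-nonempty", "empty stoichiometry"))
            continue
        dangling = [m for m in rxn.stoichiometry if m not in model.metabolites]
        if dangling:
            diags.append(
                Diagnostic(rxn.id, "metabolite-exists",
                           f"references unknown metabolites: {', '.join(sorted(dangling))}")
            )
            continue
        if rxn.pathway == "exchange":
            touched = [m for m in rxn.stoichiometry
                       if not model.metabolites[m].is_boundary]
            if len(touched) != 1:
                diags.append(
                    Diagnostic(rxn.id, "exchange-shape",
                               f"exchange touches {len(touched)} non-boundary metabolites")
                )
        elif rxn.pathway not in {"biomass", "maintenance"}:
            # Elemental balance only when every participant has a formula.
            mets = [model.metabolites[m] for m in rxn.stoichiometry]
            if all(m.formula for m in mets):
                net = model.reaction_balance(rxn, elements)
                for element, value in net.items():
                    if abs(value) > tol:
                        diags.append(
                            Diagnostic(rxn.id, "element-balance",
                                       f"element {element} imbalanced by {value:+g}")
                        )

    for rid in model.objective:
        if rid not in model.reactions:
            diags.append(
                Diagnostic(rid, "objective-reference",
                           f"objective references unknown reaction {rid!r}")
            )

    return diags
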