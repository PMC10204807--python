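"""Network connectivity checks: dead-end metabolites and blocked reactions.

Mirrors the detection half of the GapFind family of methods: species that
cannot be produced or consumed under the directionality allowed by the flux
bounds, and reactions whose feasible flux range is exactly {0} once every
exchange is opened.  Gap *filling* is deliberately out of scope — curation
of a real model is a manual act.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .fba import FEASIBILITY_TOL, FBAProblem, InfeasibleProblemError, ObjectiveSpec
from .model import DEFAULT_BOUND, StoichiometricModel

__all__ = ["GapReport", "find_gaps", "find_dead_end_metabolites", "find_blocked_reactions"]


@dataclass
class GapReport:
    dead_end_metabolites: List[str] = field(default_factory=list)
    blocked_reactions: List[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.dead_end_metabolites and not self.blocked_reactions


def _producible_consumable(model: StoichiometricModel) -> Dict[str, Tuple[bool, bool]]:
    status: Dict[str, Tuple[bool, bool]] = {
        m.id: (False, False)
        for m in model.metabolites.values()
        if not m.is_boundary and not model.is_external(m)
    }
    for rxn in model.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met, coef in rxn.stoichiometry.items():
            if met not in status:
                continue
            produced, consumed = status[met]
            if coef > 0:
                produced = produced or fwd
                consumed = consumed or rev
            elif coef < 0:
                consumed = consumed or fwd
                produced = produced or rev
            status[met] = (produced, consumed)
    return status


def find_dead_end_metabolites(model: StoichiometricModel) -> List[str]:
    """Internal species lacking a producer or a consumer under the bound
    directionality (root no-production/no-consumption gaps)."""
    out = []
    for met, (produced, consumed) in _producible_consumable(model).items():
        if not (produced and consumed):
            out.append(met)
    return sorted(out)


def find_blocked_reactions(
    model: StoichiometricModel,
    open_exchanges: bool = True,
    tol: float = FEASIBILITY_TOL,
) -> List[str]:
    """Reactions whose flux range is {0} under flux variability.

    With ``open_exchanges`` every exchange reaction is relaxed to the default
    bounds first, so blockage reflects network structure rather than the
    scenario bounds of the moment.
    """
    work = model.copy()
    if open_exchanges:
        for rxn in work.exchanges():
            rxn.lower_bound = -DEFAULT_BOUND
            rxn.upper_bound = DEFAULT_BOUND
    # a zero objective keeps FVA from imposing any optimality restriction
    first = next(iter(work.reactions))
    prob = FBAProblem(work, ObjectiveSpec({first: 0.0}, "maximize"))
    ranges = prob.flux_variability(fraction_of_optimum=0.0)
    return sorted(
        rid for rid, (lo, hi) in ranges.items() if abs(lo) <= tol and abs(hi) <= tol
    )


def find_gaps(model: StoichiometricModel) -> GapReport:
    """Dead-end metabolites and blocked reactions of a validated model."""
    return GapReport(
        dead_end_metabolites=find_dead_end_metabolites(model),
        blocked_reactions=find_blocked_reactions(model),
    )
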