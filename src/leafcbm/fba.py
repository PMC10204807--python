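"""Flux balance analysis: LP formulation, ratio coupling, canonical fluxes.

The optimization is the classic FBA linear program

    max  c . v     subject to   S v = 0,   LB <= v <= UB

optionally extended with ratio equalities ``v_num - r * v_den = 0`` (used to
pin the RuBisCO carboxylation/oxygenation ratio Vc/Vo).  Because FBA optima
are generally degenerate in individual fluxes, reported per-reaction values
are taken from the *canonical* solution: the flux vector of minimum total
absolute flux among all optima (parsimonious FBA).  Solving goes through
COBRApy with the GLPK backend, which is deterministic on a fixed problem.

Tolerances: steady-state feasibility 1e-6, optimality fixing 1e-9 relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io import to_cobra
from .model import StoichiometricModel

__all__ = [
    "ObjectiveSpec",
    "RatioConstraint",
    "FluxSolution",
    "FBAProblem",
    "solve_fba",
    "canonicalize",
    "flux_variability",
    "apply_ratio_constraint",
    "set_photon_constraint",
    "steady_state_residual",
    "InfeasibleProblemError",
    "FEASIBILITY_TOL",
    "OPTIMALITY_TOL",
]

FEASIBILITY_TOL = 1e-6
OPTIMALITY_TOL = 1e-9
SOLVER = "glpk"


class InfeasibleProblemError(RuntimeError):
    """The LP has no feasible point under the given constraints."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """Linear objective ``sense sum_j coefficients[j] * v_j``."""

    coefficients: Mapping[str, float]
    sense: str = "maximize"

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("objective must reference at least one reaction")
        if self.sense not in {"maximize", "minimize"}:
            raise ValueError(f"unknown sense {self.sense!r}")

    @classmethod
    def from_model(cls, model: StoichiometricModel) -> "ObjectiveSpec":
        return cls(dict(model.objective), "maximize")


@dataclass(frozen=True)
class RatioConstraint:
    """Linear coupling ``v_numerator = ratio * v_denominator``.

    Used for the carboxylation/oxygenation (Vc/Vo) coupling; both operand
    reactions must be irreversible so the equality through zero is sound.
    """

    numerator_reaction: str
    denominator_reaction: str
    ratio: float

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("ratio must be positive")


@dataclass
class FluxSolution:
    """An LP solution: fluxes (mmol/gDW/day), objective value and status."""

    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_value: float = math.nan
    status: str = "infeasible"
    canonicalized: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def total_flux(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))


def _check_ratio_constraint(model: StoichiometricModel, rc: RatioConstraint) -> None:
    for rid in (rc.numerator_reaction, rc.denominator_reaction):
        if rid not in model.reactions:
            raise KeyError(f"ratio constraint references unknown reaction {rid!r}")
        if model.reactions[rid].lower_bound < 0:
            raise ValueError(
                f"ratio constraint operand {rid!r} is reversible; "
                "couple only irreversible reactions"
            )


class FBAProblem:
    """A solver-backed handle for one model plus extra linear constraints.

    Thin stateful wrapper over a COBRApy model: constraints added through
    :meth:`apply_ratio_constraint` persist for subsequent solves, which is
    what scenario runs need (apply once, solve baseline and variants).
    """

    def __init__(
        self,
        model: StoichiometricModel,
        objective: Optional[ObjectiveSpec] = None,
        solver: str = SOLVER,
    ) -> None:
        self.model = model
        self.objective = objective or ObjectiveSpec.from_model(model)
        self.cobra_model = to_cobra(model)
        self.cobra_model.solver = solver
        self.cobra_model.tolerance = FEASIBILITY_TOL
        self._set_objective(self.objective)
        self.ratio_constraints: List[RatioConstraint] = []

    # -- constraint management -------------------------------------------
    def _set_objective(self, spec: ObjectiveSpec) -> None:
        cm = self.cobra_model
        for rid in spec.coefficients:
            if rid not in self.model.reactions:
                raise KeyError(f"objective references unknown reaction {rid!r}")
        cm.objective = {
            cm.reactions.get_by_id(rid): coef for rid, coef in spec.coefficients.items()
        }
        cm.objective_direction = "max" if spec.sense == "maximize" else "min"

    def apply_ratio_constraint(self, rc: RatioConstraint) -> "FBAProblem":
        _check_ratio_constraint(self.model, rc)
        cm = self.cobra_model
        num = cm.reactions.get_by_id(rc.numerator_reaction)
        den = cm.reactions.get_by_id(rc.denominator_reaction)
        cons = cm.problem.Constraint(
            num.flux_expression - rc.ratio * den.flux_expression,
            lb=0.0,
            ub=0.0,
            name=f"ratio_{rc.numerator_reaction}_{rc.denominator_reaction}",
        )
        cm.add_cons_vars(cons)
        self.ratio_constraints.append(rc)
        return self

    def set_bounds(self, reaction_id: str, lb: float, ub: float) -> "FBAProblem":
        rxn = self.cobra_model.reactions.get_by_id(reaction_id)
        rxn.bounds = (lb, ub)
        return self

    # -- solving ----------------------------------------------------------
    def _harvest(self, canonicalized: bool) -> FluxSolution:
        cm = self.cobra_model
        fluxes = {r.id: float(r.flux) for r in cm.reactions}
        obj = float(
            sum(
                coef * fluxes[rid]
                for rid, coef in self.objective.coefficients.items()
            )
        )
        return FluxSolution(fluxes=fluxes, objective_value=obj, status="optimal",
                            canonicalized=canonicalized)

    def solve(self, canonical: bool = True) -> FluxSolution:
        """Optimize; with ``canonical`` also minimize total absolute flux at
        the optimum so per-reaction fluxes are well defined."""
        cm = self.cobra_model
        value = cm.slim_optimize(error_value=math.nan)
        status = cm.solver.status
        if math.isnan(value) or status != "optimal":
            return FluxSolution(status="infeasible" if status != "unbounded" else "unbounded")
        if not canonical:
            return self._harvest(canonicalized=False)

        # stage 2: fix the achieved objective, minimize sum |v|
        from optlang.symbolics import Zero

        direction = cm.objective_direction
        bound = value - OPTIMALITY_TOL * max(1.0, abs(value))
        if direction == "min":
            bound = value + OPTIMALITY_TOL * max(1.0, abs(value))
        fix = cm.problem.Constraint(
            cm.objective.expression,
            lb=bound if direction == "max" else None,
            ub=bound if direction == "min" else None,
            name="objective_fixed",
        )
        old_objective = cm.objective.expression
        cm.add_cons_vars(fix)
        try:
            cm.objective = cm.problem.Objective(Zero, direction="min", sloppy=True)
            coefs = {}
            for r in cm.reactions:
                coefs[r.forward_variable] = 1.0
                coefs[r.reverse_variable] = 1.0
            cm.objective.set_linear_coefficients(coefs)
            value2 = cm.slim_optimize(error_value=math.nan)
            if math.isnan(value2) or cm.solver.status != "optimal":  # pragma: no cover
                raise InfeasibleProblemError("canonicalization stage failed")
            sol = self._harvest(canonicalized=True)
        finally:
            cm.remove_cons_vars(fix)
            cm.objective = old_objective
            cm.objective_direction = direction
        return sol

    def flux_variability(self, fraction_of_optimum: float = 1.0):
        """Per-reaction [min, max] flux with objective >= fraction * Z*."""
        if not 0.0 <= fraction_of_optimum <= 1.0:
            raise ValueError("fraction_of_optimum must be in [0, 1]")
        from cobra.flux_analysis import flux_variability_analysis

        cm = self.cobra_model
        if math.isnan(cm.slim_optimize(error_value=math.nan)):
            raise InfeasibleProblemError(
                f"base problem infeasible (fraction={fraction_of_optimum})"
            )
        fva = flux_variability_analysis(
            cm, fraction_of_optimum=fraction_of_optimum, processes=1
        )
        return {
            rid: (float(row["minimum"]), float(row["maximum"]))
            for rid, row in fva.iterrows()
        }


# ---------------------------------------------------------------------------
# functional front-ends
# ---------------------------------------------------------------------------

def solve_fba(
    model: StoichiometricModel,
    objective: Optional[ObjectiveSpec] = None,
    ratio_constraints: Sequence[RatioConstraint] = (),
    canonical: bool = False,
) -> FluxSolution:
    """Solve max/min c.v subject to S v = 0, bounds and ratio equalities."""
    prob = FBAProblem(model, objective)
    for rc in ratio_constraints:
        prob.apply_ratio_constraint(rc)
    return prob.solve(canonical=canonical)


def canonicalize(
    model: StoichiometricModel,
    solution: FluxSolution,
    objective: Optional[ObjectiveSpec] = None,
    ratio_constraints: Sequence[RatioConstraint] = (),
) -> FluxSolution:
    """Minimum-total-flux representative of the optimum in ``solution``.

    The objective value is preserved to 1e-9 relative; the returned vector
    minimizes sum_j |v_j| subject to the original constraints.
    """
    if not solution.optimal:
        raise ValueError("can only canonicalize an optimal solution")
    return solve_fba(model, objective, ratio_constraints, canonical=True)


def flux_variability(
    model: StoichiometricModel,
    objective: Optional[ObjectiveSpec] = None,
    fraction_of_optimum: float = 1.0,
    ratio_constraints: Sequence[RatioConstraint] = (),
) -> Dict[str, Tuple[float, float]]:
    prob = FBAProblem(model, objective)
    for rc in ratio_constraints:
        prob.apply_ratio_constraint(rc)
    return prob.flux_variability(fraction_of_optimum)


def apply_ratio_constraint(problem: FBAProblem, rc: RatioConstraint) -> FBAProblem:
    """Attach ``v_num = r * v_den`` to a problem handle (see FBAProblem)."""
    return problem.apply_ratio_constraint(rc)


def set_photon_constraint(
    model: StoichiometricModel,
    net_photosynthesis: float,
    lue: float,
) -> StoichiometricModel:
    """Bound photon uptake by ``net_photosynthesis / lue``.

    ``lue`` is the light-use efficiency in mol CO2 fixed per mol photons, so
    a measured net CO2 assimilation rate translates into the photon flux the
    leaf can have absorbed at most.
    """
    if lue <= 0:
        raise ValueError("light use efficiency must be positive")
    if net_photosynthesis < 0:
        raise ValueError("net photosynthesis must be non-negative")
    try:
        rxn = model.reaction_by_role("photon_exchange")
    except KeyError as exc:
        raise KeyError("model has no reaction annotated role=photon_exchange") from exc
    model.set_uptake_bound(rxn.id, net_photosynthesis / lue)
    rxn.upper_bound = 0.0  # photons are not exported
    return model


def steady_state_residual(model: StoichiometricModel, solution: FluxSolution) -> float:
    """max_i |(S v)_i| over non-boundary metabolites."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = np.array([solution.fluxes[r] for r in rxn_ids])
    if S.size == 0:
        return 0.0
    return float(np.max(np.abs(S @ v)))
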