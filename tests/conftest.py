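"""Shared fixtures: toy models, random models, and an independent LP oracle.

The oracle solves the same linear programs as the package but through a
completely separate code path: dense matrices assembled by hand and
scipy.optimize.linprog with the HiGHS backend (the package uses COBRApy on
GLPK), so agreement is a genuine cross-check.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pytest
import scipy.optimize

from leafcbm.fba import RatioConstraint
from leafcbm.fixtures import FixtureConfig, build_fixture_leaf_model
from leafcbm.model import Metabolite, Reaction, StoichiometricModel
from leafcbm.scenarios import run_baseline


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

def make_model(
    reactions: Dict[str, Tuple[Dict[str, float], float, float]],
    externals: Sequence[str] = (),
    objective: Optional[Dict[str, float]] = None,
    formulas: Optional[Dict[str, str]] = None,
) -> StoichiometricModel:
    """Compact model builder: reaction id -> (stoichiometry, lb, ub)."""
    model = StoichiometricModel(id="toy")
    model.add_compartment("c")
    model.add_compartment("e")
    formulas = formulas or {}
    mets = {m for stoich, _, _ in reactions.values() for m in stoich}
    for m in sorted(mets):
        model.add_metabolite(
            Metabolite(id=m, compartment="e" if m in externals else "c",
                       formula=formulas.get(m))
        )
    for rid, (stoich, lb, ub) in reactions.items():
        pathway = "exchange" if rid.startswith("EX_") else ""
        model.add_reaction(
            Reaction(id=rid, stoichiometry=dict(stoich), lower_bound=lb,
                     upper_bound=ub, pathway=pathway)
        )
    model.objective = dict(objective or {})
    return model


def chain_model(uptake: float = 10.0) -> StoichiometricModel:
    """EX_A -(uptake)-> A -> B -> biomass drain; unique optimum."""
    return make_model(
        {
            "EX_A": ({"A_e": -1.0}, -uptake, 0.0),
            "T_A": ({"A_e": -1.0, "A": 1.0}, -1000.0, 1000.0),
            "R1": ({"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            "BIO": ({"B": -1.0}, 0.0, 1000.0),
        },
        externals=["A_e"],
        objective={"BIO": 1.0},
    )


def random_model(seed: int, n_mets: int = 8, n_rxns: int = 12) -> StoichiometricModel:
    """Random bounded network; always feasible (v = 0) and bounded (box)."""
    rng = np.random.default_rng(seed)
    model = StoichiometricModel(id=f"rand{seed}")
    model.add_compartment("c")
    model.add_compartment("e")
    for i in range(n_mets):
        model.add_metabolite(Metabolite(id=f"m{i}", compartment="c"))
    for j in range(n_rxns):
        k = int(rng.integers(2, 5))
        mets = rng.choice(n_mets, size=min(k, n_mets), replace=False)
        coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=len(mets))
        stoich = {f"m{int(i)}": float(c) for i, c in zip(mets, coefs)}
        reversible = rng.random() < 0.5
        model.add_reaction(
            Reaction(id=f"r{j}", stoichiometry=stoich,
                     lower_bound=-10.0 if reversible else 0.0, upper_bound=10.0)
        )
    weights = rng.normal(size=n_rxns)
    model.objective = {f"r{j}": float(weights[j]) for j in range(n_rxns)}
    return model


# ---------------------------------------------------------------------------
# dense LP oracle (scipy / HiGHS)
# ---------------------------------------------------------------------------

def oracle_solve(
    model: StoichiometricModel,
    objective: Optional[Dict[str, float]] = None,
    ratio_constraints: Sequence[RatioConstraint] = (),
    maximize: bool = True,
) -> Tuple[float, Dict[str, float]]:
    """Direct dense LP on the explicit stoichiometric matrix."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays(rxn_ids)
    idx = {r: j for j, r in enumerate(rxn_ids)}
    rows = [S] if S.size else []
    for rc in ratio_constraints:
        row = np.zeros((1, len(rxn_ids)))
        row[0, idx[rc.numerator_reaction]] = 1.0
        row[0, idx[rc.denominator_reaction]] = -rc.ratio
        rows.append(row)
    A_eq = np.vstack(rows)
    b_eq = np.zeros(A_eq.shape[0])
    c = np.zeros(len(rxn_ids))
    for rid, coef in (objective or model.objective).items():
        c[idx[rid]] = coef
    res = scipy.optimize.linprog(
        -c if maximize else c,
        A_eq=A_eq, b_eq=b_eq, bounds=list(zip(lb, ub)), method="highs",
    )
    if not res.success:
        raise RuntimeError(f"oracle LP failed: {res.message}")
    value = float(-res.fun if maximize else res.fun)
    return value, {r: float(res.x[j]) for j, r in enumerate(idx)}


def oracle_min_total_flux(
    model: StoichiometricModel,
    optimum: float,
    objective: Optional[Dict[str, float]] = None,
    ratio_constraints: Sequence[RatioConstraint] = (),
) -> float:
    """min sum |v| subject to S v = 0, bounds and c.v >= optimum.

    Irreversible-split formulation: v = p - n with p, n >= 0.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays(rxn_ids)
    idx = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids)
    rows = [S] if S.size else []
    for rc in ratio_constraints:
        row = np.zeros((1, n))
        row[0, idx[rc.numerator_reaction]] = 1.0
        row[0, idx[rc.denominator_reaction]] = -rc.ratio
        rows.append(row)
    A = np.vstack(rows)
    A_eq = np.hstack([A, -A])  # v = p - n
    b_eq = np.zeros(A_eq.shape[0])
    c_obj = np.zeros(n)
    for rid, coef in (objective or model.objective).items():
        c_obj[idx[rid]] = coef
    eye = np.eye(n)
    A_ub = np.vstack(
        [
            np.hstack([-c_obj, c_obj]),  # -c.(p-n) <= -optimum
            np.hstack([eye, -eye]),      # p - n <= ub
            np.hstack([-eye, eye]),      # -(p - n) <= -lb
        ]
    )
    b_ub = np.concatenate(
        [[-(optimum - 1e-9 * max(1.0, abs(optimum)))], ub, -lb]
    )
    res = scipy.optimize.linprog(
        np.ones(2 * n),
        A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=[(0, None)] * (2 * n),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"oracle min-flux LP failed: {res.message}")
    return float(res.fun)


# ---------------------------------------------------------------------------
# session fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def leaf_model():
    return build_fixture_leaf_model()


@pytest.fixture(scope="session")
def leaf_baseline(leaf_model):
    result = run_baseline(leaf_model)
    assert result.optimal
    return result


@pytest.fixture()
def toy_chain():
    return chain_model()
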