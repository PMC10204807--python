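"""Tabular filter for protein homology-search hits.

Enzyme reactions imported into a reconstruction from donor models are kept
only when the encoding protein has a credible homolog in the target genome.
The filter applies the conventional three-way criterion — E-value at most
``max_evalue``, percent identity at least ``min_identity_pct`` and query
coverage at least ``min_coverage_pct`` — with inclusive comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["HomologyCriterion", "filter_homology_hits", "SchemaError"]

REQUIRED_COLUMNS = ("gene", "evalue", "identity_pct", "coverage_pct")


class SchemaError(ValueError):
    """The hits table is missing required columns or has non-numeric data."""


@dataclass(frozen=True)
class HomologyCriterion:
    """Acceptance thresholds for a homology hit (all inclusive)."""

    max_evalue: float = 1e-10
    min_identity_pct: float = 60.0
    min_coverage_pct: float = 80.0

    def __post_init__(self) -> None:
        if not self.max_evalue > 0:
            raise ValueError("max_evalue must be positive")
        for pct in (self.min_identity_pct, self.min_coverage_pct):
            if not 0.0 <= pct <= 100.0:
                raise ValueError("percentage thresholds must lie in [0, 100]")


def filter_homology_hits(
    hits: pd.DataFrame,
    criterion: HomologyCriterion = HomologyCriterion(),
) -> pd.DataFrame:
    """Rows meeting all three thresholds simultaneously, original order kept."""
    missing = [c for c in REQUIRED_COLUMNS if c not in hits.columns]
    if missing:
        raise SchemaError(f"hits table missing columns: {', '.join(missing)}")
    numeric = hits[list(REQUIRED_COLUMNS[1:])].apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise SchemaError(f"non-numeric values in columns: {', '.join(bad)}")
    keep = (
        (numeric["evalue"] <= criterion.max_evalue)
        & (numeric["identity_pct"] >= criterion.min_identity_pct)
        & (numeric["coverage_pct"] >= criterion.min_coverage_pct)
    )
    return hits.loc[keep].copy()
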