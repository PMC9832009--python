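"""Cohort incidence tables and worked-example statistics.

Holds per-genotype mouse cohort counts (animals examined, animals with
squamous lesions) and computes squamous-transdifferentiation incidence as
a whole-percent figure alongside the exact fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = ["CohortTable", "cohort_incidence"]


@dataclass
class CohortTable:
    """Rows of (group name, n_total mice, n_with_scc mice)."""

    table: pd.DataFrame

    REQUIRED = ("group", "n_total", "n_with_scc")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"cohort table missing columns: {missing}")
        t = self.table
        if t["group"].duplicated().any():
            raise FormatError("duplicate group names")
        if (t["n_total"] < 0).any() or (t["n_with_scc"] < 0).any():
            raise FormatError("cohort counts must be nonnegative")
        if (t["n_with_scc"] > t["n_total"]).any():
            raise FormatError("n_with_scc cannot exceed n_total")

    @classmethod
    def from_rows(cls, rows: list[tuple[str, int, int]]) -> "CohortTable":
        return cls(pd.DataFrame(rows, columns=["group", "n_total", "n_with_scc"]))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cohort_incidence(t: CohortTable) -> pd.DataFrame:
    """Per-group SCC incidence: whole-percent (half-up) plus exact fraction.

    Groups with zero animals get a missing incidence.
    """
    rows = []
    for _i, r in t.table.iterrows():
        n, k = int(r["n_total"]), int(r["n_with_scc"])
        if n == 0:
            pct, frac = np.nan, np.nan
        else:
            frac = k / n
            pct = _round_half_up(100.0 * k / n)
        rows.append(
            {
                "group": r["group"],
                "n_total": n,
                "n_with_scc": k,
                "incidence_pct": pct,
                "incidence_fraction": frac,
            }
        )
    return pd.DataFrame(rows)
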