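"""Novel-object-recognition discrimination index.

DI = (Tn - Tf) / (Tn + Tf), where Tn and Tf are the seconds spent exploring
the novel and the familiar object. Animals with too little total exploration
are excluded rather than scored, since the index is unstable at small
denominators; the conventional cut-off is 8 s of exploration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["ExplorationRecord", "DIResult", "discrimination_index", "score_table"]

MIN_EXPLORATION_S = 8.0


@dataclass(frozen=True)
class ExplorationRecord:
    """Seconds of exploration of the novel (tn) and familiar (tf) object."""

    tn: float
    tf: float

    def __post_init__(self) -> None:
        if self.tn < 0 or self.tf < 0:
            raise ValueError("exploration times must be >= 0")


@dataclass(frozen=True)
class DIResult:
    di: float  # NaN when excluded
    excluded: bool


def discrimination_index(
    rec: ExplorationRecord,
    min_total_s: float = MIN_EXPLORATION_S,
    rule: str = "total",
) -> DIResult:
    """Score one animal; apply the low-exploration exclusion first.

    ``rule="total"`` (default) excludes when tn + tf < min_total_s;
    ``rule="each"`` is the alternative reading that requires each object to
    have been explored at least min_total_s seconds.
    """
    if rule == "total":
        excluded = (rec.tn + rec.tf) < min_total_s
    elif rule == "each":
        excluded = rec.tn < min_total_s or rec.tf < min_total_s
    else:
        raise ValueError("rule must be 'total' or 'each'")
    total = rec.tn + rec.tf
    if excluded or total == 0:
        return DIResult(math.nan, True)
    return DIResult((rec.tn - rec.tf) / total, False)


def score_table(
    table: pd.DataFrame,
    min_total_s: float = MIN_EXPLORATION_S,
    rule: str = "total",
) -> pd.DataFrame:
    """Score a table with columns (animal, tn, tf); returns it with
    ``di`` and ``excluded`` columns appended."""
    results = [
        discrimination_index(ExplorationRecord(row.tn, row.tf), min_total_s, rule)
        for row in table.itertuples()
    ]
    out = table.copy()
    out["di"] = [r.di for r in results]
    out["excluded"] = [r.excluded for r in results]
    return out
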