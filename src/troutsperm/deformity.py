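"""Deformity scan counting: the ~100-cell stopping rule and proportion tables.

Scanning protocol: fields of view are inspected in order and every discernible
cell is scored as normal, kink, coil, short or tailless.  Counting stops once
the cumulative total reaches the target (nominally 100 cells), but the field
of view that crosses the target is always counted *in full*, so realised
totals overshoot.  Aggregations of cells that cannot be told apart are
recorded separately and never enter any denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import DEFORMITY_CATEGORIES

__all__ = ["FieldScan", "DeformityCount", "InsufficientScanError",
           "count_with_stopping_rule", "tabulate_proportions"]


class InsufficientScanError(ValueError):
    """The scan ran out of fields before the target count was reached."""


@dataclass(frozen=True)
class FieldScan:
    """Ordered per-field-of-view category counts for one sample."""

    fields: tuple[Mapping[str, int], ...]
    excluded_aggregates: int = 0

    def __post_init__(self) -> None:
        for i, f in enumerate(self.fields):
            unknown = set(f) - set(DEFORMITY_CATEGORIES)
            if unknown:
                raise ValueError(f"field {i}: unknown categories {sorted(unknown)}")
            if any(int(f.get(c, 0)) < 0 for c in DEFORMITY_CATEGORIES):
                raise ValueError(f"field {i}: counts must be non-negative")
        if self.excluded_aggregates < 0:
            raise ValueError("excluded_aggregates must be non-negative")

    def field_sizes(self) -> list[int]:
        return [sum(int(f.get(c, 0)) for c in DEFORMITY_CATEGORIES) for f in self.fields]


@dataclass(frozen=True)
class DeformityCount:
    """Per-category totals over the counted fields of one sample."""

    totals: Mapping[str, int]
    n_fields_counted: int

    @property
    def total_counted(self) -> int:
        return sum(self.totals.values())

    @property
    def n_deformed(self) -> int:
        return self.total_counted - self.totals.get("normal", 0)

    @property
    def proportion_deformed(self) -> float:
        return self.n_deformed / self.total_counted


def count_with_stopping_rule(scan: FieldScan, target: int = 100) -> DeformityCount:
    """Consume fields in order until the cumulative count reaches ``target``.

    The final field is counted in full even if it overshoots; a partial field
    is never counted.  Raises :class:`InsufficientScanError` (reporting the
    shortfall) if the whole scan holds fewer than ``target`` cells.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    if not scan.fields:
        raise InsufficientScanError(f"empty scan: short of target by {target} cells")
    totals = {c: 0 for c in DEFORMITY_CATEGORIES}
    counted = 0
    n_fields = 0
    for f in scan.fields:
        for c in DEFORMITY_CATEGORIES:
            totals[c] += int(f.get(c, 0))
        counted = sum(totals.values())
        n_fields += 1
        if counted >= target:
            return DeformityCount(totals=totals, n_fields_counted=n_fields)
    raise InsufficientScanError(
        f"scan exhausted at {counted} cells, short of target {target} "
        f"by {target - counted}")


def tabulate_proportions(counts: Mapping[str, DeformityCount],
                         groups: Mapping[str, str]) -> pd.DataFrame:
    """Per-male category proportions with per-group means appended.

    Parameters
    ----------
    counts
        male_id -> :class:`DeformityCount`.
    groups
        male_id -> acclimation group label.

    Returns a table with one row per male (``level='male'``) followed by one
    mean row per group (``level='group_mean'``), shaped like a deformity
    summary table: per-category proportions plus the overall deformed
    proportion.
    """
    if not counts:
        raise ValueError("no counts supplied")
    rows = []
    for male_id, c in counts.items():
        tot = c.total_counted
        row = {"male_id": male_id, "group": groups[male_id], "level": "male",
               "total_counted": tot,
               **{f"prop_{cat}": c.totals[cat] / tot for cat in DEFORMITY_CATEGORIES},
               "proportion_deformed": c.proportion_deformed}
        rows.append(row)
    df = pd.DataFrame(rows)
    means = (df.groupby("group", sort=True)
               .mean(numeric_only=True).reset_index())
    means.insert(0, "male_id", "(mean)")
    means["level"] = "group_mean"
    return pd.concat([df, means], ignore_index=True)
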