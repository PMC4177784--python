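"""Cross-tabulation of cardiovascular risk categories before vs after the
storage-decay correction, with the summary layout used in reclassification
tables (per-category before/after counts, net change, and the overall share
of patients whose category changed)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .score import CATEGORIES

__all__ = ["ReclassTable", "build_table", "summarize", "render_summary"]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (47.5 -> 48, -47.5 -> -48)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class ReclassTable:
    """3x3 count matrix indexed (before category, after category)."""

    counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValueError("counts must be a 3x3 matrix")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if int(c.sum()) != self.n_total:
            raise ValueError("counts do not sum to n_total")

    @property
    def before_counts(self) -> np.ndarray:
        return np.asarray(self.counts).sum(axis=1)

    @property
    def after_counts(self) -> np.ndarray:
        return np.asarray(self.counts).sum(axis=0)

    @property
    def n_reclassified(self) -> int:
        return int(self.n_total - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CATEGORIES),
                            columns=list(CATEGORIES))


def build_table(before, after) -> ReclassTable:
    """Tally aligned per-patient category pairs into a :class:`ReclassTable`."""
    before = list(before)
    after = list(after)
    if len(before) != len(after):
        raise ValueError(
            f"before/after lengths differ ({len(before)} vs {len(after)})"
        )
    idx = {c: i for i, c in enumerate(CATEGORIES)}
    counts = np.zeros((3, 3), dtype=int)
    for b, a in zip(before, after):
        try:
            counts[idx[b], idx[a]] += 1
        except KeyError as err:
            raise ValueError(f"unknown category {err.args[0]!r}") from None
    return ReclassTable(counts, len(before))


def summarize(table: ReclassTable) -> pd.DataFrame:
    """Per-category before/after counts, percents and net change.

    Percent columns are whole percents rounded half away from zero.  The
    per-category change percent uses that category's before count as the
    denominator; the overall reclassified percent uses the cohort size.  The
    returned frame has one row per category plus a ``total`` row in which
    ``net_change`` is the overall number of patients whose category changed.
    """
    if table.n_total == 0:
        raise ValueError("empty table: no patients to summarize")
    rows = []
    before = table.before_counts
    after = table.after_counts
    for i, cat in enumerate(CATEGORIES):
        net = int(after[i] - before[i])
        pct_net = (
            round_half_away(100.0 * abs(net) / before[i]) if before[i] > 0 else 0
        )
        rows.append(
            {
                "category": cat,
                "before_n": int(before[i]),
                "before_pct": round_half_away(100.0 * before[i] / table.n_total),
                "after_n": int(after[i]),
                "after_pct": round_half_away(100.0 * after[i] / table.n_total),
                "net_change": net,
                "net_change_pct": pct_net,
            }
        )
    rows.append(
        {
            "category": "total",
            "before_n": table.n_total,
            "before_pct": 100,
            "after_n": table.n_total,
            "after_pct": 100,
            "net_change": table.n_reclassified,
            "net_change_pct": round_half_away(
                100.0 * table.n_reclassified / table.n_total
            ),
        }
    )
    return pd.DataFrame(rows)


def render_summary(summary: pd.DataFrame) -> str:
    """Plain-text rendering: category, before n (%), after n (%), change n (%)."""
    lines = [f"{'CV risk':<14}{'Before n (%)':>16}{'After n (%)':>16}{'Change n (%)':>16}"]
    for _, r in summary.iterrows():
        sign = "+" if r["net_change"] > 0 else ""
        lines.append(
            f"{r['category']:<14}"
            f"{f'{r.before_n} ({r.before_pct}%)':>16}"
            f"{f'{r.after_n} ({r.after_pct}%)':>16}"
            f"{f'{sign}{r.net_change} ({r.net_change_pct}%)':>16}"
        )
    return "\n".join(lines)
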