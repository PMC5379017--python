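"""RNA-group screening versus IHC protein truth: confusion tables and
diagnostic metrics.

A screen that sends only RNA-high samples to IHC is a binary diagnostic
test: screen-positive = RNA-high, screen-negative = RNA-low or RNA-medium
pooled, truth = the IHC positivity call (H-score rule by default).  From a
per-group tally of screened and IHC-positive samples the 2x2 confusion
table follows, and from it accuracy, sensitivity, specificity, PPV and
NPV.  Metrics with a zero denominator are reported as undefined (``None``
/ ``NaN``), never as 0 or 100.

Between-group differences in positivity rates are assessed with the
two-sided Fisher exact test of :mod:`prescreen.enrichment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_away
from .enrichment import fisher_exact_2x2

__all__ = [
    "GroupCounts",
    "ConfusionTable",
    "sample_per_group",
    "build_confusion",
    "metric_ranges",
    "compare_groups",
]

METRICS: tuple[str, ...] = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class GroupCounts:
    """Per-RNA-group tally: samples screened by IHC and samples IHC-positive."""

    counts: dict[str, tuple[int, int]]  # group -> (n_screened, n_ihc_positive)

    def __post_init__(self) -> None:
        for group, (screened, positive) in self.counts.items():
            if not 0 <= positive <= screened:
                raise ValueError(
                    f"group {group!r}: need 0 <= positives ({positive}) <= screened ({screened})"
                )


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 screen-vs-truth counts with derived diagnostic metrics.

    Metric attributes are exact percentages (floats) or ``None`` when the
    denominator is zero; ``rounded()`` gives the integer-percent view used
    in printed reports (half away from zero).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float | None = field(init=False)
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        object.__setattr__(self, "accuracy", _ratio(self.tp + self.tn, self.total))
        object.__setattr__(self, "sensitivity", _ratio(self.tp, self.tp + self.fn))
        object.__setattr__(self, "specificity", _ratio(self.tn, self.tn + self.fp))
        object.__setattr__(self, "ppv", _ratio(self.tp, self.tp + self.fp))
        object.__setattr__(self, "npv", _ratio(self.tn, self.tn + self.fn))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def rounded(self) -> dict[str, int | None]:
        """Metrics rounded half away from zero to integer percent."""
        return {
            m: (round_half_away(v) if v is not None else None)
            for m in METRICS
            for v in [getattr(self, m)]
        }


def sample_per_group(
    groups: dict[str, list],
    n_per_group: int,
    seed,
) -> dict[str, list]:
    """Uniform random selection without replacement within each RNA group.

    Selects ``min(n_per_group, group size)`` ids per group, reproducibly
    under ``seed`` (an int, a ``SeedSequence`` or a ``Generator``).  Groups
    are processed in sorted-name order so the draw does not depend on dict
    insertion order.
    """
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {name!r} is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, list] = {}
    for name in sorted(groups):
        members = list(groups[name])
        k = min(n_per_group, len(members))
        chosen = rng.choice(len(members), size=k, replace=False)
        out[name] = [members[i] for i in sorted(chosen)]
    return out


def build_confusion(
    group_counts: GroupCounts,
    positive_groups: frozenset[str] | set[str] = frozenset({"high"}),
) -> ConfusionTable:
    """Collapse per-group tallies into a screen-vs-truth confusion table.

    Screen-positive are the samples in ``positive_groups`` (RNA-high by
    default); all remaining groups pool into screen-negative.
    """
    if not positive_groups:
        raise ValueError("positive_groups must be nonempty")
    tp = fp = fn = tn = 0
    for group, (screened, positive) in group_counts.counts.items():
        if group in positive_groups:
            tp += positive
            fp += screened - positive
        else:
            fn += positive
            tn += screened - positive
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def metric_ranges(
    tables: dict[str, ConfusionTable], rounded: bool = True
) -> dict[str, tuple[float, float]]:
    """Per-metric (min, max) across named confusion tables.

    Undefined metrics are skipped; a metric undefined in every table is
    absent from the result.  With ``rounded=True`` (the printed-report
    convention) the extrema are taken over integer-rounded percentages.
    """
    if not tables:
        raise ValueError("need at least one confusion table")
    out: dict[str, tuple[float, float]] = {}
    for m in METRICS:
        vals = [
            (t.rounded()[m] if rounded else getattr(t, m))
            for t in tables.values()
            if getattr(t, m) is not None
        ]
        if vals:
            out[m] = (min(vals), max(vals))
    return out


def compare_groups(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p for a difference in positivity rates.

    Each argument is ``(n_positive, n_screened)``.
    """
    pos_a, n_a = counts_a
    pos_b, n_b = counts_b
    if not (0 <= pos_a <= n_a and 0 <= pos_b <= n_b):
        raise ValueError("need 0 <= positives <= screened in both groups")
    p, _ = fisher_exact_2x2(pos_a, n_a - pos_a, pos_b, n_b - pos_b)
    return p


def confusion_frame(tables: dict[str, ConfusionTable]) -> pd.DataFrame:
    """Long-format report of per-stratum counts and metrics.

    Exact metrics are written unrounded; a rounded integer column sits
    alongside for display.
    """
    rows = []
    for name, t in tables.items():
        row: dict[str, object] = {
            "stratum": name,
            "tp": t.tp,
            "fp": t.fp,
            "fn": t.fn,
            "tn": t.tn,
        }
        r = t.rounded()
        for m in METRICS:
            v = getattr(t, m)
            row[m] = np.nan if v is None else v
            row[f"{m}_int"] = np.nan if r[m] is None else r[m]
        rows.append(row)
    return pd.DataFrame(rows)
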