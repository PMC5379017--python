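"""Immunohistochemistry H-scores and CD30 positivity calls.

A pathologist's semiquantitative read of one FFPE slide is a staining
profile: the percentage of cells at each staining intensity 0, 1+, 2+, 3+
(membranous, cytoplasmic or Golgi staining pooled).  Two scores derive
from it:

* the composite **H-score**, ``sum_i i * pct[i]``, in [0, 300];
* the **stained fraction**, ``100 - pct[0]``, the percentage of cells
  stained at any intensity above 0.

Two positivity definitions are in clinical use and both are provided: the
trial-eligibility rule (>= 10% of cells stained at any intensity > 0) and
the H-score rule (H >= 10).  At the default thresholds H-positivity
implies fraction-positivity, but not conversely.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "StainingProfile",
    "IHCResult",
    "h_score",
    "call_positive_fraction",
    "call_positive_hscore",
    "score_staining_table",
]

_PCT_SUM_TOL = 1e-6


@dataclass(frozen=True)
class StainingProfile:
    """Percent of cells at each staining intensity for one sample.

    ``pct_at_intensity`` maps intensity 0..3 to a percentage in [0, 100];
    the four percentages must sum to 100 (within 1e-6).  ``cell_population``
    records which cells were scored; it does not affect any computation.
    """

    sample_id: str
    pct_at_intensity: dict[int, float]
    cell_population: str = "neoplastic_cells"

    def __post_init__(self) -> None:
        pct = {int(k): float(v) for k, v in self.pct_at_intensity.items()}
        if set(pct) != {0, 1, 2, 3}:
            raise ValueError("pct_at_intensity must have exactly the keys 0, 1, 2, 3")
        for i, p in pct.items():
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"percentage at intensity {i} out of [0, 100]: {p}")
        total = sum(pct.values())
        if abs(total - 100.0) > _PCT_SUM_TOL:
            raise ValueError(f"percentages must sum to 100, got {total}")
        object.__setattr__(self, "pct_at_intensity", pct)

    @property
    def stained_fraction(self) -> float:
        """Percent of cells stained at any intensity > 0."""
        return 100.0 - self.pct_at_intensity[0]


@dataclass(frozen=True)
class IHCResult:
    sample_id: str
    h_score: float
    positive_by_fraction: bool
    positive_by_hscore: bool


def h_score(profile: StainingProfile) -> float:
    """Composite H-score: sum over intensities of intensity x percent of cells."""
    return float(sum(i * p for i, p in profile.pct_at_intensity.items()))


def call_positive_fraction(profile: StainingProfile, min_pct: float = 10.0) -> bool:
    """Trial-eligibility call: >= ``min_pct`` % of cells stained at intensity > 0."""
    return profile.stained_fraction >= min_pct


def call_positive_hscore(h: float, min_h: float = 10.0) -> bool:
    """Protein-expression-group call: H-score >= ``min_h``."""
    if not 0.0 <= h <= 300.0:
        raise ValueError(f"H-score out of [0, 300]: {h}")
    return h >= min_h


def score_staining_table(
    staining: pd.DataFrame, min_pct: float = 10.0, min_h: float = 10.0
) -> pd.DataFrame:
    """Score a table of staining profiles.

    Parameters
    ----------
    staining : pandas.DataFrame
        Columns ``sample_id, pct_0, pct_1, pct_2, pct_3``.

    Returns
    -------
    pandas.DataFrame
        Columns ``sample_id, h_score, positive_by_fraction,
        positive_by_hscore``.
    """
    required = ["sample_id", "pct_0", "pct_1", "pct_2", "pct_3"]
    missing = [c for c in required if c not in staining.columns]
    if missing:
        raise ValueError(f"staining table lacks required column(s): {', '.join(missing)}")
    rows = []
    for rec in staining.itertuples(index=False):
        profile = StainingProfile(
            sample_id=str(rec.sample_id),
            pct_at_intensity={0: rec.pct_0, 1: rec.pct_1, 2: rec.pct_2, 3: rec.pct_3},
        )
        h = h_score(profile)
        rows.append(
            (
                profile.sample_id,
                h,
                call_positive_fraction(profile, min_pct=min_pct),
                call_positive_hscore(h, min_h=min_h),
            )
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "h_score", "positive_by_fraction", "positive_by_hscore"]
    )
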