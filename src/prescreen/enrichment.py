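"""Tissue-of-origin enrichment of biomarker-high samples.

For each tumor site with enough expression profiles, the fraction of
samples in the RNA-high group (global Z >= 1 by default) is compared to
the rest of the warehouse with a two-sided Fisher exact test.  The module
also exports per-tissue Gaussian kernel density summaries of the Z-score
distributions on a shared grid, the tabular form of the usual ridge/density
figure.

The two-sided p-value follows the minimum-likelihood convention used by
mainstream statistical software: with the table margins fixed, sum the
hypergeometric probabilities of every table whose probability does not
exceed that of the observed table.  Probabilities within a relative 1e-14
of the observed one count as ties and are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away

__all__ = [
    "TissueEnrichmentRow",
    "fisher_exact_2x2",
    "two_sided_pvalues",
    "summarize_by_tissue",
    "export_density",
]

#: Relative tolerance for probability ties in the two-sided sum; matches the
#: convention of the major statistics libraries.
_TIE_GAMMA = 1.0 + 1e-14


@dataclass(frozen=True)
class TissueEnrichmentRow:
    """Per-tissue counts, Z summaries and enrichment test result."""

    tissue: str
    n: int
    n_high: int
    pct_high: float
    pct_high_int: int
    fisher_p: float
    odds_ratio: float
    mean_z: float
    median_z: float
    sd_z: float
    direction: str


def two_sided_pvalues(total: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every table with the given margins.

    Considers 2x2 tables ``[[a, b], [c, d]]`` with ``a + b = row1``,
    ``a + c = col1`` and grand total ``total``.  The count ``a`` ranges over
    the hypergeometric support.

    Returns
    -------
    (support, pvalues)
        ``support`` — the admissible values of ``a``; ``pvalues`` — the
        minimum-likelihood two-sided p-value for each.
    """
    low = max(0, col1 - (total - row1))
    high = min(row1, col1)
    support = np.arange(low, high + 1)
    pmf = stats.hypergeom.pmf(support, total, row1, col1)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    # for each a: sum of all pmf values <= pmf[a] * (1 + eps)
    idx = np.searchsorted(sorted_pmf, pmf * _TIE_GAMMA, side="right")
    pvals = np.minimum(csum[idx - 1], 1.0)
    return support, pvals


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table ``[[a, b], [c, d]]``.

    Returns
    -------
    (p, odds_ratio)
        ``p`` — minimum-likelihood two-sided p-value; ``odds_ratio`` — the
        sample odds ratio ``(a*d)/(b*c)``, ``inf`` when ``b*c == 0`` with a
        nonzero numerator and ``nan`` for 0/0.
    """
    counts = (a, b, c, d)
    if any(int(x) != x for x in counts):
        raise ValueError("cell counts must be integers")
    a, b, c, d = (int(x) for x in counts)
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    total = a + b + c + d
    if total == 0:
        raise ValueError("table is empty")
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    support, pvals = two_sided_pvalues(total, a + b, a + c)
    p = float(pvals[np.searchsorted(support, a)])
    return p, odds


def summarize_by_tissue(
    zscores: pd.DataFrame,
    z_threshold: float = 1.0,
    min_n: int = 50,
) -> pd.DataFrame:
    """Per-tissue Z summaries and Fisher enrichment of high-Z samples.

    Parameters
    ----------
    zscores : pandas.DataFrame
        One row per sample with columns ``tissue_type`` and ``z``.  The
        *whole* input is the background: each qualifying tissue is tested
        against all other samples supplied, including samples of tissues
        too small to get a row of their own.
    z_threshold : float
        Z cut defining the high group.
    min_n : int
        Tissues with fewer samples are excluded from the output (they still
        contribute to the background).

    Returns
    -------
    pandas.DataFrame
        One row per qualifying tissue, sorted by percent-high descending,
        with columns matching :class:`TissueEnrichmentRow`.
    """
    for col in ("tissue_type", "z"):
        if col not in zscores.columns:
            raise ValueError(f"zscores table lacks required column {col!r}")
    if len(zscores) == 0:
        raise ValueError("empty zscores table")
    z = zscores["z"].to_numpy(dtype=float)
    high = z >= z_threshold
    total_n = len(zscores)
    total_high = int(high.sum())
    rows: list[TissueEnrichmentRow] = []
    for tissue, idx in zscores.groupby("tissue_type").indices.items():
        n = len(idx)
        if n < min_n:
            continue
        zt = z[idx]
        n_high = int(high[idx].sum())
        a, b = n_high, n - n_high
        c, d = total_high - n_high, (total_n - n) - (total_high - n_high)
        p, odds = fisher_exact_2x2(a, b, c, d)
        pct = 100.0 * n_high / n
        rows.append(
            TissueEnrichmentRow(
                tissue=str(tissue),
                n=n,
                n_high=n_high,
                pct_high=pct,
                pct_high_int=round_half_away(pct),
                fisher_p=p,
                odds_ratio=odds,
                mean_z=float(zt.mean()),
                median_z=float(np.median(zt)),
                sd_z=float(zt.std(ddof=1)) if n > 1 else float("nan"),
                direction="over" if odds > 1 else "under",
            )
        )
    if not rows:
        raise ValueError(f"no tissue reaches min_n={min_n} samples")
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out.sort_values(
        ["pct_high", "tissue"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def export_density(
    zscores: pd.DataFrame,
    min_n: int = 50,
    grid_size: int = 512,
    pad: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue Gaussian KDE of Z-scores on a shared grid, plus medians.

    The grid spans the pooled Z range extended by ``pad`` on each side so
    the Gaussian tails are captured and each density integrates to 1 on the
    grid (within 1e-3).

    Returns
    -------
    (density, medians)
        ``density`` — long-format DataFrame ``tissue_type, z_grid,
        density``; ``medians`` — ``tissue_type, median_z`` (the dot of the
        usual density figure).
    """
    for col in ("tissue_type", "z"):
        if col not in zscores.columns:
            raise ValueError(f"zscores table lacks required column {col!r}")
    z = zscores["z"].to_numpy(dtype=float)
    grid = np.linspace(z.min() - pad, z.max() + pad, grid_size)
    dens_frames = []
    medians = []
    for tissue, idx in zscores.groupby("tissue_type").indices.items():
        if len(idx) < min_n:
            continue
        zt = z[idx]
        kde = stats.gaussian_kde(zt)
        dens_frames.append(
            pd.DataFrame(
                {"tissue_type": str(tissue), "z_grid": grid, "density": kde(grid)}
            )
        )
        medians.append((str(tissue), float(np.median(zt))))
    if not dens_frames:
        raise ValueError(f"no tissue reaches min_n={min_n} samples")
    density = pd.concat(dens_frames, ignore_index=True)
    medians_df = pd.DataFrame(medians, columns=["tissue_type", "median_z"])
    return density, medians_df
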