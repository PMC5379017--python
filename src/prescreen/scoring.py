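"""Expression scaling, global Z-scores and low/medium/high trichotomization.

The screening pipeline compares one gene's expression in a sample against
the whole multi-tissue warehouse.  Raw probe intensities are first brought
onto a common scale by multiplying each array's values by a single factor
so that the trimmed mean equals a fixed target (500 by default), then log2
transformed.  A *global* Z-score is computed against the mean and sample
standard deviation of the entire data set — all tissue types, primary and
metastatic disease pooled — and each sample is assigned to one of three
RNA expression groups:

* ``low``    — Z <= -1
* ``medium`` — -1 < Z < 1
* ``high``   — Z >= 1

The boundary values belong to the outer groups: a Z of exactly -1 is low
and exactly +1 is high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ZScoreAssignment",
    "scale_and_log",
    "global_z",
    "categorize",
    "assign_zscores",
    "CATEGORIES",
]

#: The three RNA expression groups, in increasing order of expression.
CATEGORIES: tuple[str, str, str] = ("low", "medium", "high")


@dataclass(frozen=True)
class ZScoreAssignment:
    """A sample's global Z-score and RNA expression group."""

    sample_id: str
    z: float
    category: str


def scale_and_log(
    raw_intensities,
    target_trimmed_mean: float = 500.0,
    trim_fraction: float = 0.02,
    floor: float = 1.0,
) -> np.ndarray:
    """Scale raw intensities to a fixed trimmed mean, then log2 transform.

    A single multiplicative factor ``c`` is chosen so that the trimmed mean
    of ``c * raw_intensities`` — excluding the lowest and highest
    ``trim_fraction`` of sorted values — equals ``target_trimmed_mean``.
    Scaled values below ``floor`` are clipped to ``floor`` before the log2
    so that zero intensities map to a finite value.

    Parameters
    ----------
    raw_intensities : array-like of nonnegative floats
        Pre-scaling probe intensities for one array.
    target_trimmed_mean : float
        The trimmed mean every array is scaled to.
    trim_fraction : float
        Fraction of sorted values discarded from *each* tail before
        averaging, in [0, 0.5).
    floor : float
        Lower clip applied to scaled values before the log2.

    Returns
    -------
    numpy.ndarray
        log2 of the scaled (and floored) intensities.
    """
    x = np.asarray(raw_intensities, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("raw_intensities must be a nonempty 1-D vector")
    if np.any(~np.isfinite(x)):
        raise ValueError("raw_intensities must be finite")
    if np.any(x < 0):
        raise ValueError("raw_intensities must be nonnegative")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    tm = stats.trim_mean(x, trim_fraction)
    if tm <= 0:
        raise ValueError("trimmed mean is zero; scale factor undefined")
    scaled = x * (target_trimmed_mean / tm)
    return np.log2(np.maximum(scaled, floor))


def global_z(log2_values) -> np.ndarray:
    """Standardize log2 expression against the whole data set.

    Uses the sample standard deviation (``n - 1`` denominator).  The output
    has mean 0 and standard deviation 1 by construction.
    """
    x = np.asarray(log2_values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two values to standardize")
    if np.any(~np.isfinite(x)):
        raise ValueError("log2 values must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; Z-scores undefined")
    return (x - x.mean()) / sd


def categorize(z, z_low: float = -1.0, z_high: float = 1.0):
    """Assign Z-scores to RNA groups: low (Z <= z_low), high (Z >= z_high),
    medium otherwise.

    Accepts a scalar or an array; returns a string or an object array of
    strings correspondingly.
    """
    arr = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("Z-scores must be finite")
    out = np.where(arr <= z_low, "low", np.where(arr >= z_high, "high", "medium"))
    if np.isscalar(z) or arr.ndim == 0:
        return str(out[()])
    return out


def assign_zscores(
    expression: pd.DataFrame,
    z_low: float = -1.0,
    z_high: float = 1.0,
    value_column: str = "log2_expression",
) -> pd.DataFrame:
    """Compute global Z-scores and groups for an expression table.

    Parameters
    ----------
    expression : pandas.DataFrame
        Must carry ``sample_id`` and ``value_column``; any other columns
        (``patient_id``, ``tissue_type``) are passed through.
    z_low, z_high : float
        Trichotomization cut points.

    Returns
    -------
    pandas.DataFrame
        The input columns plus ``z`` and ``category``.
    """
    if value_column not in expression.columns:
        raise ValueError(f"expression table lacks required column {value_column!r}")
    out = expression.copy()
    out["z"] = global_z(out[value_column].to_numpy())
    out["category"] = categorize(out["z"].to_numpy(), z_low=z_low, z_high=z_high)
    return out
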