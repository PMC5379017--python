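"""Published summary statistics of the reference CD30 solid-tumor screen.

The original clinical-genomic warehouse behind the CD30 prescreening study is
not publicly deposited; what is available are its printed summaries: the
eligibility-funnel survivor counts, per-tissue global Z-score summaries for
the 24 primary tumor sites with at least 50 expression profiles, and the
RNA-group-conditional IHC positivity counts for the four tumor types taken
to protein-level confirmation.  Those summaries are recorded here verbatim
and serve two purposes:

* calibration defaults for :mod:`prescreen.simulate`, so synthetic
  warehouses reproduce the reference cohort's statistical structure, and
* direct inputs for re-deriving every downstream quantity that is a pure
  function of the printed counts (pooled group positivity, confusion-table
  metric ranges, between-group exact tests).

All Z-score figures are unitless global Z values; percentages are of
samples within the row's tissue.
"""

from __future__ import annotations

from types import MappingProxyType

#: Ordered eligibility-funnel stages with reference survivor counts.
#: Each stage is a subset of the one before it.
FUNNEL_STAGE_COUNTS: tuple[tuple[str, int], ...] = (
    ("consented", 120_887),
    ("consent_active", 99_241),
    ("alive", 49_562),
    ("has_ffpe", 12_802),
    ("has_expression", 8_307),
    ("z_ge_threshold", 1_138),
)

#: Per-stage retention probabilities implied by the reference funnel counts
#: (count of a stage divided by the count of the stage before it).  The final
#: Z-score stage is not a Bernoulli eligibility draw and is excluded.
FUNNEL_RETENTION_RATES: tuple[tuple[str, float], ...] = tuple(
    (FUNNEL_STAGE_COUNTS[i][0], FUNNEL_STAGE_COUNTS[i][1] / FUNNEL_STAGE_COUNTS[i - 1][1])
    for i in range(1, 5)
)

#: Per-tissue reference summaries: n profiled samples, n with global Z >= 1,
#: the printed integer percentage, and mean / median / SD of the tissue's
#: global Z-scores.  Tissues with fewer than 50 samples were not reported.
TISSUE_SUMMARY: tuple[tuple[str, int, int, int, float, float, float], ...] = (
    # (tissue, n, n_high, pct_high_printed, mean_z, median_z, sd_z)
    ("lymph_nodes", 50, 25, 50, 1.271, 1.011, 1.382),
    ("soft_tissue", 94, 30, 32, 0.512, 0.399, 1.237),
    ("ovary", 668, 141, 21, 0.182, 0.092, 1.104),
    ("oral_cavity", 96, 20, 21, 0.444, 0.475, 0.887),
    ("lung", 2667, 503, 19, 0.178, 0.202, 0.986),
    ("esophagus", 89, 16, 18, 0.092, 0.099, 0.988),
    ("skin", 562, 101, 18, 0.062, 0.152, 1.132),
    ("cervix", 75, 13, 17, 0.204, 0.183, 0.939),
    ("bladder", 208, 35, 17, 0.087, 0.107, 0.996),
    ("breast", 3676, 529, 14, 0.065, 0.015, 0.913),
    ("rectum_anus", 180, 26, 14, 0.084, -0.003, 0.961),
    ("larynx", 54, 7, 13, 0.285, 0.317, 0.648),
    ("small_intestine", 50, 6, 12, -0.721, -0.713, 1.356),
    ("stomach", 128, 15, 12, -0.061, 0.040, 1.125),
    ("uterus", 374, 43, 11, -0.251, -0.329, 1.036),
    ("pancreas", 457, 49, 11, -0.046, -0.026, 0.940),
    ("thyroid", 70, 7, 10, 0.024, 0.274, 0.946),
    ("endometrium", 334, 30, 9, -0.293, -0.339, 0.986),
    ("large_bowel", 2077, 178, 9, -0.152, -0.193, 0.871),
    ("kidney", 846, 53, 6, -0.154, -0.123, 0.866),
    ("brain", 435, 24, 6, -0.500, -0.520, 1.059),
    ("renal_pelvis", 62, 3, 5, -0.612, -0.643, 1.022),
    ("prostate", 305, 9, 3, -0.636, -0.655, 0.802),
    ("liver", 113, 2, 2, -0.826, -0.784, 0.915),
)

#: Total samples across the listed tissues (the background set for the
#: per-tissue enrichment tests re-derivable from the printed counts).
TISSUE_SUMMARY_TOTAL_N: int = sum(row[1] for row in TISSUE_SUMMARY)
TISSUE_SUMMARY_TOTAL_HIGH: int = sum(row[2] for row in TISSUE_SUMMARY)

#: RNA-group-conditional IHC positivity probabilities pooled over the four
#: protein-confirmed tumor types (0/39 low, 1/39 medium, 12/39 high).
GROUP_POSITIVITY_RATES: MappingProxyType = MappingProxyType(
    {"low": 0.0 / 39.0, "medium": 1.0 / 39.0, "high": 12.0 / 39.0}
)

#: Per-tumor-type IHC confirmation counts: for each RNA group the number of
#: samples screened by IHC and the number called CD30-positive.
CONCORDANCE_STRATA: MappingProxyType = MappingProxyType(
    {
        "breast": {"low": (10, 0), "medium": (10, 0), "high": (10, 3)},
        "lung": {"low": (9, 0), "medium": (10, 0), "high": (10, 4)},
        "ovary": {"low": (10, 0), "medium": (9, 0), "high": (10, 2)},
        "skin": {"low": (10, 0), "medium": (10, 1), "high": (9, 3)},
    }
)


def pooled_group_counts() -> dict[str, tuple[int, int]]:
    """Sum the per-tumor IHC confirmation counts over tumor types.

    Returns
    -------
    dict
        ``{group: (n_screened, n_ihc_positive)}`` pooled across the four
        protein-confirmed tumor types.
    """
    pooled: dict[str, list[int]] = {g: [0, 0] for g in ("low", "medium", "high")}
    for counts in CONCORDANCE_STRATA.values():
        for group, (screened, positive) in counts.items():
            pooled[group][0] += screened
            pooled[group][1] += positive
    return {g: (v[0], v[1]) for g, v in pooled.items()}
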