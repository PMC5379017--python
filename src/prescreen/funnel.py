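"""Ordered eligibility funnel and attrition reporting.

Trial prescreening against a clinical-genomic warehouse proceeds through
an ordered sequence of inclusion filters, each applied to the survivors of
the previous one:

1. all consented patients,
2. consent still active (not withdrawn, site open to accrual),
3. vital status alive,
4. archival FFPE tissue available,
5. expression assay available,
6. biomarker-high (global Z-score at or above the threshold).

The report carries the survivor count after every stage and the
identifiers of the final candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["FunnelReport", "apply_funnel", "BOOLEAN_STAGES"]

#: Eligibility flags applied in order after the all-consented stage.
BOOLEAN_STAGES: tuple[str, ...] = ("consent_active", "alive", "has_ffpe", "has_expression")


@dataclass(frozen=True)
class FunnelReport:
    """Per-stage survivor counts and the final candidate identifiers."""

    stages: tuple[tuple[str, int], ...]
    final_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = [n for _, n in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("stage counts must be nonincreasing")
        if self.stages and len(self.final_ids) != counts[-1]:
            raise ValueError("final_ids length must equal the last stage count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_remaining"])


def apply_funnel(
    patients: pd.DataFrame,
    zscores: pd.DataFrame,
    z_threshold: float = 1.0,
) -> FunnelReport:
    """Apply the eligibility filters in order and report attrition.

    Parameters
    ----------
    patients : pandas.DataFrame
        One row per patient with ``patient_id`` and the boolean columns
        ``consent_active, alive, has_ffpe, has_expression``.
    zscores : pandas.DataFrame
        Z assignments with ``patient_id`` and ``z``; every patient with
        ``has_expression`` true must appear here.  Whether the Z values
        were standardized globally or within the funnel survivors is the
        caller's choice — the funnel applies whatever table it is given.
    z_threshold : float
        Final-stage cut; survivors have ``z >= z_threshold``.

    Returns
    -------
    FunnelReport
    """
    required = ["patient_id", *BOOLEAN_STAGES]
    missing = [c for c in required if c not in patients.columns]
    if missing:
        raise ValueError(f"patients table lacks required column(s): {', '.join(missing)}")
    for col in ("patient_id", "z"):
        if col not in zscores.columns:
            raise ValueError(f"zscores table lacks required column {col!r}")

    stages: list[tuple[str, int]] = [("consented", len(patients))]
    survivors = patients
    for stage in BOOLEAN_STAGES:
        survivors = survivors[survivors[stage].astype(bool)]
        stages.append((stage, len(survivors)))

    expr_ids = set(survivors["patient_id"])
    z_by_patient = zscores.set_index("patient_id")["z"]
    missing_z = expr_ids - set(z_by_patient.index)
    if missing_z:
        some = ", ".join(sorted(map(str, missing_z))[:5])
        raise ValueError(
            f"{len(missing_z)} patient(s) with an expression assay lack a Z-score "
            f"assignment (e.g. {some})"
        )
    final = survivors[
        z_by_patient.reindex(survivors["patient_id"]).to_numpy() >= z_threshold
    ]
    stages.append((f"z_ge_{z_threshold:g}", len(final)))
    return FunnelReport(
        stages=tuple(stages), final_ids=tuple(map(str, final["patient_id"]))
    )
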