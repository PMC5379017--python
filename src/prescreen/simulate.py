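"""Synthetic clinical-genomic warehouse generator.

Real prescreening warehouses — hundreds of thousands of consented patients
with banked tumor tissue and pregenerated expression profiles — are not
publicly distributable, so every downstream stage of this package is
exercised against synthetic warehouses whose statistical structure matches
the published summaries of the reference CD30 screen
(:mod:`prescreen.calibration`):

* tissue composition and per-tissue log2-expression distributions
  reproducing the reference per-tissue Z-score means and spreads;
* independent per-stage eligibility booleans calibrated to the reference
  funnel's retention ratios;
* a latent per-sample IHC-positivity flag drawn conditionally on the
  sample's RNA expression group, calibrated to the reference
  group-conditional positivity rates (0/39 low, 1/39 medium, 12/39 high);
* an inverse staining model that turns a latent flag into a full staining
  profile guaranteed to round-trip through the IHC scoring rules.

A single NumPy generator seeded from the config drives all draws, so an
identical config yields a bit-identical warehouse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import calibration
from .funnel import BOOLEAN_STAGES
from .ihc import StainingProfile
from .scoring import categorize

__all__ = [
    "SimulationConfig",
    "Warehouse",
    "default_config",
    "simulate_warehouse",
    "simulate_staining",
    "simulate_staining_table",
]

_BASE_LOG2 = math.log2(500.0)  # location of the log2 scale after trimmed-mean scaling


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic warehouse.

    Attributes
    ----------
    n_patients : int
        Number of consented patients to simulate.
    tissue_mix : dict[str, float]
        Tumor-site proportions; must sum to 1.
    tissue_expr_params : dict[str, tuple[float, float]]
        Per-tissue (mean, sd) of log2 expression.  Every tissue in
        ``tissue_mix`` must have parameters.
    funnel_rates : tuple[tuple[str, float], ...]
        Ordered (stage name, retention probability) pairs for the boolean
        eligibility stages; each boolean is drawn independently.
    ihc_positivity_by_group : dict[str, float]
        Probability that a sample's latent IHC truth is positive, given
        its RNA group (low / medium / high).
    seed : int
        Seed of the single RNG stream driving all draws.
    p_primary : float
        Probability a patient's disease setting is primary (vs metastatic).
    standardize_within : str
        ``"all_samples"`` — the Z-scores used for the latent IHC draw are
        standardized over every expression sample; ``"funnel_survivors"``
        — the mean/sd come from samples of patients passing all boolean
        eligibility stages (and are applied to everyone).
    """

    n_patients: int
    tissue_mix: dict[str, float]
    tissue_expr_params: dict[str, tuple[float, float]]
    funnel_rates: tuple[tuple[str, float], ...]
    ihc_positivity_by_group: dict[str, float]
    seed: int = 0
    p_primary: float = 0.7
    standardize_within: str = "all_samples"

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if abs(sum(self.tissue_mix.values()) - 1.0) > 1e-9:
            raise ValueError("tissue_mix proportions must sum to 1")
        if any(p < 0 for p in self.tissue_mix.values()):
            raise ValueError("tissue_mix proportions must be nonnegative")
        missing = set(self.tissue_mix) - set(self.tissue_expr_params)
        if missing:
            raise ValueError(
                f"tissue(s) in tissue_mix without expression parameters: {sorted(missing)}"
            )
        for t, (_, sd) in self.tissue_expr_params.items():
            if sd <= 0:
                raise ValueError(f"tissue {t!r}: sd must be positive")
        stage_names = tuple(s for s, _ in self.funnel_rates)
        if stage_names != BOOLEAN_STAGES:
            raise ValueError(f"funnel_rates must name the stages {BOOLEAN_STAGES} in order")
        probs = [r for _, r in self.funnel_rates]
        probs += list(self.ihc_positivity_by_group.values())
        probs.append(self.p_primary)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if set(self.ihc_positivity_by_group) != {"low", "medium", "high"}:
            raise ValueError("ihc_positivity_by_group must have keys low, medium, high")
        if self.standardize_within not in ("all_samples", "funnel_survivors"):
            raise ValueError("standardize_within must be 'all_samples' or 'funnel_survivors'")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["tissue_expr_params"] = {
            t: tuple(v) for t, v in raw["tissue_expr_params"].items()
        }
        raw["funnel_rates"] = tuple((s, float(r)) for s, r in raw["funnel_rates"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        doc = {
            "n_patients": self.n_patients,
            "tissue_mix": dict(self.tissue_mix),
            "tissue_expr_params": {t: list(v) for t, v in self.tissue_expr_params.items()},
            "funnel_rates": [list(x) for x in self.funnel_rates],
            "ihc_positivity_by_group": dict(self.ihc_positivity_by_group),
            "seed": self.seed,
            "p_primary": self.p_primary,
            "standardize_within": self.standardize_within,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass(frozen=True)
class Warehouse:
    """One simulated warehouse: patients, expression and latent IHC truth."""

    patients: pd.DataFrame
    expression: pd.DataFrame
    latent_positive: pd.Series  # indexed by sample_id; the ground-truth flag


def default_config(n_patients: int = 50_000, seed: int = 0, **overrides) -> SimulationConfig:
    """A config calibrated to the reference screen's published summaries.

    Tissue proportions follow the per-tissue sample counts; per-tissue
    log2-expression means and spreads reproduce the published per-tissue
    Z-score summaries (shifted to sit around log2(500), which the global
    standardization makes immaterial); funnel retention and
    group-conditional IHC positivity rates follow the published counts.
    """
    total = calibration.TISSUE_SUMMARY_TOTAL_N
    mix = {row[0]: row[1] / total for row in calibration.TISSUE_SUMMARY}
    expr = {row[0]: (_BASE_LOG2 + row[4], row[6]) for row in calibration.TISSUE_SUMMARY}
    cfg = dict(
        n_patients=n_patients,
        tissue_mix=mix,
        tissue_expr_params=expr,
        funnel_rates=calibration.FUNNEL_RETENTION_RATES,
        ihc_positivity_by_group=dict(calibration.GROUP_POSITIVITY_RATES),
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def simulate_warehouse(config: SimulationConfig) -> Warehouse:
    """Draw one synthetic warehouse from the configured model.

    Tissue of origin is drawn from ``tissue_mix``; log2 expression from the
    tissue's normal distribution; the four eligibility booleans
    independently with the configured retention probabilities.  One
    expression record exists per patient with an available assay.  The
    latent IHC flag is Bernoulli with the probability attached to the
    sample's RNA group, where groups come from standardizing the simulated
    log2 values over the scope named by ``standardize_within``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    tissues = np.array(sorted(config.tissue_mix))
    props = np.array([config.tissue_mix[t] for t in tissues])
    props = props / props.sum()

    patient_id = np.array([f"P{i:07d}" for i in range(n)])
    tissue = tissues[rng.choice(len(tissues), size=n, p=props)]
    flags = {stage: rng.random(n) < rate for stage, rate in config.funnel_rates}
    disease = np.where(rng.random(n) < config.p_primary, "primary", "metastatic")

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "consent_active": flags["consent_active"],
            "alive": flags["alive"],
            "has_ffpe": flags["has_ffpe"],
            "has_expression": flags["has_expression"],
            "tissue_type": tissue,
            "disease_setting": disease,
        }
    )

    has_expr = flags["has_expression"]
    expr_idx = np.flatnonzero(has_expr)
    means = np.array([config.tissue_expr_params[t][0] for t in tissues])
    sds = np.array([config.tissue_expr_params[t][1] for t in tissues])
    t_codes = np.searchsorted(tissues, tissue[expr_idx])
    log2_expr = rng.normal(means[t_codes], sds[t_codes])

    expression = pd.DataFrame(
        {
            "sample_id": np.char.replace(patient_id[expr_idx], "P", "S"),
            "patient_id": patient_id[expr_idx],
            "tissue_type": tissue[expr_idx],
            "log2_expression": log2_expr,
        }
    )

    if config.standardize_within == "funnel_survivors":
        survive = np.ones(n, dtype=bool)
        for stage in BOOLEAN_STAGES:
            survive &= flags[stage]
        scope = log2_expr[survive[expr_idx]]
        if scope.size < 2:
            raise ValueError("too few funnel survivors to standardize within")
    else:
        scope = log2_expr
    sd = scope.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in simulated expression")
    z = (log2_expr - scope.mean()) / sd
    group = categorize(z)
    p_pos = np.array([config.ihc_positivity_by_group[g] for g in group])
    latent = rng.random(len(expr_idx)) < p_pos

    return Warehouse(
        patients=patients,
        expression=expression,
        latent_positive=pd.Series(latent, index=expression["sample_id"], name="latent_ihc_positive"),
    )


def simulate_staining(
    is_positive: bool, rng: np.random.Generator, sample_id: str = "sim"
) -> StainingProfile:
    """Draw a staining profile consistent with a latent positivity flag.

    The profile is built from a stained fraction ``f`` (percent of cells
    at any intensity > 0) and a mean stain intensity ``m`` in [1, 3] among
    stained cells, split across two adjacent intensity levels; its H-score
    is ``f * m``.  Positive draws take ``f`` in [10.5, 95] so that both
    positivity rules hold (H = f*m >= f >= 10, fraction >= 10).  Negative
    draws cap ``f`` at 9.5 and ``m`` at 9.5/f so that both rules fail with
    a safety margin; a quarter of negatives are fully unstained.
    """
    if is_positive:
        f = rng.uniform(10.5, 95.0)
        m = rng.uniform(1.0, 3.0)
    else:
        if rng.random() < 0.25:
            return StainingProfile(
                sample_id=sample_id, pct_at_intensity={0: 100.0, 1: 0.0, 2: 0.0, 3: 0.0}
            )
        f = rng.uniform(0.1, 9.5)
        m = rng.uniform(1.0, min(3.0, 9.5 / f))
    if m <= 2.0:
        p2 = f * (m - 1.0)
        p1, p3 = f - p2, 0.0
    else:
        p3 = f * (m - 2.0)
        p2, p1 = f - p3, 0.0
    return StainingProfile(
        sample_id=sample_id,
        pct_at_intensity={0: 100.0 - f, 1: p1, 2: p2, 3: p3},
    )


def simulate_staining_table(
    latent_positive: pd.Series, seed: int
) -> pd.DataFrame:
    """Staining profiles for every sample in a latent-truth series.

    Returns a DataFrame ``sample_id, pct_0, pct_1, pct_2, pct_3`` whose
    positivity calls round-trip to the latent flags.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, flag in latent_positive.items():
        prof = simulate_staining(bool(flag), rng, sample_id=str(sample_id))
        p = prof.pct_at_intensity
        rows.append((prof.sample_id, p[0], p[1], p[2], p[3]))
    return pd.DataFrame(rows, columns=["sample_id", "pct_0", "pct_1", "pct_2", "pct_3"])
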