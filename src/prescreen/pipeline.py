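"""End-to-end pipeline driver: simulate → score → funnel → enrich → IHC →
concordance, with every intermediate written as a TSV report table.

The driver is deliberately dumb glue: each stage is a call into the
corresponding module, and re-running with an identical config is
bit-identical on every output (no timestamps enter the report bundle; the
run log records versions, seed, thresholds and per-stage row counts).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .concordance import (
    GroupCounts,
    build_confusion,
    compare_groups,
    confusion_frame,
    metric_ranges,
    sample_per_group,
)
from .enrichment import export_density, summarize_by_tissue
from .funnel import BOOLEAN_STAGES, apply_funnel
from .ihc import score_staining_table
from .scoring import CATEGORIES, categorize
from .simulate import SimulationConfig, simulate_staining_table, simulate_warehouse

__all__ = ["RunConfig", "run_pipeline"]

#: Tumor types taken to protein-level confirmation in the reference screen.
DEFAULT_CONCORDANCE_TISSUES: tuple[str, ...] = ("breast", "lung", "ovary", "skin")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, paths and seeds for one end-to-end run.

    When ``simulation`` is set the warehouse is simulated; otherwise
    ``patients_path`` / ``expression_path`` / ``staining_path`` name
    existing input tables.  ``group_counts_path`` bypasses per-sample
    concordance and evaluates a pre-tabulated per-stratum group-count
    table instead.
    """

    out_dir: str
    simulation: SimulationConfig | None = None
    patients_path: str | None = None
    expression_path: str | None = None
    staining_path: str | None = None
    group_counts_path: str | None = None
    z_low: float = -1.0
    z_high: float = 1.0
    min_n: int = 50
    min_pct: float = 10.0
    min_h: float = 10.0
    n_per_group: int = 10
    positive_group: str = "high"
    truth: str = "hscore"  # or "fraction"
    concordance_tissues: tuple[str, ...] = DEFAULT_CONCORDANCE_TISSUES
    standardize_within: str = "all_samples"
    seed: int = 0
    quiet: bool = False

    def __post_init__(self) -> None:
        if self.truth not in ("hscore", "fraction"):
            raise ValueError("truth must be 'hscore' or 'fraction'")
        if self.positive_group not in CATEGORIES:
            raise ValueError(f"positive_group must be one of {CATEGORIES}")
        if self.simulation is None and not (self.patients_path and self.expression_path):
            raise ValueError("either a simulation config or input table paths are required")


def zscore_table(
    expression: pd.DataFrame,
    patients: pd.DataFrame,
    z_low: float = -1.0,
    z_high: float = 1.0,
    standardize_within: str = "all_samples",
) -> pd.DataFrame:
    """Global Z-scores with a selectable standardization scope.

    ``all_samples`` standardizes against every expression sample;
    ``funnel_survivors`` takes the mean/sd from samples whose patients pass
    all boolean eligibility stages, then standardizes every sample against
    them.
    """
    x = expression["log2_expression"].to_numpy(dtype=float)
    if standardize_within == "funnel_survivors":
        elig = patients.set_index("patient_id")[list(BOOLEAN_STAGES)].all(axis=1)
        mask = elig.reindex(expression["patient_id"]).fillna(False).to_numpy(dtype=bool)
        scope = x[mask]
        if scope.size < 2:
            raise ValueError("too few funnel survivors to standardize within")
    elif standardize_within == "all_samples":
        scope = x
    else:
        raise ValueError("standardize_within must be 'all_samples' or 'funnel_survivors'")
    sd = scope.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in log2 expression")
    out = expression.copy()
    out["z"] = (x - scope.mean()) / sd
    out["category"] = categorize(out["z"].to_numpy(), z_low=z_low, z_high=z_high)
    return out


def _log(config: RunConfig, lines: list[str], message: str) -> None:
    lines.append(message)
    if not config.quiet:
        print(message, file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle under ``out_dir``.

    Returns a mapping from artifact name to written path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    artifacts: dict[str, Path] = {}
    _log(config, log, f"prescreen {__version__} | numpy {np.__version__} | pandas {pd.__version__}")
    _log(
        config,
        log,
        f"seed={config.seed} z_cuts=({config.z_low},{config.z_high}) min_n={config.min_n} "
        f"min_pct={config.min_pct} min_h={config.min_h} n_per_group={config.n_per_group} "
        f"truth={config.truth} scope={config.standardize_within}",
    )

    # --- inputs: simulate or load -------------------------------------------------
    if config.simulation is not None:
        wh = simulate_warehouse(config.simulation)
        patients, expression = wh.patients, wh.expression
        staining = simulate_staining_table(wh.latent_positive, seed=config.simulation.seed + 1)
        _log(config, log, f"simulated warehouse: {len(patients)} patients, "
                          f"{len(expression)} expression samples")
    else:
        patients = io.read_patients(config.patients_path)
        expression = io.read_expression(config.expression_path)
        staining = io.read_staining(config.staining_path) if config.staining_path else None
        _log(config, log, f"loaded warehouse: {len(patients)} patients, "
                          f"{len(expression)} expression samples")
    for name, df in (("patients", patients), ("expression", expression)):
        io.write_table(df, out / f"{name}.tsv")
        artifacts[name] = out / f"{name}.tsv"
    if staining is not None:
        io.write_table(staining, out / "staining.tsv")
        artifacts["staining"] = out / "staining.tsv"

    # --- scoring ------------------------------------------------------------------
    zsc = zscore_table(
        expression,
        patients,
        z_low=config.z_low,
        z_high=config.z_high,
        standardize_within=config.standardize_within,
    )
    io.write_table(zsc[["sample_id", "z", "category"]], out / "zscores.tsv")
    artifacts["zscores"] = out / "zscores.tsv"
    _log(config, log, f"scored {len(zsc)} samples; "
                      f"high={int((zsc['category'] == 'high').sum())}")

    # --- funnel -------------------------------------------------------------------
    report = apply_funnel(patients, zsc[["patient_id", "z"]], z_threshold=config.z_high)
    io.write_table(report.to_frame(), out / "funnel.tsv")
    (out / "candidates.txt").write_text("\n".join(report.final_ids) + "\n", encoding="utf-8")
    artifacts["funnel"] = out / "funnel.tsv"
    artifacts["candidates"] = out / "candidates.txt"
    _log(config, log, "funnel: " + " -> ".join(f"{s}={n}" for s, n in report.stages))

    # --- tissue enrichment --------------------------------------------------------
    enrich = summarize_by_tissue(zsc, z_threshold=config.z_high, min_n=config.min_n)
    io.write_table(enrich, out / "enrichment.tsv")
    artifacts["enrichment"] = out / "enrichment.tsv"
    density, medians = export_density(zsc, min_n=config.min_n)
    io.write_table(density, out / "density.tsv")
    io.write_table(medians, out / "density_medians.tsv")
    artifacts["density"] = out / "density.tsv"
    _log(config, log, f"enrichment: {len(enrich)} tissues with n >= {config.min_n}")

    # --- IHC scoring --------------------------------------------------------------
    ihc_table = None
    if staining is not None:
        ihc_table = score_staining_table(staining, min_pct=config.min_pct, min_h=config.min_h)
        io.write_table(ihc_table, out / "ihc.tsv")
        artifacts["ihc"] = out / "ihc.tsv"
        _log(config, log, f"ihc: scored {len(ihc_table)} staining profiles")

    # --- concordance --------------------------------------------------------------
    if config.group_counts_path is not None:
        gc_table = io.read_group_counts(config.group_counts_path)
        strata = {
            str(stratum): GroupCounts(
                {
                    str(r.group): (int(r.n_screened), int(r.n_ihc_positive))
                    for r in sub.itertuples(index=False)
                }
            )
            for stratum, sub in gc_table.groupby("stratum")
        }
    elif ihc_table is not None:
        truth_col = "positive_by_hscore" if config.truth == "hscore" else "positive_by_fraction"
        truth = ihc_table.set_index("sample_id")[truth_col]
        strata = {}
        for i, tissue in enumerate(sorted(config.concordance_tissues)):
            sub = zsc[zsc["tissue_type"] == tissue]
            groups = {
                g: sub.loc[sub["category"] == g, "sample_id"].tolist() for g in CATEGORIES
            }
            if any(len(v) == 0 for v in groups.values()):
                _log(config, log, f"concordance: skipping {tissue} (an RNA group is empty)")
                continue
            chosen = sample_per_group(
                groups, config.n_per_group, np.random.SeedSequence([config.seed, i])
            )
            strata[tissue] = GroupCounts(
                {
                    g: (len(ids), int(truth.reindex(ids).sum()))
                    for g, ids in chosen.items()
                }
            )
    else:
        strata = {}

    if strata:
        tables = {
            name: build_confusion(gc, positive_groups={config.positive_group})
            for name, gc in strata.items()
        }
        io.write_table(confusion_frame(tables), out / "concordance.tsv")
        ranges = metric_ranges(tables)
        io.write_table(
            pd.DataFrame(
                [(m, lo, hi) for m, (lo, hi) in ranges.items()],
                columns=["metric", "min", "max"],
            ),
            out / "ranges.tsv",
        )
        artifacts["concordance"] = out / "concordance.tsv"
        artifacts["ranges"] = out / "ranges.tsv"

        pooled: dict[str, list[int]] = {g: [0, 0] for g in CATEGORIES}
        for gc in strata.values():
            for g, (screened, positive) in gc.counts.items():
                pooled[g][0] += screened
                pooled[g][1] += positive
        comparisons = []
        for other in ("low", "medium"):
            if other == config.positive_group:
                continue
            p = compare_groups(
                (pooled[config.positive_group][1], pooled[config.positive_group][0]),
                (pooled[other][1], pooled[other][0]),
            )
            comparisons.append((f"{config.positive_group}_vs_{other}", p))
        io.write_table(
            pd.DataFrame(comparisons, columns=["comparison", "fisher_p"]),
            out / "group_comparisons.tsv",
        )
        artifacts["group_comparisons"] = out / "group_comparisons.tsv"
        _log(config, log, "concordance: " + "; ".join(
            f"{name}: tp={t.tp} fp={t.fp} fn={t.fn} tn={t.tn}" for name, t in tables.items()
        ))

    (out / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    artifacts["run_log"] = out / "run_log.txt"
    return artifacts
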