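# Methods

## The screening model

The package implements a two-tier biomarker screen. Tier one is cheap and
warehouse-wide: one gene's expression, measured on arrays, is standardized
against the entire multi-tissue sample set (primary and metastatic disease
pooled) and trichotomized. Tier two is expensive and per-slide:
immunohistochemistry (IHC) on archival FFPE tissue, read semiquantitatively
by a pathologist. The statistical question throughout is how well tier-one
positivity (RNA-high) predicts tier-two positivity (protein expression),
because tier two is what actually gates trial enrollment.

### Expression scaling and the global Z-score

Raw probe intensities for an array are multiplied by a single factor `c`
chosen so that the trimmed mean of the scaled vector equals 500, then log2
transformed. The trim removes the lowest and highest 2% of sorted values
from each tail before averaging (`scipy.stats.trim_mean`); 2% per tail is
the conventional choice for this scaling step and is exposed as
`trim_fraction`. Scaled values below 1.0 are clipped to 1.0 before the
log2 so degenerate zero intensities map to 0 rather than −∞; this affects
only synthetic corner cases, since real scaled intensities sit far above 1.

The global Z-score is `(x − x̄)/s` with the sample (n−1) standard
deviation. The n−1 denominator is a documented choice (the definition is
silent on it in the source material); at warehouse sample sizes the
difference from the n denominator is far below every decision threshold.
Groups are **low** z ≤ −1, **medium** −1 < z < 1, **high** z ≥ 1; the
boundary values belong to the outer groups. The medium interval is read as
the open interval (−1, 1), which is the only reading consistent with the
≤/≥ definitions of the outer groups.

The composed map raw-intensities → category is invariant to multiplying
all raw intensities by a positive constant and to adding a constant to all
log2 values (both shift the whole set, and standardization removes
location and scale); these invariances are property-tested.

Per-tissue or per-cohort re-standardization is deliberately out of scope:
the global cut is the published procedure, and a single cut is known to
fit poorly at the extremes (very high- or very low-expressing cancer
types). The `z_low`/`z_high` cuts are parameters for sensitivity analyses.

### Eligibility funnel

Filters are applied in a fixed order — all consented → consent active →
alive → FFPE available → expression assay available → z ≥ threshold —
each to the survivors of the previous stage, so counts are cumulative and
nonincreasing (enforced and property-tested). The funnel consumes whatever
Z table it is given; see the standardization-scope note below.

### Tissue-of-origin enrichment

For each tumor site with at least `min_n = 50` samples, the 2×2 table
(site-high, site-not-high, rest-high, rest-not-high) is tested with a
two-sided Fisher exact test, where "rest" is every other sample passed to
the operation — callers control the background by controlling the input.
Re-deriving the reference screen's lymph-node p-value from its printed
counts against the 13,670 samples of its listed tissues reproduces the
printed 8.12×10⁻¹⁰, which pins that background choice; the package keeps
the caller-supplied-background contract rather than hard-coding it.

The two-sided p follows the minimum-likelihood convention: with margins
fixed, sum the hypergeometric probabilities of every table whose
probability is at most that of the observed table, treating probabilities
within a relative 1e-14 as tied. The implementation evaluates the whole
hypergeometric support at once (`scipy.stats.hypergeom` pmf, sort,
cumulative sum), which makes exhaustive verification cheap: tests compare
it against exact integer-arithmetic enumeration for every 2×2 table with
grand total ≤ 60 and against `scipy.stats.fisher_exact` on random tables.
The odds ratio is the sample odds ratio `ad/bc`, reported as ∞ (or NaN for
0/0) rather than Haldane-corrected — it is display-only; the p-value is
the inferential quantity. Raw p-values are reported without
multiple-testing correction, matching the published presentation.
Percentages in report tables are rounded half away from zero, the printed
convention of the source tables.

Density exports use `scipy.stats.gaussian_kde` (Scott bandwidth) per
qualifying tissue on a shared grid padded 3 Z-units beyond the pooled
range, so each curve integrates to 1 on the grid to better than 1e-3.

### IHC scoring

A staining profile gives the percent of cells at intensities 0–3+
(membranous, cytoplasmic and Golgi staining pooled; percentages may be
fractional). The H-score is `Σ i·pct_i ∈ [0, 300]`; `H/100` is the mean
stain intensity per cell. Two positivity rules coexist: the
trial-eligibility rule (≥ 10% of cells at any intensity > 0) and the
H-score rule (H ≥ 10). They are independent operations; the concordance
stage uses the H-score rule as its default truth call, with the fraction
rule selectable. Note the logical relation at the default thresholds:
every stained cell contributes at least intensity 1, so H ≥ stained
fraction and fraction-positivity *implies* H-positivity; the converse
fails (5% of cells at 3+ gives H = 15 with only 5% stained).

### Concordance metrics

Per RNA group, `n_per_group` samples are drawn uniformly without
replacement (9–10 in the reference screen; configurable) and their IHC
truth tallied. Screen-positive is the high group; low and medium pool into
screen-negative — the pooling under which the published metric ranges
reproduce exactly. Accuracy, sensitivity, specificity, PPV and NPV are
percentages; any metric with a zero denominator is undefined and reported
as missing, never 0 or 100. Reported metrics are rounded half away from
zero to integer percent (70.37 → 70, 79.31 → 79, matching the printed
ranges); exact values are written alongside. Between-group positivity
differences use the same two-sided Fisher exact test; two-sided reproduces
both published p-values (1.8×10⁻⁴, 1.5×10⁻³). Confidence intervals and
ROC analysis over continuous Z cuts are out of scope.

## The synthetic warehouse

The simulator emulates the reference screen's published structure, and its
defaults are that calibration:

- **Tissue mix**: the 24 listed tumor sites, proportional to their
  published sample counts (13,670 samples total).
- **Expression**: per-tissue normal log2 expression with mean
  `log2(500) + m_t` and the published per-tissue SD, where `m_t` is the
  published per-tissue mean Z. Anchoring at log2(500) puts values on the
  scale a trimmed-mean-500 pipeline produces; the anchor is immaterial
  under global standardization. Because the global mixture of these
  components has mean ≈ 0 and SD ≈ 1 on the Z scale, the simulated
  per-tissue Z summaries land near the published ones without any
  fine-tuning.
- **Funnel**: four independent Bernoulli eligibility flags with retention
  99,241/120,887 (active consent), 49,562/99,241 (alive), 12,802/49,562
  (FFPE), 8,307/12,802 (expression assay). Only marginal counts are
  published, so no dependence structure is modeled — the simplest model
  that reproduces the published ratios.
- **Latent protein truth**: Bernoulli per sample with probability 0/39,
  1/39 or 12/39 by RNA group — the published pooled positivity rates. The
  dependence is on group, not continuously on Z, because group-level
  concordance is the only published signal; a continuous dose-response is
  deferred.
- **Disease setting**: primary vs metastatic at 0.7/0.3. The split is not
  published; 70% primary is a realistic archival-bank figure, and nothing
  downstream consumes the field (it exists so record schemas are complete).
- One expression sample per patient: the funnel is patient-level, and
  multi-sample patients would add bookkeeping without testable behavior.

A single `numpy.random.default_rng(seed)` stream drives all draws in a
fixed order, so an identical config is bit-identical. Staining profiles
are generated by an inverse model of the scorer: a stained fraction `f`
and mean intensity `m ∈ [1, 3]` split across two adjacent intensity
levels give `H = f·m`; positive draws take `f ∈ [10.5, 95]` (so both
positivity rules hold), negative draws cap `f ≤ 9.5` and `m ≤ 9.5/f` (so
both fail), with a quarter of negatives fully unstained. The half-point
margins keep the round-trip through the scorer exact under floating-point
arithmetic; tests assert zero round-trip error in both directions.

**What the simulator does not emulate**: probe-level array noise and
normalization artifacts, correlated eligibility (e.g. alive patients being
likelier to have tissue), within-tissue substructure (histology,
metastatic site), continuous RNA–protein dose response, pathologist
inter-rater variability, and longitudinal follow-up. Passing tests
therefore demonstrate that the analysis machinery is correct under the
published marginal structure — not that the published biology would
replicate in a new cohort.

### Standardization scope

It is not stated whether the funnel's final Z cut used Z-scores
standardized over all profiled samples or recomputed within the funnel
survivors. Both are supported (`standardize_within = "all_samples" |
"funnel_survivors"`, in the simulator and the pipeline); the default is
`all_samples`, since the published Methods derive the global Z from the
entire data set. The survivor scope takes mean and SD from survivors and
applies them to everyone, preserving sample ordering.

## Numerical choices and degenerate inputs

- Fisher tie tolerance: relative 1e-14, matching scipy's convention, so
  the in-package computation and `scipy.stats.fisher_exact` agree to
  ~1e-12 or better everywhere tested.
- Zero-variance expression, empty tables, all-zero intensity vectors,
  probabilities outside [0, 1], tissue-mix sums off by more than 1e-9 and
  staining rows not summing to 100 (tolerance 1e-6) are rejected with
  named-column error messages rather than propagated.
- TSV I/O writes shortest round-trip float representations and reads with
  `float_precision="round_trip"`, so write→read is lossless and re-runs
  are byte-identical.
- Report problem sizes: acceptance-style checks simulate 50,000-patient
  warehouses (statistical recovery bands of ±3 SE are then a small
  fraction of each rate); unit tests use 2,000–20,000 patients.

## Known limitations

- The per-tissue enrichment p-values depend on the background set the
  caller supplies; there is no canonical background constant in the
  package beyond the calibration table.
- Funnel stages are modeled independent, so simulated joint attrition
  should not be interpreted epidemiologically.
- The published per-tissue means/medians/SDs summarize an unreleased
  cohort; the simulator reproduces them only in distribution, and no test
  asserts them as point targets.
- Undefined diagnostic metrics are dropped from min–max ranges; a stratum
  set in which a metric is never defined yields no range for it.
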