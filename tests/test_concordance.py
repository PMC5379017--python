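import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prescreen.concordance import (
    ConfusionTable,
    GroupCounts,
    build_confusion,
    compare_groups,
    metric_ranges,
    sample_per_group,
)


def gc(low, medium, high):
    return GroupCounts({"low": low, "medium": medium, "high": high})


class TestBuildConfusion:
    def test_lung_counts(self):
        t = build_confusion(gc((9, 0), (10, 0), (10, 4)))
        assert (t.tp, t.fp, t.fn, t.tn) == (4, 6, 0, 19)
        r = t.rounded()
        assert r["sensitivity"] == 100
        assert r["specificity"] == 76
        assert r["ppv"] == 40
        assert r["npv"] == 100
        assert r["accuracy"] == 79

    def test_skin_counts(self):
        t = build_confusion(gc((10, 0), (10, 1), (9, 3)))
        assert (t.tp, t.fp, t.fn, t.tn) == (3, 6, 1, 19)
        assert t.rounded()["sensitivity"] == 75
        assert t.rounded()["npv"] == 95

    def test_zero_denominators_reported_undefined(self):
        # every screened sample is a true positive: no truth-negatives and
        # no screen-negatives, so specificity and npv have no denominator
        t = build_confusion(GroupCounts({"high": (10, 10)}))
        assert t.specificity is None and t.npv is None
        assert t.rounded()["specificity"] is None
        assert t.sensitivity == 100.0
        # with truth-negatives present but all screened positive, specificity
        # is a defined 0%, not undefined
        t2 = build_confusion(GroupCounts({"high": (10, 4)}))
        assert t2.specificity == 0.0 and t2.npv is None

    def test_empty_positive_groups_rejected(self):
        with pytest.raises(ValueError):
            build_confusion(gc((1, 0), (1, 0), (1, 1)), positive_groups=set())

    def test_invalid_group_counts_rejected(self):
        with pytest.raises(ValueError):
            gc((5, 6), (1, 0), (1, 0))

    def test_degenerate_partition(self):
        """All groups screen-positive: no screen-negatives exist, so npv is
        undefined, sensitivity is trivially 100% and ppv equals the overall
        positivity rate (specificity is a defined 0% whenever truth-negatives
        exist)."""
        t = build_confusion(
            gc((10, 1), (10, 2), (10, 3)), positive_groups={"low", "medium", "high"}
        )
        assert t.fn == 0 and t.tn == 0
        assert t.npv is None
        assert t.specificity == 0.0
        assert t.sensitivity == 100.0
        assert t.ppv == pytest.approx(100.0 * 6 / 30)

    @given(
        lo=st.tuples(st.integers(1, 30), st.integers(0, 30)).map(lambda t: (max(t), min(t))),
        md=st.tuples(st.integers(1, 30), st.integers(0, 30)).map(lambda t: (max(t), min(t))),
        hi=st.tuples(st.integers(1, 30), st.integers(0, 30)).map(lambda t: (max(t), min(t))),
    )
    def test_accuracy_between_sensitivity_and_specificity(self, lo, md, hi):
        t = build_confusion(gc(lo, md, hi))
        if t.sensitivity is not None and t.specificity is not None:
            lo_m = min(t.sensitivity, t.specificity) - 1e-9
            hi_m = max(t.sensitivity, t.specificity) + 1e-9
            assert lo_m <= t.accuracy <= hi_m


class TestMetricRanges:
    def test_singleton_min_equals_max(self):
        t = build_confusion(gc((9, 0), (10, 0), (10, 4)))
        ranges = metric_ranges({"only": t})
        assert all(lo == hi for lo, hi in ranges.values())

    def test_two_hand_built_tables(self):
        a = ConfusionTable(tp=4, fp=6, fn=0, tn=19)
        b = ConfusionTable(tp=2, fp=8, fn=0, tn=19)
        ranges = metric_ranges({"a": a, "b": b})
        assert ranges["ppv"] == (20, 40)
        assert ranges["accuracy"] == (72, 79)
        assert ranges["sensitivity"] == (100, 100)

    def test_undefined_metrics_skipped(self):
        defined = ConfusionTable(tp=1, fp=1, fn=1, tn=1)
        degenerate = ConfusionTable(tp=2, fp=0, fn=0, tn=0)
        ranges = metric_ranges({"a": defined, "b": degenerate})
        assert ranges["specificity"] == (50, 50)  # only the defined table counts

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metric_ranges({})


class TestCompareGroups:
    def test_printed_pvalues(self):
        assert compare_groups((12, 39), (0, 39)) == pytest.approx(1.8e-4, rel=0.05)
        assert compare_groups((12, 39), (1, 39)) == pytest.approx(1.5e-3, rel=0.05)

    def test_identical_proportions_null(self):
        assert compare_groups((5, 10), (5, 10)) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_groups((11, 10), (0, 10))


class TestSamplePerGroup:
    def test_exhaustion_returns_whole_group(self):
        out = sample_per_group({"g": list("abcde")}, n_per_group=10, seed=0)
        assert sorted(out["g"]) == list("abcde")

    def test_same_seed_same_selection(self):
        groups = {"a": list(range(50)), "b": list(range(100, 160))}
        assert sample_per_group(groups, 10, seed=42) == sample_per_group(groups, 10, seed=42)

    def test_selection_independent_of_dict_order(self):
        groups = {"a": list(range(50)), "b": list(range(100, 160))}
        flipped = {"b": groups["b"], "a": groups["a"]}
        assert sample_per_group(groups, 10, seed=5) == sample_per_group(flipped, 10, seed=5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sample_per_group({"g": []}, 5, seed=0)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            sample_per_group({"g": [1]}, 0, seed=0)

    def test_uniform_selection_frequency(self):
        """Choosing 10 of 100 repeatedly hits each member ~10% of the time."""
        members = list(range(100))
        reps = 10_000
        rng = np.random.default_rng(99)
        hits = np.zeros(100)
        for _ in range(reps):
            for m in sample_per_group({"g": members}, 10, seed=rng)["g"]:
                hits[m] += 1
        freq = hits / reps
        se = math.sqrt(0.1 * 0.9 / reps)
        assert np.all(np.abs(freq - 0.1) <= 4 * se)  # 100 simultaneous checks


def test_pipeline_parameter_recovery():
    """Sampling 2,000 per RNA group from a simulated warehouse recovers the
    configured group-conditional positivity: PPV -> pi_high, NPV -> 1 minus
    the screen-negative pool's mean positivity."""
    from prescreen.pipeline import zscore_table
    from prescreen.simulate import SimulationConfig, simulate_warehouse

    rates = {"low": 0.0, "medium": 1 / 39, "high": 12 / 39}
    cfg = SimulationConfig(
        n_patients=40_000,
        tissue_mix={"only": 1.0},
        tissue_expr_params={"only": (8.0, 1.0)},
        funnel_rates=(
            ("consent_active", 1.0),
            ("alive", 1.0),
            ("has_ffpe", 1.0),
            ("has_expression", 1.0),
        ),
        ihc_positivity_by_group=rates,
        seed=12345,
    )
    wh = simulate_warehouse(cfg)
    zsc = zscore_table(wh.expression, wh.patients)
    truth = wh.latent_positive
    groups = {
        g: zsc.loc[zsc["category"] == g, "sample_id"].tolist()
        for g in ("low", "medium", "high")
    }
    n_per = 2_000
    chosen = sample_per_group(groups, n_per, seed=54321)
    counts = gc(
        *[
            (len(chosen[g]), int(truth.reindex(chosen[g]).sum()))
            for g in ("low", "medium", "high")
        ]
    )
    t = build_confusion(counts)
    pi_high = rates["high"]
    n_hi = len(chosen["high"])
    assert abs(t.ppv / 100 - pi_high) <= 3 * math.sqrt(pi_high * (1 - pi_high) / n_hi)
    n_lo, n_md = len(chosen["low"]), len(chosen["medium"])
    pi_neg = (n_lo * rates["low"] + n_md * rates["medium"]) / (n_lo + n_md)
    assert abs(t.npv / 100 - (1 - pi_neg)) <= 3 * math.sqrt(
        pi_neg * (1 - pi_neg) / (n_lo + n_md)
    )
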