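"""Tests for ROC/AUC evaluation, deviation statistics and batch
consistency."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioage import (
    CohortConfig,
    DegenerateStatisticsError,
    auc,
    auc_ci_and_test,
    batch_consistency,
    binary_labels,
    build_cohort,
    compare_groups,
    deviation_stats,
    evaluate_cohort,
)


def pair_counting_auc(scores, labels):
    """Exhaustive oracle: fraction of (event, non-event) pairs won, ties
    counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_tied_example(self):
        # pairs: (2,1)=1, (2,2)=0.5, (3,1)=1, (3,2)=1 -> 3.5/4
        assert auc([1, 2, 2, 3], [0, 0, 1, 1]) == pytest.approx(0.875)

    def test_chance_level_on_independent_labels(self, rng):
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.3
        assert auc(scores, labels.astype(int)) == pytest.approx(0.5, abs=0.02)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateStatisticsError):
            auc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=200)
    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=30).filter(
            lambda v: len(v) >= 2
        ),
        st.data(),
    )
    def test_matches_pair_counting_oracle(self, scores, data):
        labels = data.draw(
            st.lists(
                st.integers(0, 1), min_size=len(scores), max_size=len(scores)
            ).filter(lambda y: 0 < sum(y) < len(y))
        )
        assert auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=500)
        labels = (rng.random(500) < 0.2).astype(int)
        labels[0], labels[1] = 0, 1
        a = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert auc(3 * scores - 7, labels) == pytest.approx(a, abs=1e-12)

    def test_agrees_with_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = rng.integers(0, 6, size=100).astype(float)
            labels = (rng.random(100) < 0.3).astype(int)
            labels[:2] = [0, 1]
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=300)
        labels = (rng.random(300) < 0.3).astype(int)
        labels[0], labels[1] = 0, 1
        assert auc(scores, 1 - labels) == pytest.approx(
            1 - auc(scores, labels), abs=1e-12
        )


class TestAucCiAndTest:
    def test_perfect_separation_ci_truncated(self):
        a, ci, p = auc_ci_and_test([1, 2, 3, 4], [0, 0, 1, 1])
        assert a == 1.0
        assert ci[1] == 1.0

    def test_reproducible(self, rng):
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.2).astype(int)
        labels[:2] = [0, 1]
        assert auc_ci_and_test(scores, labels) == auc_ci_and_test(scores, labels)

    def test_ci_brackets_point_estimate(self, rng):
        scores = rng.normal(size=300) + np.repeat([0, 1], 150)
        labels = np.repeat([0, 1], 150)
        a, ci, p = auc_ci_and_test(scores, labels)
        assert ci[0] <= a <= ci[1]
        assert p < 0.05

    def test_exact_mannwhitney_alternative(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.4).astype(int)
        labels[:2] = [0, 1]
        a1, ci1, p1 = auc_ci_and_test(scores, labels, method="delong")
        a2, ci2, p2 = auc_ci_and_test(scores, labels, method="mannwhitney_exact")
        assert a1 == a2 and ci1 == ci2
        assert 0 <= p2 <= 1

    def test_too_few_per_class(self):
        with pytest.raises(DegenerateStatisticsError):
            auc_ci_and_test([1, 2, 3], [0, 0, 1])


class TestDeviationStats:
    def test_identical_vectors(self):
        d = deviation_stats([50, 60, 70], [50, 60, 70])
        assert (d.mean, d.median, d.iqr, d.fraction_higher) == (0, 0, 0, 0)
        assert d.fraction_equal == 1.0

    def test_hand_computed(self):
        d = deviation_stats([50, 70], [60, 60])
        assert d.mean == 10.0
        assert d.fraction_higher == 0.5
        assert d.fraction_lower == 0.5
        assert d.mean_signed == 0.0

    def test_iqr_linear_interpolation(self):
        d = deviation_stats([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert d.iqr == 2.0  # Q3 - Q1 = 4 - 2 on (1..5)

    def test_sd_uses_sample_denominator(self):
        d = deviation_stats([1.0, 3.0], [0.0, 0.0])
        assert d.sd == pytest.approx(np.std([1, 3], ddof=1))


class TestBinaryLabels:
    def test_event_within_followup(self):
        recs = build_cohort(CohortConfig(n_patients=50, seed=2, parse_failure_rate=0))
        labels = binary_labels(recs)
        for r, y in zip(recs, labels):
            assert y == (1 if r.mace_event != "none" else 0)

    def test_study_composition_counts(self):
        """A cohort with the reference composition (2 deaths + 5 MIs + 22
        late revascularizations among 346) yields 29 positive labels."""
        import dataclasses

        recs = build_cohort(CohortConfig(n_patients=346, seed=1, parse_failure_rate=0))
        events = ["death"] * 2 + ["myocardial_infarction"] * 5 + [
            "late_revascularization"
        ] * 22
        fixed = []
        for i, r in enumerate(recs):
            if i < len(events):
                fixed.append(
                    dataclasses.replace(
                        r, mace_event=events[i], mace_event_time=r.followup_time / 2
                    )
                )
            else:
                fixed.append(
                    dataclasses.replace(r, mace_event="none", mace_event_time=None)
                )
        assert binary_labels(fixed).sum() == 29


class TestBatchConsistency:
    @pytest.fixture()
    def cohort_arrays(self):
        recs = build_cohort(CohortConfig(n_patients=346, seed=4, parse_failure_rate=0))
        bio = np.array([r.true_bioage for r in recs])
        age = np.array([r.chrono_age for r in recs])
        return bio, age, binary_labels(recs)

    def test_single_batch_equals_full_summary(self, cohort_arrays):
        bio, age, y = cohort_arrays
        table = batch_consistency(bio, age, y, [len(y)])
        summary = evaluate_cohort(bio, age, y)
        assert table.loc[0, "auc_bioage"] == summary.auc_bioage
        assert table.loc[0, "p_chrono"] == summary.p_chrono

    def test_cumulative_prefixes(self, cohort_arrays):
        bio, age, y = cohort_arrays
        table = batch_consistency(bio, age, y, (94, 149, 252, 346))
        assert len(table) == 4
        assert list(table["n"]) == [94, 149, 252, 346]
        assert list(table["n_events"]) == sorted(table["n_events"])
        full = evaluate_cohort(bio, age, y)
        assert table.loc[3, "auc_bioage"] == full.auc_bioage

    def test_disjoint_mode_partitions(self, cohort_arrays):
        bio, age, y = cohort_arrays
        table = batch_consistency(bio, age, y, (100, 100, 146), cumulative=False)
        assert list(table["n"]) == [100, 100, 146]
        assert table["n_events"].sum() == y.sum()

    def test_single_class_prefix_flagged_not_raised(self):
        bio = np.arange(20.0)
        age = np.arange(20.0)
        y = np.zeros(20, int)
        y[-5:] = 1  # first-10 prefix has no events
        table = batch_consistency(bio, age, y, (10, 20))
        assert bool(table.loc[0, "undefined"])
        assert not bool(table.loc[1, "undefined"])
        assert np.isnan(table.loc[0, "auc_bioage"])


class TestCompareGroups:
    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 300)
        b = rng.normal(1.0, 1, 300)
        _, p = compare_groups(a, b)
        assert p < 1e-6

    def test_identical_groups_not_detected(self, rng):
        x = rng.normal(0, 1, 300)
        _, p = compare_groups(x, x)
        assert p > 0.9
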