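import numpy as np
import pandas as pd
import pytest

from alscore.evaluation import (
    ParticipantTimeline,
    align_to_event,
    bootstrap_ci,
    confusion_matrix,
    multiclass_auc,
    pairwise_r2,
    participant_slope,
)


def brute_force_multiclass_auc(distributions, labels):
    """Mann-Whitney pair-counting oracle with midrank tie handling."""
    p = np.asarray(distributions)
    y = np.asarray(labels)
    aucs = []
    for k in range(5):
        pos = p[y == k, k]
        neg = p[y != k, k]
        if len(pos) == 0 or len(neg) == 0:
            continue
        wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
        aucs.append(wins / (len(pos) * len(neg)))
    return float(np.mean(aucs))


class TestMulticlassAuc:
    def test_perfect_one_hot_ranking_gives_1(self):
        y = np.array([0, 1, 2, 3, 4, 2])
        p = np.eye(5)[y]
        assert multiclass_auc(p, y) == 1.0

    def test_consistently_wrong_one_hot_gives_0(self):
        y = np.array([0, 4, 0, 4])
        p = np.eye(5)[4 - y]  # predicts the opposite extreme
        assert multiclass_auc(p, y) == 0.0

    def test_matches_pair_counting_oracle_on_small_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = rng.integers(4, 13)
            y = rng.integers(0, 5, size=n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.dirichlet(np.ones(5), size=n)
            assert multiclass_auc(p, y) == pytest.approx(
                brute_force_multiclass_auc(p, y), abs=1e-12
            )

    def test_invariant_to_monotone_transform_of_class_scores(self, rng):
        y = rng.integers(0, 5, size=30)
        p = rng.dirichlet(np.ones(5), size=30)
        q = p.copy()
        q[:, 2] = np.exp(3 * q[:, 2])  # strictly increasing transform
        assert multiclass_auc(q, y) == pytest.approx(multiclass_auc(p, y))

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            multiclass_auc(np.full((3, 5), 0.2), np.array([1, 1, 1]))


class TestBootstrapCi:
    def test_constant_statistic_collapses_to_point(self, rng):
        records = rng.normal(size=50)
        lo, hi = bootstrap_ci(lambda s: 7.25, records, n_boot=200, seed=0)
        assert lo == hi == 7.25

    def test_interval_brackets_resample_percentiles(self, rng):
        records = rng.normal(size=100)
        lo, hi = bootstrap_ci(np.mean, records, n_boot=500, seed=1)
        assert lo < float(np.mean(records)) < hi

    def test_undefined_resamples_are_redrawn(self):
        records = np.array([0, 0, 0, 0, 1])  # single-class draws are common

        def metric(sample):
            if len(np.unique(sample)) < 2:
                raise ValueError("single class")
            return float(np.mean(sample))

        lo, hi = bootstrap_ci(metric, records, n_boot=100, seed=2)
        assert 0.0 < lo <= hi < 1.0

    def test_deterministic_given_seed(self, rng):
        records = rng.normal(size=40)
        assert bootstrap_ci(np.mean, records, seed=5) == bootstrap_ci(
            np.mean, records, seed=5
        )

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            bootstrap_ci(np.mean, [], seed=0)


class TestPairwiseR2:
    def test_column_against_itself_is_1(self, rng):
        x = rng.normal(size=50)
        r2 = pairwise_r2(pd.DataFrame({"a": x, "b": x}))
        assert r2.loc["a", "b"] == pytest.approx(1.0)

    def test_sign_blind(self, rng):
        x = rng.normal(size=50)
        r2 = pairwise_r2(pd.DataFrame({"a": x, "b": -x}))
        assert r2.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        df = pd.DataFrame(rng.normal(size=(10000, 2)), columns=["a", "b"])
        assert pairwise_r2(df).loc["a", "b"] < 0.01

    def test_symmetric_unit_diagonal_bounded(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        r2 = pairwise_r2(df)
        np.testing.assert_allclose(r2.values, r2.values.T)
        np.testing.assert_allclose(np.diag(r2.values), 1.0)
        assert ((r2.values >= 0) & (r2.values <= 1)).all()

    def test_zero_variance_column_flagged_not_fabricated(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        r2 = pairwise_r2(df)
        assert np.isnan(r2.loc["a", "b"])
        assert r2.loc["b", "b"] == 1.0


class TestParticipantSlope:
    def test_exact_line_recovers_slope(self):
        tl = ParticipantTimeline("P", "speech", [0, 10, 20], [4, 3, 2])
        slope, r = participant_slope(tl)
        assert slope == pytest.approx(-0.1)
        assert r == pytest.approx(-1.0)

    def test_constant_scores_give_zero_slope(self):
        tl = ParticipantTimeline("P", "speech", [0, 5, 9], [2, 2, 2])
        assert participant_slope(tl) == (0.0, 0.0)

    def test_two_points_insufficient_by_default(self):
        tl = ParticipantTimeline("P", "speech", [0, 10], [4, 3])
        with pytest.raises(ValueError, match="at least 3"):
            participant_slope(tl)

    def test_non_increasing_days_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ParticipantTimeline("P", "speech", [0, 10, 10], [4, 3, 2])


class TestAlignToEvent:
    def test_reindexes_event_to_day_zero(self):
        tl = ParticipantTimeline("P", "speech", [90, 110], [3, 2])
        full, pre, post = align_to_event(tl, 100)
        np.testing.assert_array_equal(full.days, [-10, 10])
        np.testing.assert_array_equal(pre.days, [-10])
        np.testing.assert_array_equal(post.days, [10])

    def test_all_points_before_event_leaves_post_empty(self):
        tl = ParticipantTimeline("P", "speech", [0, 10, 20], [4, 4, 3])
        _, pre, post = align_to_event(tl, 50)
        assert len(post.days) == 0 and len(pre.days) == 3

    def test_pre_post_slopes_gated_by_three_point_rule(self):
        tl = ParticipantTimeline(
            "P", "speech", [0, 10, 20, 30, 40, 50], [4, 4, 3, 3, 2, 2]
        )
        _, pre, post = align_to_event(tl, 25)
        slope_pre, _ = participant_slope(pre)   # 3 points: allowed
        slope_post, _ = participant_slope(post)
        assert slope_pre < 0 and slope_post < 0
        _, pre2, _ = align_to_event(tl, 15)     # only 2 points before
        with pytest.raises(ValueError):
            participant_slope(pre2)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 4, 4])
        cm = confusion_matrix(np.eye(5)[y], y)
        assert cm.sum() == 6
        np.testing.assert_array_equal(cm, np.diag([1, 1, 1, 1, 2]))

    def test_total_count_conserved_and_rows_match_class_counts(self, rng):
        y = rng.integers(0, 5, size=40)
        p = rng.dirichlet(np.ones(5), size=40)
        cm = confusion_matrix(p, y)
        assert cm.sum() == 40
        np.testing.assert_array_equal(cm.sum(axis=1), np.bincount(y, minlength=5))

    def test_uniform_distributions_tie_break_to_class_0(self):
        y = np.array([1, 2, 3])
        cm = confusion_matrix(np.full((3, 5), 0.2), y)
        assert cm[:, 0].sum() == 3 and cm[:, 1:].sum() == 0
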