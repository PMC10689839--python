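import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aucreshape import (
    EPS,
    BoostSchedule,
    BoostVector,
    MulticlassBatch,
    PredictionBatch,
    ThresholdSet,
    compute_boosts,
    reshaped_binary_loss,
    reshaped_multiclass_loss,
)
from aucreshape.core_loss import ConfigurationError


def batch(scores, labels):
    return PredictionBatch(np.asarray(scores, float), np.asarray(labels, int))


class TestPredictionBatch:
    def test_scores_clamped_into_open_interval(self):
        b = batch([0.0, 1.0, 0.5], [0, 1, 1])
        assert b.scores[0] == EPS and b.scores[1] == 1.0 - EPS

    @pytest.mark.parametrize(
        "scores, labels",
        [([], []), ([0.5], [2]), ([0.5, 0.5], [1]), ([np.nan], [1])],
    )
    def test_invalid_inputs_rejected(self, scores, labels):
        with pytest.raises(ValueError):
            batch(scores, labels)


class TestBoostSchedule:
    def test_levels_must_increase_strictly(self):
        with pytest.raises(ConfigurationError):
            BoostSchedule([(0.95, 0.1), (0.90, 0.2)])

    def test_boost_must_be_below_one(self):
        with pytest.raises(ConfigurationError):
            BoostSchedule([(0.95, 1.0)])

    def test_uniform_constructor(self):
        s = BoostSchedule.uniform(0.2, [0.9, 0.95])
        assert s.boosts == (0.2, 0.2) and s.levels == (0.9, 0.95)


class TestComputeBoosts:
    thresholds = ThresholdSet({0.90: 0.50, 0.92: 0.60, 0.95: 0.70, 0.98: 0.80})
    schedule = BoostSchedule(list(zip([0.90, 0.92, 0.95, 0.98], [0.4, 0.2, 0.1, 0.1])))

    def test_negatives_never_boosted(self, rng):
        b = batch(rng.uniform(0.01, 0.99, 50), np.zeros(50))
        assert (compute_boosts(b, self.thresholds, self.schedule).boosts == 0).all()

    def test_single_level_misclassified_positive(self):
        b = batch([0.30], [1])
        out = compute_boosts(b, ThresholdSet({0.95: 0.70}), BoostSchedule([(0.95, 0.2)]))
        assert out.boosts[0] == 0.2

    @pytest.mark.parametrize(
        "score, expected",
        [
            (0.30, 0.4),   # below the lowest threshold: lowest level's boost
            (0.55, 0.2),   # [theta_0.90, theta_0.92)
            (0.65, 0.1),   # [theta_0.92, theta_0.95): the 0.95-level boost
            (0.75, 0.1),   # [theta_0.95, theta_0.98)
            (0.80, 0.0),   # at theta_max: correctly classified
            (0.95, 0.0),
        ],
    )
    def test_band_assignment(self, score, expected):
        """A positive receives the boost of the single band containing its score:
        level s_k's boost applies on [theta_{k-1}, theta_k)."""
        out = compute_boosts(batch([score], [1]), self.thresholds, self.schedule)
        assert out.boosts[0] == expected

    def test_band_assignment_matches_bruteforce_conditional(self, rng):
        """Exhaustive check on random batches against a literal re-evaluation of
        the banded conditional."""
        theta = np.array(self.thresholds.thresholds)
        boosts = np.array(self.schedule.boosts)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            b = batch(rng.uniform(0.01, 0.99, n), rng.integers(0, 2, n))
            got = compute_boosts(b, self.thresholds, self.schedule).boosts
            for i in range(n):
                expected = 0.0
                if b.labels[i] == 1 and b.scores[i] < theta[-1]:
                    k = next(j for j, t in enumerate(theta) if b.scores[i] < t)
                    expected = boosts[k]
                assert got[i] == expected

    def test_boost_targeting_only_misclassified_positives(self, rng):
        theta_max = max(self.thresholds.thresholds)
        for _ in range(50):
            n = int(rng.integers(1, 100))
            b = batch(rng.uniform(0.01, 0.99, n), rng.integers(0, 2, n))
            nz = compute_boosts(b, self.thresholds, self.schedule).boosts > 0
            assert (nz == ((b.labels == 1) & (b.scores < theta_max))).all()

    def test_empty_schedule_yields_zeros(self):
        b = batch([0.3, 0.7], [1, 1])
        assert (compute_boosts(b, ThresholdSet({}), None).boosts == 0).all()

    def test_mismatched_threshold_order_rejected(self):
        bad = ThresholdSet({0.90: 0.8, 0.92: 0.6, 0.95: 0.7, 0.98: 0.9})
        with pytest.raises(ConfigurationError):
            compute_boosts(batch([0.3], [1]), bad, self.schedule)


class TestBinaryLoss:
    @pytest.mark.parametrize(
        "y, p, b, expected",
        [
            (1, 0.4, 0.0, -np.log(0.4)),
            (1, 0.4, 0.2, -np.log(0.2)),
            (0, 0.3, 0.0, -np.log(0.7)),
            (1, 0.1, 0.2, -np.log(EPS)),  # clamp active
        ],
    )
    def test_closed_form_values(self, y, p, b, expected):
        _, per = reshaped_binary_loss(batch([p], [y]), BoostVector(np.array([b])))
        assert per[0] == pytest.approx(expected, abs=1e-9)

    def test_zero_boost_equals_cross_entropy(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 50))
            p = rng.uniform(0.01, 0.99, n)
            y = rng.integers(0, 2, n)
            _, per = reshaped_binary_loss(batch(p, y), BoostVector.zeros(n))
            ce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
            assert np.abs(per - ce).max() <= 1e-12

    @given(
        p=st.floats(0.05, 0.95),
        b1=st.floats(0.0, 0.8),
        b2=st.floats(0.0, 0.8),
    )
    @settings(deadline=None, max_examples=200)
    def test_penalty_monotone_in_boost(self, p, b1, b2):
        lo, hi = sorted((b1, b2))
        _, per_lo = reshaped_binary_loss(batch([p], [1]), BoostVector(np.array([lo])))
        _, per_hi = reshaped_binary_loss(batch([p], [1]), BoostVector(np.array([hi])))
        assert per_hi[0] >= per_lo[0]
        if p - hi > EPS and hi - lo > 1e-9:
            assert per_hi[0] > per_lo[0]

    def test_gradient_amplification(self):
        """With the clamp inactive, |d loss / d p| = 1/(p - b) > 1/p."""
        p, b = 0.5, 0.2
        h = 1e-6
        lo = reshaped_binary_loss(batch([p - h], [1]), BoostVector(np.array([b])))[0]
        hi = reshaped_binary_loss(batch([p + h], [1]), BoostVector(np.array([b])))[0]
        num = (hi - lo) / (2 * h)
        assert num == pytest.approx(-1.0 / (p - b), rel=1e-5)
        assert abs(num) > 1.0 / p

    def test_class_weights_scale_per_sample_losses(self):
        b = batch([0.4, 0.3], [1, 0])
        _, unweighted = reshaped_binary_loss(b, BoostVector.zeros(2))
        _, weighted = reshaped_binary_loss(b, BoostVector.zeros(2), class_weights=(3.0, 0.5))
        assert weighted[0] == pytest.approx(0.5 * unweighted[0])
        assert weighted[1] == pytest.approx(3.0 * unweighted[1])

    def test_boost_of_one_or_more_rejected(self):
        with pytest.raises(ConfigurationError):
            reshaped_binary_loss(batch([0.5], [1]), BoostVector(np.array([1.0])))

    def test_misaligned_boosts_rejected(self):
        with pytest.raises(ConfigurationError):
            reshaped_binary_loss(batch([0.5], [1]), BoostVector.zeros(2))


class TestMulticlassLoss:
    def test_worked_example_mass_moved_to_runner_up(self):
        mb = MulticlassBatch(np.array([[0.5, 0.3, 0.2]]), np.array([2]))
        _, per = reshaped_multiclass_loss(mb, critical_class=2, threshold=0.5, boost=0.1)
        assert per[0] == pytest.approx(-np.log(0.1), abs=1e-12)

    def test_confident_sample_untouched(self):
        mb = MulticlassBatch(np.array([[0.1, 0.1, 0.8]]), np.array([2]))
        _, per = reshaped_multiclass_loss(mb, critical_class=2, threshold=0.5, boost=0.1)
        assert per[0] == pytest.approx(-np.log(0.8), abs=1e-12)

    def test_zero_boost_is_plain_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(4), size=30)
        labels = rng.integers(0, 4, 30)
        mb = MulticlassBatch(probs, labels)
        _, per = reshaped_multiclass_loss(mb, critical_class=1, threshold=0.9, boost=0.0)
        expected = -np.log(probs[np.arange(30), labels])
        assert np.abs(per - expected).max() <= 1e-12

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=50)
    def test_mass_conserved_and_entries_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(1, 20)), int(rng.integers(2, 6))
        probs = rng.dirichlet(np.ones(k), size=n)
        labels = rng.integers(0, k, n)
        crit = int(rng.integers(0, k))
        boost = float(rng.uniform(0, 0.5))
        mb = MulticlassBatch(probs, labels)
        # re-derive the modified vectors by applying the documented rule
        hit = (labels == crit) & (probs[:, crit] < 0.6)
        q = probs.copy()
        for i in np.flatnonzero(hit):
            others = [j for j in range(k) if j != crit]
            m = others[int(np.argmax(q[i, others]))]
            moved = min(boost, q[i, crit])
            q[i, crit] -= moved
            q[i, m] += moved
        assert np.abs(q.sum(axis=1) - 1.0).max() <= 1e-9
        assert (q >= 0).all() and (q <= 1 + 1e-12).all()
        _, per = reshaped_multiclass_loss(mb, crit, threshold=0.6, boost=boost)
        expected = -np.log(np.clip(q[np.arange(n), labels], EPS, None))
        assert np.allclose(per, expected, atol=1e-12)

    def test_tie_broken_toward_lowest_index(self):
        mb = MulticlassBatch(np.array([[0.3, 0.3, 0.4]]), np.array([2]))
        total, per = reshaped_multiclass_loss(mb, critical_class=2, threshold=0.5, boost=0.1)
        # class 0 (not 1) receives the mass; label loss sees 0.4 - 0.1
        assert per[0] == pytest.approx(-np.log(0.3), abs=1e-12)

    def test_critical_class_out_of_range(self):
        mb = MulticlassBatch(np.array([[0.5, 0.5]]), np.array([0]))
        with pytest.raises(ConfigurationError):
            reshaped_multiclass_loss(mb, critical_class=5, threshold=0.5, boost=0.1)
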