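"""Semilog ROC / LogAUC metric tests, including an independent numerical oracle."""

import itertools

import numpy as np
import pytest

from screenopt.enrichment import (
    DEFAULT_LAMBDA,
    RocCurve,
    ScoredClasses,
    adjusted_logauc,
    get_criterion,
    logauc,
    normalized_logauc,
    normalized_logauc_from_ranks,
    random_baseline,
    roc_curve,
)

# closed forms: R = (1 - lam) / (ln10 * log10(1/lam)); worst = -R / (1 - R)
R_0001 = (1 - 0.001) / (np.log(10) * 3.0)
WORST_0001 = -R_0001 / (1 - R_0001)


def semilog_auc_numeric(points, lam=DEFAULT_LAMBDA, n_sub=4000):
    """Independent oracle: per-segment dense trapezoid integration in u = log10(x)."""
    total = 0.0
    for (x1, y1), (x2, y2) in zip(points[:-1], points[1:]):
        if x2 <= lam or x2 <= x1:
            continue
        if x1 < lam:
            y1 = y1 + (y2 - y1) * (lam - x1) / (x2 - x1)
            x1 = lam
        u = np.linspace(np.log10(x1), np.log10(x2), n_sub)
        x = 10.0**u
        y = y1 + (y2 - y1) * (x - x1) / (x2 - x1)
        total += np.trapezoid(y, u)
    return total / np.log10(1.0 / lam)


def rank_scores(positions, total):
    """Scores for a ranking where positives occupy the given 0-based positions."""
    pos = np.array(sorted(positions), dtype=float)
    neg = np.array(sorted(set(range(total)) - set(positions)), dtype=float)
    return ScoredClasses(scores_pos=pos, scores_neg=neg)


class TestRocCurve:
    def test_perfect_separation_passes_0_1(self):
        curve = roc_curve(ScoredClasses([1.0, 2.0], [3.0, 4.0, 5.0]))
        assert any(np.allclose(p, [0.0, 1.0]) for p in curve.points)
        assert np.allclose(curve.points[0], [0, 0]) and np.allclose(curve.points[-1], [1, 1])

    def test_complete_ties_give_diagonal(self):
        curve = roc_curve(ScoredClasses(np.zeros(3), np.zeros(7)))
        assert np.allclose(curve.points, [[0, 0], [1, 1]])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ScoredClasses([], [1.0])

    def test_tied_block_vertices_match_enumeration_oracle(self):
        """Interleaved 2 pos / 4 neg with a tied block: the curve's vertices are the
        cumulative (fpr, tpr) counts at each distinct score, and each vertex equals
        the average endpoint over every strict ordering of the tie."""
        # one score level shared by 1 pos + 2 neg
        scored = ScoredClasses([1.0, 5.0], [2.0, 5.0, 5.0, 9.0])
        curve = roc_curve(scored)
        expected_vertices = [
            (0, 0), (0, 0.5), (0.25, 0.5), (0.75, 1.0), (1.0, 1.0)
        ]
        assert np.allclose(curve.points, expected_vertices)
        # block-boundary vertex equals the mean cumulative counts over orderings
        ends = []
        for perm in set(itertools.permutations(["p", "n", "n"])):
            tp = 1 + perm.count("p")  # pos at score 1 plus tied pos
            fp = 1 + perm.count("n")
            ends.append((fp / 4, tp / 2))
        assert np.allclose(np.mean(ends, axis=0), (0.75, 1.0))

    def test_tie_diagonal_equals_mean_over_orderings_for_uniform_auc(self):
        """For the unweighted AUC the diagonal tie treatment is exactly the
        expectation over uniformly random tie-breaking."""
        scored = ScoredClasses([1.0, 5.0], [2.0, 5.0, 5.0, 9.0])
        pts = roc_curve(scored).points
        auc_diag = np.trapezoid(pts[:, 1], pts[:, 0])
        aucs = []
        for perm in itertools.permutations(["p", "n", "n"]):  # all 3! orderings
            pos, neg = [], []
            layout = ["p", "n", *perm, "n"]
            for rank, c in enumerate(layout):
                (pos if c == "p" else neg).append(rank)
            p = roc_curve(rank_scores_from(pos, neg)).points
            aucs.append(np.trapezoid(p[:, 1], p[:, 0]))
        assert auc_diag == pytest.approx(np.mean(aucs), abs=1e-12)


def rank_scores_from(pos, neg):
    return ScoredClasses(np.array(pos, dtype=float), np.array(neg, dtype=float))


class TestLogAuc:
    def test_perfect_curve_is_exactly_one(self):
        scored = ScoredClasses(np.arange(20.0), np.arange(1000.0) + 100)
        assert logauc(roc_curve(scored)) == 1.0
        assert normalized_logauc(scored) == 1.0

    def test_diagonal_matches_closed_form(self):
        scored = ScoredClasses(np.zeros(5), np.zeros(10))
        assert logauc(roc_curve(scored)) == pytest.approx(R_0001, abs=1e-12)
        assert R_0001 == pytest.approx(0.14462, abs=5e-6)
        assert normalized_logauc(scored) == pytest.approx(0.0, abs=1e-12)

    def test_worst_curve_matches_closed_form(self):
        scored = ScoredClasses(np.arange(20.0) + 2000, np.arange(1000.0))
        assert logauc(roc_curve(scored)) == pytest.approx(0.0, abs=1e-12)
        assert normalized_logauc(scored) == pytest.approx(WORST_0001, abs=1e-12)
        assert WORST_0001 == pytest.approx(-0.16907, abs=5e-6)

    def test_agrees_with_numeric_integration_on_all_small_rankings(self):
        """Closed-form segment integration vs dense numerical oracle, all C(8,k) rankings."""
        lam = DEFAULT_LAMBDA
        for n_pos in range(1, 8):
            for positions in itertools.combinations(range(8), n_pos):
                scored = rank_scores(positions, 8)
                curve = roc_curve(scored, lam)
                expected = semilog_auc_numeric(curve.points, lam)
                assert logauc(curve) == pytest.approx(expected, abs=1e-9)

    def test_rank_fast_path_matches_generic(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n_pos, n_neg = rng.integers(1, 8), rng.integers(1, 40)
            positions = np.sort(rng.choice(n_pos + n_neg, n_pos, replace=False))
            scored = rank_scores(positions, n_pos + n_neg)
            fast = normalized_logauc_from_ranks(positions - np.arange(n_pos), n_neg)
            assert fast == pytest.approx(normalized_logauc(scored), abs=1e-12)


class TestProperties:
    def test_bounded_above_by_one_and_one_iff_perfect(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pos = rng.normal(size=5)
            neg = rng.normal(size=20)
            v = normalized_logauc(ScoredClasses(pos, neg))
            assert v <= 1.0
            assert (v == 1.0) == (pos.max() < neg.min())

    def test_improving_one_positive_never_decreases_value(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            neg = np.sort(rng.normal(size=30))
            pos = rng.normal(size=4)
            base = normalized_logauc(ScoredClasses(pos, neg))
            improved = pos.copy()
            improved[0] -= abs(rng.normal()) + 0.01  # strictly better score
            assert normalized_logauc(ScoredClasses(improved, neg)) >= base - 1e-12

    def test_monotone_curve_validation(self):
        with pytest.raises(ValueError):
            RocCurve(points=np.array([[0.0, 0.5], [0.5, 0.2], [1.0, 1.0]]))

    def test_criterion_registry(self):
        assert get_criterion("normalized_logauc") is normalized_logauc
        scored = ScoredClasses([0.0], [1.0, 2.0])
        assert get_criterion("adjusted_logauc")(scored) == pytest.approx(
            adjusted_logauc(scored)
        )
        with pytest.raises(KeyError):
            get_criterion("pose_reproduction")

    def test_random_baseline_depends_on_lambda(self):
        assert random_baseline(0.01) == pytest.approx((1 - 0.01) / (np.log(10) * 2), abs=1e-12)
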