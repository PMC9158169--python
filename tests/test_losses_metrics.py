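"""Loss identities and confusion-matrix metrics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from hmpi.losses_metrics import (
    LOG_FLOOR,
    CentreSet,
    cce_loss,
    confusion_report,
    evaluate,
    joint_loss,
    lsr_loss,
    smoothed_targets,
    softmax_probs,
)


def random_prob_vectors(n, k, seed):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(k), size=n)
    return p


class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(softmax_probs([0.0, 0.0]), [0.5, 0.5])

    def test_shift_invariance_uniform(self):
        for c in (-3.0, 0.0, 100.0):
            assert np.allclose(softmax_probs([c] * 5), np.full(5, 0.2))

    def test_no_overflow(self):
        p = softmax_probs([1000.0, 0.0])
        assert np.isfinite(p).all() and p[0] > 0.999

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax_probs([np.inf, 0.0])


class TestCce:
    def test_perfect_prediction(self):
        assert cce_loss(np.array([0.0, 1.0]), 1) == pytest.approx(-math.log(1.0 - 0.0))

    def test_uniform_binary(self):
        assert cce_loss(np.array([0.5, 0.5]), 0) == pytest.approx(math.log(2))

    def test_sum_form_equals_shortcut(self):
        # the full sum over classes with one-hot targets vs the -log p(y) shortcut
        for i, p in enumerate(random_prob_vectors(200, 4, seed=1)):
            y = i % 4
            q = smoothed_targets(y, 4, epsilon=0.0)
            sum_form = -(q * np.log(np.maximum(p, LOG_FLOOR))).sum()
            assert cce_loss(p, y) == pytest.approx(sum_form, rel=1e-12)

    def test_zero_probability_floored(self):
        loss = cce_loss(np.array([1.0, 0.0]), 1)
        assert np.isfinite(loss) and loss == pytest.approx(-math.log(LOG_FLOOR))


class TestLsr:
    def test_epsilon_zero_equals_cce(self):
        ps = random_prob_vectors(10_000, 3, seed=2)
        for i, p in enumerate(ps):
            y = i % 3
            assert lsr_loss(p, y, 0.0) == cce_loss(p, y)

    @pytest.mark.parametrize("k", [2, 4, 6])
    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.2, 0.5])
    def test_uniform_p_gives_ln_k(self, k, eps):
        p = np.full(k, 1.0 / k)
        assert lsr_loss(p, 0, eps) == pytest.approx(math.log(k), rel=1e-12)

    def test_smoothed_target_binary(self):
        q = smoothed_targets(0, 2, 0.2)
        assert np.allclose(q, [0.9, 0.1])

    def test_matches_smoothed_sum_form(self):
        for i, p in enumerate(random_prob_vectors(100, 5, seed=3)):
            y = i % 5
            q = smoothed_targets(y, 5, 0.2)
            sum_form = -(q * np.log(p)).sum()
            assert lsr_loss(p, y, 0.2) == pytest.approx(sum_form, rel=1e-10)

    def test_continuity_in_epsilon(self):
        p = np.array([0.7, 0.2, 0.1])
        losses = [lsr_loss(p, 0, e) for e in np.linspace(0, 0.3, 20)]
        assert np.all(np.abs(np.diff(losses)) < 0.05)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            lsr_loss(np.array([0.5, 0.5]), 0, 1.0)


class TestJointLoss:
    def test_at_centre_equals_cce(self):
        centres = CentreSet(np.array([[1.0, 2.0], [3.0, 4.0]]), lam=5.0)
        p = np.array([0.3, 0.7])
        assert joint_loss(p, 1, np.array([3.0, 4.0]), centres) == cce_loss(p, 1)

    def test_lambda_zero_equals_cce(self):
        centres = CentreSet(np.zeros((2, 3)), lam=0.0)
        p = np.array([0.4, 0.6])
        assert joint_loss(p, 0, np.array([9.0, 9.0, 9.0]), centres) == cce_loss(p, 0)

    def test_three_four_five_arithmetic(self):
        centres = CentreSet(np.zeros((2, 2)), lam=0.01)
        p = np.array([0.0, 1.0])
        val = joint_loss(p, 1, np.array([3.0, 4.0]), centres)
        assert val == pytest.approx(0.25, abs=1e-9)

    def test_dominates_cce(self):
        rng = np.random.default_rng(4)
        centres = CentreSet(rng.normal(size=(3, 4)), lam=0.1)
        for i, p in enumerate(random_prob_vectors(50, 3, seed=5)):
            x = rng.normal(size=4)
            assert joint_loss(p, i % 3, x, centres) >= cce_loss(p, i % 3)

    def test_dimension_mismatch(self):
        centres = CentreSet(np.zeros((2, 3)), lam=0.1)
        with pytest.raises(ValueError):
            joint_loss(np.array([0.5, 0.5]), 0, np.zeros(4), centres)


def mcc_oracle(tp, tn, fp, fn):
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return num / den if den else 0.0


class TestEvaluate:
    def test_perfect(self):
        rep = evaluate([1, 0, 1, 0], [1, 0, 1, 0], positive_class=1)
        assert (rep.sn, rep.sp, rep.acc, rep.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_inverted(self):
        rep = evaluate([0, 1, 0, 1], [1, 0, 1, 0], positive_class=1)
        assert rep.mcc == -1.0

    def test_hand_arithmetic_table(self):
        rep = confusion_report(tp=9, fn=1, tn=8, fp=2)
        assert rep.sn == pytest.approx(0.9)
        assert rep.sp == pytest.approx(0.8)
        assert rep.acc == pytest.approx(0.85)
        assert rep.mcc == pytest.approx(mcc_oracle(9, 8, 2, 1))

    def test_exhaustive_small_tables_vs_oracle(self):
        for tp, tn, fp, fn in itertools.product(range(6), repeat=4):
            if tp + tn + fp + fn == 0:
                continue
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = confusion_report(tp=tp, tn=tn, fp=fp, fn=fn)
            assert rep.mcc == pytest.approx(mcc_oracle(tp, tn, fp, fn), abs=1e-12)
            assert -1.0 <= rep.mcc <= 1.0
            assert rep.acc == pytest.approx((tp + tn) / (tp + tn + fp + fn))

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(6)
        truths = rng.integers(2, size=200)
        preds = rng.integers(2, size=200)
        rep = evaluate(list(preds), list(truths), positive_class=1)
        assert rep.mcc == pytest.approx(matthews_corrcoef(truths, preds), abs=1e-12)

    def test_class_swap_invariance(self):
        rng = np.random.default_rng(7)
        truths = list(rng.integers(2, size=100))
        preds = list(rng.integers(2, size=100))
        a = evaluate(preds, truths, positive_class=1)
        b = evaluate([1 - p for p in preds], [1 - t for t in truths], positive_class=0)
        assert a.mcc == pytest.approx(b.mcc)

    def test_degenerate_marginal_flagged(self):
        with pytest.warns(RuntimeWarning):
            rep = evaluate([1, 1, 1], [1, 1, 0], positive_class=1)
        assert rep.mcc == 0.0 and rep.mcc_degenerate

    def test_multiclass_one_vs_rest(self):
        preds = ["a", "b", "c", "a", "b", "c"]
        truths = ["a", "b", "c", "c", "b", "a"]
        rep = evaluate(preds, truths, positive_class="a")
        assert rep.per_class is not None and set(rep.per_class) == {"a", "b", "c"}
        assert rep.per_class["b"].mcc == 1.0

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="outside"):
            evaluate([0, 2], [0, 1], positive_class=1, classes=[0, 1])

    def test_summary_has_four_decimals(self):
        rep = confusion_report(tp=9, fn=1, tn=8, fp=2)
        assert "85.0000" in rep.summary()


def test_expected_cce_minimised_at_true_distribution():
    # proper-scoring spot check: E_y~q[-log p(y)] over a grid of binary p
    # is minimised at p = q
    q = 0.7
    grid = np.linspace(0.01, 0.99, 99)
    risk = [-(q * np.log(g) + (1 - q) * np.log(1 - g)) for g in grid]
    assert abs(grid[int(np.argmin(risk))] - q) < 0.011
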