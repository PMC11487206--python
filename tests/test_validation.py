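"""Diagnostic validation engine: 2x2 tables, ROC, Youden, trapezoid AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frailscreen.errors import ValidationError
from frailscreen.validation import (
    Contingency2x2,
    HIGHER_IS_POSITIVE,
    LOWER_IS_POSITIVE,
    auc_trapezoid,
    contingency,
    diagnostics,
    percent,
    roc_curve,
    round_half_up,
    youden_optimal,
)


class TestContingency:
    def test_perfect_agreement(self):
        v = [True] * 6 + [False] * 4
        c = contingency(v, v)
        assert (c.tp, c.fp, c.fn, c.tn) == (6, 0, 0, 4)

    def test_perfect_disagreement(self):
        cond = [True] * 5 + [False] * 5
        scr = [not x for x in cond]
        c = contingency(scr, cond)
        assert c.tp == 0 and c.tn == 0 and c.fp == 5 and c.fn == 5

    def test_direct_count_n22(self):
        cond = [True] * 5 + [False] * 17
        scr = [True] * 5 + [True] + [False] * 16
        c = contingency(scr, cond)
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 1, 0, 16)
        assert c.total == 22

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            contingency([True], [True, False])

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            Contingency2x2(tp=-1, fp=0, fn=0, tn=2)


class TestDiagnostics:
    def test_reconstructed_tug_row(self):
        d = diagnostics(Contingency2x2(tp=5, fp=1, fn=0, tn=16))
        assert round_half_up(d.sensitivity) == 1.00
        assert round_half_up(d.specificity) == 0.94
        assert round_half_up(d.ppv) == 0.83
        assert round_half_up(d.npv) == 1.00

    def test_reconstructed_sppb_gait_balance_row(self):
        d = diagnostics(Contingency2x2(tp=3, fp=3, fn=0, tn=16))
        assert round_half_up(d.specificity) == 0.84
        assert round_half_up(d.ppv) == 0.50

    def test_zero_denominator_is_undefined_not_clamped(self):
        d = diagnostics(Contingency2x2(tp=0, fp=2, fn=0, tn=8))
        assert d.sensitivity is None
        assert d.specificity == pytest.approx(0.80)

    @given(st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0))
    @settings(derandomize=True, max_examples=200)
    def test_rates_stay_in_unit_interval(self, counts):
        d = diagnostics(Contingency2x2(*counts))
        for v in (d.sensitivity, d.specificity, d.ppv, d.npv, d.fpr):
            assert v is None or 0.0 <= v <= 1.0

    def test_adding_correct_classification_never_hurts(self):
        base = Contingency2x2(tp=4, fp=2, fn=3, tn=6)
        d0 = diagnostics(base)
        d_tp = diagnostics(Contingency2x2(5, 2, 3, 6))
        d_tn = diagnostics(Contingency2x2(4, 2, 3, 7))
        assert d_tp.sensitivity >= d0.sensitivity
        assert d_tn.specificity >= d0.specificity


class TestAucTrapezoid:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0), (0.06, 1.00), (1, 1)], 0.97),   # single-point TUG-style ROC
            ([(0, 0), (0.00, 0.60), (1, 1)], 0.80),   # gait-speed-style ROC
            ([(0, 0), (0.25, 0.75), (1, 1)], 0.75),   # HRR vs falls-risk style
            ([(0, 0), (1, 1)], 0.5),                  # chance diagonal
        ],
    )
    def test_known_areas(self, points, expected):
        assert auc_trapezoid(points) == pytest.approx(expected)

    def test_anchors_added_when_missing(self):
        assert auc_trapezoid([(0.2, 0.8)]) == pytest.approx(
            0.2 * 0.4 + 0.8 * 0.9
        )

    def test_single_operating_point_equals_mean_of_sens_spec(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            sens, spec = rng.uniform(0, 1, 2)
            auc = auc_trapezoid([(1 - spec, sens)])
            assert auc == pytest.approx((sens + spec) / 2)


def brute_force_youden(scores, cond, direction):
    """Independent oracle: exhaustively scan every midpoint cutoff."""
    scores = np.asarray(scores, float)
    cond = np.asarray(cond, bool)
    s = -scores if direction == LOWER_IS_POSITIVE else scores
    distinct = np.unique(s)
    cuts = [np.inf, -np.inf] + list((distinct[:-1] + distinct[1:]) / 2)
    best = -np.inf
    for cut in cuts:
        pos = s >= cut
        tpr = (pos & cond).sum() / cond.sum()
        fpr = (pos & ~cond).sum() / (~cond).sum()
        best = max(best, tpr - fpr)
    return best


class TestRocAndYouden:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert roc.auc == 1.0 and roc.youden_j == 1.0

    def test_integer_scores_bound_operating_points(self):
        scores = [0, 1, 2, 3, 4, 5, 3, 2]
        cond = [False, False, False, True, True, True, True, False]
        roc = roc_curve(scores, cond)
        assert len(roc.points) <= 7  # distinct cutoffs + anchors

    def test_anchor_points_present(self):
        roc = roc_curve([0.1, 0.9], [False, True])
        pts = [(f, t) for _, f, t in roc.points]
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_single_class_condition_rejected(self):
        with pytest.raises(ValidationError, match="tug"):
            roc_curve([1.0, 2.0], [True, True], name="tug")

    def test_lower_is_positive_direction(self):
        # low scores indicate disease: perfect separation again
        roc = roc_curve([1, 2, 3, 10, 11, 12], [True] * 3 + [False] * 3,
                        direction=LOWER_IS_POSITIVE)
        assert roc.auc == 1.0

    def test_anti_informative_screener_has_zero_youden(self):
        roc = roc_curve([10, 11, 12, 1, 2, 3], [False] * 3 + [True] * 3)
        assert roc.youden_j == pytest.approx(0.0)
        assert np.isinf(roc.optimal_cutoff)

    def test_youden_matches_exhaustive_enumeration(self):
        """50 random small instances, integer scores: the reported J equals
        the brute-force maximum over every threshold."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 31))
            scores = rng.integers(0, 8, n).astype(float)
            cond = rng.random(n) < 0.45
            if cond.all() or not cond.any():
                continue
            direction = HIGHER_IS_POSITIVE if rng.random() < 0.5 else LOWER_IS_POSITIVE
            roc = roc_curve(scores, cond, direction)
            assert roc.youden_j == pytest.approx(
                brute_force_youden(scores, cond, direction), abs=1e-12
            )

    def test_optimal_cutoff_attains_youden_j(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        cond = rng.random(40) < 0.5
        roc = roc_curve(scores, cond)
        pos = scores >= roc.optimal_cutoff
        tpr = (pos & cond).sum() / cond.sum()
        fpr = (pos & ~cond).sum() / (~cond).sum()
        assert tpr - fpr == pytest.approx(roc.youden_j)

    def test_agrees_with_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(21)
        for _ in range(10):
            scores = rng.normal(size=300) + rng.integers(0, 3, 300) * 0.5  # with ties
            cond = rng.random(300) < 0.4
            roc = roc_curve(scores, cond)
            assert roc.auc == pytest.approx(roc_auc_score(cond, scores), abs=1e-9)

    def test_permutation_null_auc_is_half(self):
        """Random labels: mean AUC over replicates sits at chance level."""
        rng = np.random.default_rng(8)
        scores = rng.normal(size=2000)
        aucs = []
        for _ in range(200):
            cond = np.zeros(2000, bool)
            cond[rng.permutation(2000)[:500]] = True
            aucs.append(roc_curve(scores, cond).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("d", [0.0, 0.5, 1.0, 2.0])
    def test_binormal_auc_matches_closed_form(self, d):
        """Scores N(0,1) vs N(d,1): trapezoid AUC within 0.01 of Phi(d/sqrt 2)."""
        from scipy.stats import norm

        rng = np.random.default_rng(100 + int(10 * d))
        scores = np.concatenate([rng.normal(0, 1, 2000), rng.normal(d, 1, 2000)])
        cond = np.array([False] * 2000 + [True] * 2000)
        roc = roc_curve(scores, cond)
        assert roc.auc == pytest.approx(norm.cdf(d / np.sqrt(2)), abs=0.01)


class TestRounding:
    def test_round_half_up(self):
        assert round_half_up(0.835) == 0.84
        assert round_half_up(0.125) == 0.13
        assert round_half_up(0.9411764, 2) == 0.94

    def test_percent_arithmetic(self):
        assert percent(9, 22) == 41
        assert percent(3, 22) == 14
        assert percent(8, 22) == 36
        assert percent(10, 22) == 45
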