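import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from stacktide.evaluation import (
    auc,
    confusion,
    cross_validate_matrix,
    evaluate_predictions,
    feature_importance,
    metrics,
)

RNG = np.random.default_rng(99)


class TestConfusion:
    def test_perfect_agreement(self):
        assert confusion([1, 1, 0, 0], [1, 1, 0, 0]) == (2, 2, 0, 0)

    def test_complement_prediction(self):
        tp, tn, fp, fn = confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert (tp, tn) == (0, 0) and fp + fn == 4

    def test_against_loop_oracle(self):
        yt = RNG.integers(0, 2, size=1000)
        yp = RNG.integers(0, 2, size=1000)
        tp = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 1)
        tn = sum(1 for a, b in zip(yt, yp) if a == 0 and b == 0)
        fp = sum(1 for a, b in zip(yt, yp) if a == 0 and b == 1)
        fn = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 0)
        assert confusion(yt, yp) == (tp, tn, fp, fn)

    def test_length_mismatch_and_nonbinary(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1, 0], [1])
        with pytest.raises(ValueError, match="binary"):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_perfect_classifier(self):
        rep = metrics(50, 50, 0, 0)
        assert (rep.ACC, rep.Sn, rep.Sp, rep.MCC) == (1.0, 1.0, 1.0, 1.0)

    def test_coin_flip(self):
        rep = metrics(25, 25, 25, 25)
        assert rep.ACC == 0.5 and rep.MCC == 0.0

    def test_hand_computed_mcc(self):
        # (9*8 - 2*1) / sqrt(11*10*10*9) = 70/sqrt(9900)
        rep = metrics(9, 8, 2, 1)
        assert rep.MCC == pytest.approx(70 / math.sqrt(9900))
        assert rep.MCC == pytest.approx(0.7035, abs=1e-4)

    def test_case_study_60_of_73_positives(self):
        # all-positive evaluation set: 60 of 73 antigens correctly called
        rep = metrics(TP=60, TN=0, FP=0, FN=13, context="case_study")
        assert rep.ACC == pytest.approx(0.822, abs=5e-4)
        assert rep.Sn == pytest.approx(60 / 73)
        assert rep.MCC == 0.0  # degenerate denominator convention

    def test_zero_denominator_convention(self):
        assert metrics(10, 0, 0, 10).MCC == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            metrics(0, 0, 0, 0)

    def test_formula_oracle_bulk(self):
        counts = RNG.integers(0, 200, size=(2000, 4))
        counts = counts[counts.sum(axis=1) > 0]
        for tp, tn, fp, fn in counts:
            rep = metrics(int(tp), int(tn), int(fp), int(fn))
            n = tp + tn + fp + fn
            assert rep.ACC == pytest.approx((tp + tn) / n)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected_mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
            assert rep.MCC == pytest.approx(expected_mcc)


class TestAUC:
    def test_separated_and_uninformative(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_hand_computed_pairwise(self):
        # pairs: (0.9>0.6), (0.9>0.2), (0.4<0.6), (0.4>0.2) -> 3/4
        assert auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == pytest.approx(0.75)

    def test_single_class_returns_none(self):
        with pytest.warns(UserWarning, match="one class"):
            assert auc([1, 1, 1], [0.2, 0.5, 0.9]) is None

    def test_against_sklearn_oracle(self):
        for _ in range(50):
            y = RNG.integers(0, 2, size=80)
            if y.min() == y.max():
                continue
            s = np.round(RNG.random(80), 2)  # rounding forces ties
            assert auc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_monotone_transform_invariance(self):
        y = RNG.integers(0, 2, size=100)
        s = RNG.random(100)
        base = auc(y, s)
        assert auc(y, np.exp(5 * s)) == pytest.approx(base)
        assert auc(y, np.log(s + 1e-9)) == pytest.approx(base)


class TestLabelConventionSymmetry:
    def test_swapping_classes_swaps_sn_sp_and_keeps_mcc_magnitude(self):
        yt = RNG.integers(0, 2, size=300)
        yp = RNG.integers(0, 2, size=300)
        rep = metrics(*confusion(yt, yp))
        rep_sw = metrics(*confusion(1 - yt, 1 - yp))
        assert rep_sw.Sn == pytest.approx(rep.Sp)
        assert rep_sw.Sp == pytest.approx(rep.Sn)
        assert abs(rep_sw.MCC) == pytest.approx(abs(rep.MCC))


class TestCrossValidateMatrix:
    def test_perfect_signal(self):
        from sklearn.ensemble import ExtraTreesClassifier
        y = np.repeat([0, 1], 40)
        X = y.reshape(-1, 1).astype(float)
        rep = cross_validate_matrix(
            lambda: ExtraTreesClassifier(n_estimators=20, random_state=0),
            X, y, k=5, seed=0)
        assert rep.ACC == 1.0 and rep.MCC == 1.0

    def test_deterministic(self):
        from sklearn.ensemble import ExtraTreesClassifier
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 40)
        X = rng.normal(size=(80, 5)) + 0.5 * y[:, None]
        reps = [cross_validate_matrix(
            lambda: ExtraTreesClassifier(n_estimators=20, random_state=1),
            X, y, k=5, seed=2).to_dict() for _ in range(2)]
        assert reps[0] == reps[1]


class TestFeatureImportance:
    def _fitted_on_planted(self):
        from stacktide.ga_sar import SelectionResult
        from stacktide.stacking import fit_stack
        from stacktide.synthetic import planted_apf

        apf, y = planted_apf(200, [2], seed=6, n_cols=12)
        sel = SelectionResult(selected_columns=[f"pf{i:03d}" for i in range(12)],
                              selected_indices=list(range(12)),
                              n_estimators=100, best_fitness=1.0)
        model = fit_stack(apf, y, sel, baselines=[], seed=6)
        return model, apf, y

    def test_planted_column_ranked_first_and_dominant(self):
        model, apf, y = self._fitted_on_planted()
        ranked = feature_importance(model, apf, y)
        assert len(ranked) == 12
        top_label, top_imp, top_sign = ranked[0]
        assert top_label == "pf002"
        assert top_sign == 1
        noise_max = max(v for l, v, s in ranked[1:])
        assert top_imp >= 10 * noise_max

    def test_unfitted_model_rejected(self):
        from sklearn.ensemble import ExtraTreesClassifier

        class Dummy:
            meta = ExtraTreesClassifier()
            selection = None

        with pytest.raises(ValueError, match="not fitted"):
            feature_importance(Dummy(), np.zeros((3, 2)), [0, 1, 0])


class TestEvaluatePredictions:
    def test_threshold_and_auc(self):
        y = [1, 1, 0, 0]
        rep = evaluate_predictions(y, [0.9, 0.6, 0.4, 0.1])
        assert rep.ACC == 1.0 and rep.AUC == 1.0
        assert rep.context == "independent_test"
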