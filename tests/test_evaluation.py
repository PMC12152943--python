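"""Metrics arithmetic, band tables, CV pooling, selection, importance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicpred import (
    BandTable,
    ConfusionCounts,
    MetricsReport,
    band_table,
    class_balance,
    compute_metrics,
    confusion,
    cross_validate,
    excluded_summary,
    mean_scaled_importance,
    metrics_from_bands,
    select_best,
)
from dicpred.errors import DataError
from dicpred.evaluation import format_ratio


def make_band_table(neg, pos):
    return BandTable(
        counts=pd.DataFrame({0: list(neg), 1: list(pos)},
                            index=["low", "middle", "high"])
    )


class TestConfusion:
    def test_hand_tallies(self):
        c = confusion([1, 0], [1, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)
        c = confusion([1, 1, 0], [0, 1, 1])
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 0)

    def test_counts_sum_to_n(self, rng):
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        c = confusion(y, p)
        assert c.total == 200
        # independent tally
        assert c.TP == sum(1 for a, b in zip(y, p) if a == 1 and b == 1)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            confusion([1, 0], [1])


class TestComputeMetrics:
    def test_reproduces_published_test_row(self):
        m = compute_metrics(ConfusionCounts(TP=28, FN=4, TN=57, FP=38))
        assert m.rounded().to_dict() == {
            "accuracy": 0.67, "MCC": 0.41, "sensitivity": 0.88,
            "specificity": 0.60, "precision": 0.42, "balanced accuracy": 0.74,
        }

    def test_reproduces_published_cv_row(self):
        m = compute_metrics(ConfusionCounts(TP=105, FN=28, TN=224, FP=170))
        assert round(m.mcc, 2) == 0.31
        assert round(m.sensitivity, 2) == 0.79

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=5, FN=0, TN=7, FP=0))
        assert m.mcc == 1.0
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_matches_sklearn_mcc(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(20):
            y = rng.integers(0, 2, 50)
            p = rng.integers(0, 2, 50)
            if len(set(y)) < 2 or len(set(p)) < 2:
                continue
            m = compute_metrics(confusion(y, p))
            assert m.mcc == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = compute_metrics(ConfusionCounts(TP=0, FN=0, TN=5, FP=2))
        assert math.isnan(m.sensitivity)
        assert math.isnan(m.mcc)
        assert math.isnan(m.balanced_accuracy)
        assert not math.isnan(m.specificity)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DataError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_mcc_bounds_label_swap_and_balance_identity(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        if not math.isnan(m.mcc):
            assert -1.0 - 1e-12 <= m.mcc <= 1.0 + 1e-12
            # inverting every prediction negates the correlation
            swapped = compute_metrics(ConfusionCounts(TP=fn, FP=tn, TN=fp, FN=tp))
            assert swapped.mcc == pytest.approx(-m.mcc, abs=1e-12)
        if not math.isnan(m.balanced_accuracy):
            assert m.balanced_accuracy == pytest.approx(
                (m.sensitivity + m.specificity) / 2
            )


class TestBandTable:
    def test_band_assignment_and_boundaries(self):
        t = band_table([0.2, 0.5, 0.9], [0, 0, 1])
        assert t.class_counts(0) == (1, 1, 0)
        assert t.class_counts(1) == (0, 0, 1)
        t = band_table([0.35, 0.65], [0, 1])
        assert t.class_counts(0) == (0, 1, 0)  # boundary -> middle band
        assert t.class_counts(1) == (0, 1, 0)

    def test_per_class_sums_conserve_class_sizes(self, rng):
        p = rng.random(100)
        y = rng.integers(0, 2, 100)
        t = band_table(p, y)
        for label in (0, 1):
            assert sum(t.class_counts(label)) == int((y == label).sum())

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(DataError):
            band_table([1.2], [1])


class TestMetricsFromBands:
    def test_published_band_counts_give_published_filtered_metrics(self):
        test_bands = make_band_table(neg=(57, 43, 38), pos=(4, 10, 28))
        m = metrics_from_bands(test_bands)
        assert round(m.mcc, 2) == 0.41
        assert round(m.sensitivity, 2) == 0.88

        train_bands = make_band_table(neg=(224, 156, 170), pos=(28, 36, 105))
        m = metrics_from_bands(train_bands)
        assert round(m.sensitivity, 2) == 0.79
        assert round(m.specificity, 2) == 0.57

    def test_empty_middle_band_equals_unfiltered(self, rng):
        p = np.concatenate([rng.uniform(0, 0.34, 40), rng.uniform(0.66, 1, 40)])
        y = rng.integers(0, 2, 80)
        t = band_table(p, y)
        filtered = metrics_from_bands(t)
        direct = compute_metrics(confusion(y, (p > 0.65).astype(int)))
        assert filtered == direct

    def test_pipeline_consistency_with_direct_confusion(self, rng):
        # filtered metrics from the band table equal metrics computed
        # directly on the retained subset, for arbitrary inputs
        for _ in range(10):
            p = rng.random(60)
            y = rng.integers(0, 2, 60)
            t = band_table(p, y)
            keep = (p < 0.35) | (p > 0.65)
            if keep.sum() == 0 or len(set(y[keep])) == 0:
                continue
            direct = compute_metrics(
                confusion(y[keep], (p[keep] > 0.65).astype(int))
            )
            via_bands = metrics_from_bands(t)
            for a, b in zip(via_bands.as_series(), direct.as_series()):
                assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


class TestExcludedSummary:
    def test_published_exclusion_counts(self):
        count, neg, pos, ratio = excluded_summary(
            make_band_table(neg=(57, 43, 38), pos=(4, 10, 28))
        )
        assert (count, neg, pos) == (53, 43, 10)
        assert round(ratio, 2) == 4.30
        count, _, _, ratio = excluded_summary(
            make_band_table(neg=(224, 156, 170), pos=(28, 36, 105))
        )
        assert count == 192
        assert round(ratio, 2) == 4.33

    def test_empty_middle_band(self):
        count, neg, pos, ratio = excluded_summary(
            make_band_table(neg=(5, 0, 5), pos=(2, 0, 2))
        )
        assert (count, neg, pos) == (0, 0, 0)
        assert math.isnan(ratio)
        assert format_ratio(ratio) == "undefined"


class TestCrossValidate:
    def test_pooled_prediction_count_and_band_totals(self, small_signal_dataset):
        from dicpred import UndersampledConsensus

        model = UndersampledConsensus(
            small_signal_dataset, algorithm="random_forest",
            hyperparameters=(("n_estimators", 30),),
        )
        cv = model.cross_validate(k=5, seed=0)
        assert len(cv.predictions) == small_signal_dataset.n
        assert sum(cv.band.class_counts(0)) == small_signal_dataset.n_negative
        assert sum(cv.band.class_counts(1)) == small_signal_dataset.n_positive
        assert len(cv.per_fold) == 5

    def test_class_smaller_than_k_rejected(self, small_signal_dataset):
        from dicpred import UndersampledConsensus

        model = UndersampledConsensus(small_signal_dataset)
        with pytest.raises(DataError):
            model.cross_validate(k=51, seed=0)


class TestSelectBest:
    def _report(self, bal, sens=0.5, mcc=0.2):
        return MetricsReport(
            accuracy=0.5, mcc=mcc, sensitivity=sens,
            specificity=2 * bal - sens, precision=0.3, balanced_accuracy=bal,
        )

    def test_balanced_accuracy_argmax(self):
        # mirrors the published baseline comparison: the combined
        # substructure+pathway+transporter fingerprint wins at 0.67
        results = [
            ("PubChem", self._report(0.64, sens=0.76)),
            ("Target", self._report(0.65, sens=0.75)),
            ("PubChem+Pathway+Transporter", self._report(0.67, sens=0.79)),
            ("Target+Pathway", self._report(0.63, sens=0.75)),
        ]
        assert select_best(results) == "PubChem+Pathway+Transporter"

    def test_single_candidate(self):
        assert select_best([("only", self._report(0.5))]) == "only"

    def test_three_decimal_tie_broken_by_sensitivity_then_mcc_then_name(self):
        a = ("a", self._report(0.6704, sens=0.70, mcc=0.2))
        b = ("b", self._report(0.6699, sens=0.80, mcc=0.2))  # same at 3 dp? no
        # 0.6704 -> 0.670, 0.6699 -> 0.670: tie at three decimals
        assert select_best([a, b]) == "b"
        c = ("c", self._report(0.670, sens=0.80, mcc=0.5))
        assert select_best([a, b, c]) == "c"
        d = ("a_first", self._report(0.670, sens=0.80, mcc=0.5))
        assert select_best([c, d]) == "a_first"

    def test_permutation_invariant(self):
        results = [
            ("m1", self._report(0.61, sens=0.7)),
            ("m2", self._report(0.67, sens=0.8)),
            ("m3", self._report(0.64, sens=0.9)),
        ]
        winner = select_best(results)
        assert select_best(results[::-1]) == winner
        assert select_best([results[1], results[0], results[2]]) == winner


class _StubEnsemble:
    def __init__(self, scores, feature_ids):
        class Sub:
            def __init__(self, s):
                self.feature_importances_ = np.array(s, dtype=float)

        self.submodels = [Sub(s) for s in scores]
        self.feature_ids = feature_ids


class TestMeanScaledImportance:
    def test_proportional_scores(self):
        e = _StubEnsemble(
            [[2, 1], [4, 2], [2, 1], [4, 2]], ["f_a", "f_b"]
        )
        ranking = mean_scaled_importance(e)
        assert list(ranking.table["feature_id"]) == ["f_a", "f_b"]
        assert list(ranking.table["mean_scaled_influence"]) == [1.0, 0.5]

    def test_all_zero_submodel_contributes_zeros_with_warning(self):
        e = _StubEnsemble([[2, 1], [0, 0], [2, 1], [4, 2]], ["f_a", "f_b"])
        with pytest.warns(UserWarning):
            ranking = mean_scaled_importance(e)
        assert ranking.table["mean_scaled_influence"].iloc[0] == pytest.approx(0.75)

    def test_influences_in_unit_interval_and_sorted(self, rng):
        scores = rng.random((4, 20))
        e = _StubEnsemble(scores, [f"f{i}" for i in range(20)])
        ranking = mean_scaled_importance(e)
        vals = ranking.table["mean_scaled_influence"].to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()
        assert (np.diff(vals) <= 1e-12).all()

    def test_single_informative_feature_ranks_first_across_seeds(self):
        from dicpred import (
            GeneratorSpec, LearnerSpec, fit_subset_ensemble,
            make_binary_dataset, undersample_subsets,
        )

        wins = 0
        for seed in range(5):
            spec = GeneratorSpec(
                n_pos=60, n_neg=180,
                blocks=(("substructure", 20, 0.2),),
                informative=(("substructure", 0.9, 0.1, 1),),
                seed=seed,
            )
            d = make_binary_dataset(spec)
            subsets = undersample_subsets(d, seed=seed)
            e = fit_subset_ensemble(
                subsets,
                LearnerSpec("random_forest", (("n_estimators", 50),), seed=seed),
            )
            ranking = mean_scaled_importance(e)
            if ranking.top(1) == [spec.informative_feature_ids()[0]]:
                wins += 1
        assert wins >= 4


class TestClassBalance:
    @pytest.mark.parametrize(
        "neg, pos, expected",
        [(688, 211, 3.26), (1342, 313, 4.29), (958, 256, 3.74),
         (696, 210, 3.31), (10, 10, 1.00)],
    )
    def test_published_ratios(self, neg, pos, expected):
        labels = [0] * neg + [1] * pos
        assert round(class_balance(labels), 2) == expected
        assert format_ratio(class_balance(labels)) == f"{expected:.2f}:1"

    def test_zero_positives_undefined(self):
        assert math.isnan(class_balance([0, 0, 0]))
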