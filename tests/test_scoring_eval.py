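import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from octmel import (
    evaluate,
    longitudinal_curves,
    make_split,
    pool_reports,
    volume_score,
    volume_scores,
)
from oracles import mann_whitney_auc


def _index(n_induced=5, n_control=5, n_images=10):
    rows = []
    for i in range(n_induced):
        for j in range(n_images):
            rows.append({"subject_id": f"I{i}", "group": "induced", "img": j})
    for i in range(n_control):
        for j in range(n_images):
            rows.append({"subject_id": f"C{i}", "group": "control", "img": j})
    return pd.DataFrame(rows)


class TestSplit:
    def test_stratified_fold_sizes(self):
        plan = make_split(_index(), n_folds=5, seed=0)
        for fold in range(5):
            groups = [s[0] for s in plan.test_subjects(fold)]
            assert sorted(groups) == ["C", "I"]

    def test_invariants_over_many_seeds(self):
        """Subject exclusivity, partition, and the 9:1 image ratio."""
        index = _index()
        subjects = set(index["subject_id"])
        for seed in range(100):
            plan = make_split(index, n_folds=5, val_fraction=0.1, seed=seed)
            assigned = set(plan.subject_fold)
            assert assigned == subjects
            for fold in range(5):
                test_subj = set(plan.test_subjects(fold))
                tr, va = plan.fold_rows[fold]
                tr_subj = set(index.iloc[tr]["subject_id"])
                va_subj = set(index.iloc[va]["subject_id"])
                assert not (tr_subj | va_subj) & test_subj
                assert len(np.intersect1d(tr, va)) == 0
                n_rest = len(tr) + len(va)
                assert abs(len(va) - 0.1 * n_rest) <= 1
                assert n_rest == (index["subject_id"]
                                  .map(plan.subject_fold) != fold).sum()

    def test_deterministic_under_seed(self):
        a = make_split(_index(), seed=42)
        b = make_split(_index(), seed=42)
        assert a.subject_fold == b.subject_fold
        for f in range(5):
            np.testing.assert_array_equal(a.fold_rows[f][0], b.fold_rows[f][0])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_split(_index(n_induced=3), n_folds=5)


class TestVolumeScore:
    def _preds(self, scores, subject="S", week=1):
        return pd.DataFrame({"subject_id": subject, "week": week,
                             "slice": range(len(scores)), "score": scores})

    def test_mean_of_extremes(self):
        assert volume_score(self._preds([0.0, 1.0])).score == pytest.approx(0.5)

    def test_constant_scores(self):
        vs = volume_score(self._preds([0.9] * 7))
        assert vs.score == pytest.approx(0.9)
        assert vs.n_slices == 7

    def test_perfect_classifier_recovers_malignant_fraction(self):
        """Mean of indicator slice scores equals the lesion fraction."""
        rng = np.random.default_rng(0)
        flags = rng.random(400) < 0.37
        vs = volume_score(self._preds(flags.astype(float)))
        assert vs.score == pytest.approx(flags.mean())

    def test_mixed_volumes_rejected(self):
        bad = pd.concat([self._preds([0.1], week=1), self._preds([0.2], week=2)])
        with pytest.raises(ValueError):
            volume_score(bad)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            volume_score(self._preds([]))


class TestCurves:
    def test_single_subject_curve_equals_scores(self):
        preds = pd.DataFrame({
            "subject_id": "A", "group": "induced",
            "week": np.repeat([0, 1, 2], 4),
            "slice": np.tile(range(4), 3),
            "score": np.repeat([0.1, 0.5, 0.9], 4),
        })
        curves = longitudinal_curves(volume_scores(preds))
        assert curves["mean"].tolist() == pytest.approx([0.1, 0.5, 0.9])
        assert np.all(curves["sd"] == 0.0)

    def test_groups_kept_separate(self):
        preds = pd.DataFrame({
            "subject_id": ["A"] * 2 + ["B"] * 2,
            "group": ["induced"] * 2 + ["control"] * 2,
            "week": [0, 0, 0, 0],
            "slice": [0, 1, 0, 1],
            "score": [0.8, 0.8, 0.1, 0.1],
        })
        curves = longitudinal_curves(volume_scores(preds))
        by_group = curves.set_index("group")["mean"]
        assert by_group["induced"] == pytest.approx(0.8)
        assert by_group["control"] == pytest.approx(0.1)


class TestEvaluate:
    def test_perfect_classifier(self):
        rep = evaluate(np.array([1.0, 1.0, 0.0, 0.0]), np.array([1, 1, 0, 0]))
        assert rep.auc == pytest.approx(1.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.accuracy == 1.0

    def test_confusion_matrix_identities(self):
        rng = np.random.default_rng(1)
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        rep = evaluate(scores, labels)
        assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / 500)
        assert rep.tp + rep.fp + rep.tn + rep.fn == 500

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(2)
        rep = evaluate(rng.random(10_000), rng.integers(0, 2, 10_000))
        assert rep.auc == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        rep = evaluate(scores, labels)
        assert rep.auc == pytest.approx(mann_whitney_auc(scores, labels),
                                        abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 5.0))
    def test_auc_invariant_under_monotone_transform(self, seed, power):
        rng = np.random.default_rng(seed)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        a = evaluate(scores, labels).auc
        b = evaluate(scores ** power, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_one_class_auc_undefined_but_matrix_returned(self):
        rep = evaluate(np.array([0.2, 0.8]), np.array([1, 1]))
        assert rep.one_class and rep.auc is None
        assert rep.tp == 1 and rep.fn == 1

    def test_roc_monotone(self):
        rng = np.random.default_rng(3)
        rep = evaluate(rng.random(200), rng.integers(0, 2, 200))
        assert np.all(np.diff(rep.roc_fpr) >= 0)
        assert np.all(np.diff(rep.roc_tpr) >= 0)


def test_pooled_matrix_is_sum_of_folds():
    rng = np.random.default_rng(4)
    reports = []
    for _ in range(5):
        reports.append(evaluate(rng.random(100), rng.integers(0, 2, 100)))
    pooled = pool_reports(reports)["pooled"]
    assert pooled["tp"] == sum(r.tp for r in reports)
    assert pooled["fn"] == sum(r.fn for r in reports)
    total = pooled["tp"] + pooled["fp"] + pooled["tn"] + pooled["fn"]
    assert total == 500
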