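import numpy as np
import pandas as pd
import pytest

from il2kit import descriptors, models
from il2kit.descriptors import FeatureMatrix
from il2kit.io import PeptideDataset, PeptideRecord

from oracles import explicit_metrics, pairwise_auc


def _matrix(X, names=None, ids=None):
    n, p = X.shape
    names = names or [f"f{j}" for j in range(p)]
    ids = ids or [f"r{i}" for i in range(n)]
    return FeatureMatrix("AAC", pd.DataFrame(X, index=ids, columns=names))


class TestConfusion:
    def test_basic(self):
        c = models.confusion([0.9, 0.1], [1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_tie_at_threshold_is_positive_call(self):
        c = models.confusion([0.5], [0])
        assert c.fp == 1

    def test_all_positive_calls(self):
        c = models.confusion([0.9] * 6, [1, 1, 1, 0, 0, 0])
        assert c.fp == 3 and c.tp == 3

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            models.confusion([], [])


class TestMetrics:
    def test_similarity_table_row(self):
        # e-value 1e-3 confusion: 2100 correct pos, 121 incorrect pos,
        # 402 correct neg, 151 incorrect neg
        c = models.ConfusionCounts(tp=2100, fp=121, tn=402, fn=151)
        rep = models.metrics(c)
        sens, spec, acc, mcc = explicit_metrics(2100, 121, 402, 151)
        assert rep.sensitivity == pytest.approx(sens, abs=1e-12)
        assert rep.specificity == pytest.approx(spec, abs=1e-12)
        assert rep.accuracy == pytest.approx(acc, abs=1e-12)
        assert rep.mcc == pytest.approx(mcc, abs=1e-12)
        assert rep.sensitivity == pytest.approx(2100 / 2251)
        assert rep.specificity == pytest.approx(402 / 523)
        assert c.total == 2774

    def test_perfect_predictions(self):
        scores, labels = [0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]
        rep = models.metrics(models.confusion(scores, labels), scores, labels)
        assert rep.mcc == 1.0 and rep.auc == 1.0 and rep.accuracy == 100.0

    def test_symmetric_confusion_zero_mcc(self):
        c = models.ConfusionCounts(tp=5, fn=5, tn=3, fp=3)
        assert models.mcc(c) == 0.0

    def test_degenerate_denominator_returns_zero(self):
        assert models.mcc(models.ConfusionCounts(tp=0, fp=0, tn=5, fn=5)) == 0.0

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # coarse grid of score values forces plenty of ties
            scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.75, 0.9], size=n)
            c = models.confusion(scores, labels)
            rep = models.metrics(c, scores, labels)
            sens, spec, acc, mcc = explicit_metrics(c.tp, c.fp, c.tn, c.fn)
            assert rep.sensitivity == pytest.approx(sens, abs=1e-12)
            assert rep.specificity == pytest.approx(spec, abs=1e-12)
            assert rep.accuracy == pytest.approx(acc, abs=1e-12)
            assert rep.mcc == pytest.approx(mcc, abs=1e-12)
            assert rep.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        labels[0], labels[1] = 0, 1
        a = models.roc_auc(scores, labels)
        b = models.roc_auc(np.exp(5 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestTrain:
    def test_learns_separable_signal(self, et_predictor, dpc_len_features, synth_split):
        _, test_fm = dpc_len_features
        rep = models.evaluate(et_predictor, test_fm, synth_split.test.labels())
        assert rep.auc >= 0.90

    def test_determinism_same_seed(self, dpc_len_features, synth_split, quick_et_spec):
        train_fm, test_fm = dpc_len_features
        y = synth_split.train.labels()
        a = models.train(train_fm, y, quick_et_spec)
        b = models.train(train_fm, y, quick_et_spec)
        assert a.best_params == b.best_params
        assert np.array_equal(a.predict_proba(test_fm), b.predict_proba(test_fm))

    def test_row_order_invariance(self, quick_et_spec):
        rng = np.random.default_rng(0)
        X = rng.random((60, 8))
        y = (X[:, 0] > 0.5).astype(int)
        fm = _matrix(X)
        perm = rng.permutation(60)
        fm_perm = FeatureMatrix("AAC", fm.frame.iloc[perm])
        a = models.train(fm, y, quick_et_spec)
        b = models.train(fm_perm, y[perm], quick_et_spec)
        assert a.best_params == b.best_params
        probe = _matrix(rng.random((10, 8)))
        assert np.allclose(a.predict_proba(probe.frame), b.predict_proba(probe.frame))

    def test_single_class_errors(self, quick_et_spec):
        fm = _matrix(np.random.default_rng(1).random((10, 3)))
        with pytest.raises(ValueError, match="both classes"):
            models.train(fm, np.ones(10, dtype=int), quick_et_spec)

    def test_nonfinite_features_error(self, quick_et_spec):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="non-finite"):
            models.train(_matrix(X), y, quick_et_spec)

    @pytest.mark.parametrize("algorithm", ["DT", "KNN", "LASSO", "SVR", "XGB"])
    def test_other_algorithms_fit_and_predict(self, algorithm):
        rng = np.random.default_rng(5)
        X = rng.random((50, 6))
        y = (X[:, 0] + 0.1 * rng.random(50) > 0.55).astype(int)
        spec = models.ModelSpec(algorithm, cv_folds=3, seed=2)
        spec.grid = {k: v[:1] for k, v in spec.grid.items()}
        pred = models.train(_matrix(X), y, spec)
        probs = pred.predict_proba(_matrix(X).frame)
        assert probs.shape == (50,) and np.all((0 <= probs) & (probs <= 1))


@pytest.fixture(scope="module")
def labeled_matrix():
    rng = np.random.default_rng(9)
    X = rng.random((120, 12))
    y = rng.integers(0, 2, size=120)
    X[:, 4] = y  # a column identical to the label
    return _matrix(X), y


class TestFeatureSelection:

    @pytest.mark.parametrize("method", ["mRMR", "L1", "RFE", "importance"])
    def test_exactly_k_distinct_subset(self, labeled_matrix, method):
        fm, y = labeled_matrix
        names = models.select_features(fm, y, method, 5, seed=0)
        assert len(names) == 5 == len(set(names))
        assert set(names) <= set(fm.column_names)

    @pytest.mark.parametrize("method", ["mRMR", "L1", "RFE", "importance"])
    def test_label_column_always_selected_first_rank(self, labeled_matrix, method):
        fm, y = labeled_matrix
        names = models.select_features(fm, y, method, 3, seed=0)
        assert "f4" in names
        if method in ("mRMR", "L1", "importance"):
            assert names[0] == "f4"

    def test_mrmr_first_pick_is_max_mutual_information(self, labeled_matrix):
        from sklearn.metrics import mutual_info_score

        fm, y = labeled_matrix
        Xd = models._discretize(fm.frame.to_numpy())
        mis = [mutual_info_score(Xd[:, j], y) for j in range(Xd.shape[1])]
        expected = fm.column_names[int(np.argmax(mis))]
        assert models.select_features(fm, y, "mRMR", 1)[0] == expected

    def test_k_too_large_errors(self, labeled_matrix):
        fm, y = labeled_matrix
        with pytest.raises(ValueError, match="exceeds"):
            models.select_features(fm, y, "importance", 13)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, quick_et_spec):
        rng = np.random.default_rng(4)
        X = rng.random((40, 5))
        y = (X[:, 1] > 0.5).astype(int)
        fm = _matrix(X)
        pred = models.train(fm, y, quick_et_spec)
        path = tmp_path / "model.joblib"
        models.save_model(pred, path)
        back = models.load_model(path)
        assert back.feature_names == pred.feature_names
        assert np.array_equal(back.predict_proba(fm.frame), pred.predict_proba(fm.frame))


class TestSimilarityAnnotate:
    def test_identical_sequence_annotated_and_self_hits_dropped(self):
        db = PeptideDataset(
            [
                PeptideRecord("dbp1", "ALEGSLQKWFY", "positive"),
                PeptideRecord("dbn1", "CCDDTTCCDDT", "negative"),
                PeptideRecord("dbn2", "WDTDTDTDTDW", "negative"),
            ]
        )
        query = PeptideDataset(
            [
                PeptideRecord("q1", "ALEGSLQKWFY", "positive"),  # exact positive
                PeptideRecord("q2", "CCDDTTCCDDT", "negative"),  # exact negative
            ]
        )
        res = models.similarity_annotate(query, db, evalue=1e-2)
        assigned = dict(zip(res.assignments["id"], res.assignments["hit_label"]))
        assert assigned["q1"] == "positive"
        assert assigned["q2"] == "negative"
        assert res.correct_positive == 1 and res.correct_negative == 1
        assert res.total_hits == 2

    def test_stringent_evalue_gives_no_hit(self):
        db = PeptideDataset([PeptideRecord("d1", "WWWWWWWWHHHH", "positive")])
        query = PeptideDataset([PeptideRecord("q1", "ACDEFGKLMNPQ", "positive")])
        res = models.similarity_annotate(query, db, evalue=1e-30)
        assert res.no_hit == 1 and res.total_hits == 0

    def test_tabulate_hits_bookkeeping(self):
        query = PeptideDataset(
            [
                PeptideRecord("a", "ACDEFGHI", "positive"),
                PeptideRecord("b", "ACDEFGHK", "positive"),
                PeptideRecord("c", "ACDEFGHL", "negative"),
                PeptideRecord("d", "ACDEFGHM", "negative"),
                PeptideRecord("e", "ACDEFGHN", "positive"),
            ]
        )
        assignments = pd.DataFrame(
            [
                {"id": "a", "hit_id": "x", "hit_label": "positive"},  # correct pos
                {"id": "b", "hit_id": "x", "hit_label": "negative"},  # incorrect neg
                {"id": "c", "hit_id": "x", "hit_label": "negative"},  # correct neg
                {"id": "d", "hit_id": "x", "hit_label": "positive"},  # incorrect pos
                {"id": "e", "hit_id": None, "hit_label": None},       # no hit
            ]
        )
        res = models.tabulate_hits(assignments, query)
        assert (
            res.correct_positive,
            res.incorrect_positive,
            res.correct_negative,
            res.incorrect_negative,
            res.no_hit,
        ) == (1, 1, 1, 1, 1)
        assert res.total_hits == 4
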