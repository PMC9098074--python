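"""Grid enumeration, confusion metrics, cross-validation and final fits."""

import numpy as np
import pytest

from refwait.cohort import LabeledNote, ReferralNote
from refwait.features import COUNT, build_vocabulary
from refwait.grid import (
    CVMetrics,
    FittedClassifier,
    GridSpec,
    PipelineConfig,
    confusion_metrics,
    cross_validate,
    enumerate_configs,
    predict_proba,
    run_grid,
    train_final,
)

CFG = PipelineConfig(index=0, stem=False, vectorizer=COUNT, penalty="l2",
                     C=1.0, class_weight=None)


class TestEnumerateConfigs:
    def test_default_grid_has_eighty_cells(self):
        grid = GridSpec()
        configs = enumerate_configs(grid)
        expected = (len(grid.stemming) * len(grid.vectorizers) * len(grid.penalties)
                    * len(grid.regularization) * len(grid.class_weights))
        assert len(configs) == expected == 80

    def test_degenerate_grid(self):
        grid = GridSpec(stemming=(False,), vectorizers=(COUNT,), penalties=("l2",),
                        regularization=(1.0,), class_weights=(None,))
        assert len(enumerate_configs(grid)) == 1

    def test_indices_are_enumeration_order(self):
        configs = enumerate_configs(GridSpec())
        assert [c.index for c in configs] == list(range(80))
        assert len({(c.stem, c.vectorizer, c.penalty, c.C, c.class_weight)
                    for c in configs}) == 80

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(penalties=())


class TestConfusionMetrics:
    def test_hand_computed_cell(self):
        # TP=3, FP=1, FN=7, TN=89
        labels = [1] * 10 + [0] * 90
        probs = [0.9] * 3 + [0.1] * 7 + [0.9] * 1 + [0.1] * 89
        m = confusion_metrics(labels, probs, 0.5)
        assert m.precision == 0.75
        assert m.recall == pytest.approx(0.30)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.3 / 1.05)
        assert m.specificity == pytest.approx(89 / 90)
        assert m.npv == pytest.approx(89 / 96)

    def test_perfect_classifier(self):
        m = confusion_metrics([1, 0, 1], [1.0, 0.0, 1.0], 0.5)
        assert (m.precision, m.recall, m.f1, m.brier) == (1.0, 1.0, 1.0, 0.0)
        assert not m.undefined

    def test_no_predicted_positives_flagged(self):
        m = confusion_metrics([1, 0], [0.1, 0.1], 0.5)
        assert m.precision == 0.0 and "precision" in m.undefined
        assert m.specificity == 1.0

    def test_threshold_is_inclusive(self):
        m = confusion_metrics([1], [0.5], 0.5)
        assert m.recall == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [0.5])

    def test_brier_in_unit_interval(self):
        rng = np.random.default_rng(0)
        m = confusion_metrics(rng.integers(0, 2, 50), rng.random(50))
        assert 0.0 <= m.brier <= 1.0


@pytest.fixture(scope="module")
def cv_single(clean_labeled):
    return cross_validate(clean_labeled, "cardiology", CFG, k=5, seed=4)


class TestCrossValidate:
    def test_too_few_positives_skipped(self, clean_labeled):
        rare = [ln for ln in clean_labeled if ln.gold_specialty != "cardiology"]
        rare += [ln for ln in clean_labeled if ln.gold_specialty == "cardiology"][:4]
        out = cross_validate(rare, "cardiology", CFG, k=5, seed=0)
        assert out.skipped and not out.fold_metrics

    def test_deterministic_given_seed(self, clean_labeled, cv_single):
        again = cross_validate(clean_labeled, "cardiology", CFG, k=5, seed=4)
        assert again.fold_metrics == cv_single.fold_metrics

    def test_f1_identity_per_fold(self, cv_single):
        for m in cv_single.fold_metrics:
            if m.precision + m.recall > 0:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall))

    def test_separable_data_scores_high(self, cv_single):
        assert cv_single.mean("f1") >= 0.9

    def test_mean_within_fold_range(self, cv_single):
        vals = [m.precision for m in cv_single.fold_metrics]
        assert min(vals) <= cv_single.mean("precision") <= max(vals)

    def test_k_validated(self, clean_labeled):
        with pytest.raises(ValueError):
            cross_validate(clean_labeled, "cardiology", CFG, k=1)

    def test_matches_grid_runner(self, clean_labeled, cv_single):
        grid = GridSpec(stemming=(False,), vectorizers=(COUNT,), penalties=("l2",),
                        regularization=(1.0,), class_weights=(None,))
        via_grid = run_grid(clean_labeled, ["cardiology"], grid, k=5, seed=4)
        assert via_grid["cardiology"][0].fold_metrics == cv_single.fold_metrics


class TestFoldPartition:
    def test_every_note_held_out_once(self, clean_labeled):
        from refwait.grid import _FoldCache

        cache = _FoldCache(clean_labeled, k=5, seed=0, min_count=5, stems=[False])
        held_out = np.concatenate([te for _, te in cache.splits])
        assert sorted(held_out.tolist()) == list(range(len(clean_labeled)))


class TestTrainFinal:
    def test_separable_training_f1(self, clean_labeled):
        clf = train_final(clean_labeled, "cardiology", CFG)
        y = np.array([ln.gold_specialty == "cardiology" for ln in clean_labeled], int)
        probs = np.array([predict_proba(clf, ln.note.text) for ln in clean_labeled[:200]])
        m = confusion_metrics(y[:200], probs, 0.5)
        assert m.f1 >= 0.99

    def test_balanced_weight_ratio(self):
        # w_c = n_total/(2 n_c): on a 90:10 corpus the minority weight is
        # n_maj/n_min = 9x the majority weight
        from sklearn.utils.class_weight import compute_class_weight

        y = np.array([0] * 90 + [1] * 10)
        w = compute_class_weight("balanced", classes=np.array([0, 1]), y=y)
        assert w[1] / w[0] == pytest.approx(9.0)
        assert w[1] == pytest.approx(100 / (2 * 10))

    def test_single_class_rejected(self, clean_labeled):
        positives = [ln for ln in clean_labeled if ln.gold_specialty == "cardiology"]
        with pytest.raises(ValueError):
            train_final(positives, "cardiology", CFG)

    def test_refit_on_training_fold_reproduces_cv_fold(self, clean_labeled):
        from refwait.grid import _FoldCache, confusion_metrics as cm

        cache = _FoldCache(clean_labeled, k=5, seed=4, min_count=5, stems=[False])
        tr, te = cache.splits[0]
        sub = [clean_labeled[i] for i in tr]
        clf = train_final(sub, "cardiology", CFG)
        y_te = np.array([clean_labeled[i].gold_specialty == "cardiology" for i in te], int)
        probs = np.array([predict_proba(clf, clean_labeled[i].note.text) for i in te])
        refit_metrics = cm(y_te, probs, 0.5)
        cv = cross_validate(clean_labeled, "cardiology", CFG, k=5, seed=4)
        expected = cv.fold_metrics[0]
        for name in ("precision", "recall", "f1", "specificity", "npv", "brier"):
            assert getattr(refit_metrics, name) == pytest.approx(
                getattr(expected, name), abs=1e-12)


class TestLassoSparsity:
    def test_stronger_penalty_never_adds_weights(self):
        # checked on a noisy (non-separable) corpus, where the penalty is
        # active; on perfectly separable data the lasso path can reorder
        from refwait.cohort import derive_gold_pairs, filter_short_notes
        from refwait.synthetic import SyntheticConfig, generate_cohort

        cfg = SyntheticConfig(notes_per_specialty=150, multi_event_rate=0.0,
                              keyword_rate=0.3, seed=2)
        notes, claims, _ = generate_cohort(cfg)
        labeled = derive_gold_pairs(filter_short_notes(notes), claims, 2015)
        nnz = []
        for C in (0.001, 0.01, 0.1, 1.0, 10.0):
            clf = train_final(labeled, "cardiology",
                              PipelineConfig(0, False, COUNT, "l1", C, None))
            nnz.append(int(np.sum(clf.weights != 0)))
        assert nnz == sorted(nnz)  # weaker penalty (larger C) keeps more weights


class TestPredictProba:
    def make_clf(self, weights, intercept):
        vocab = build_vocabulary([["angina", "stent", "rash"]] * 5, min_count=1)
        w = np.zeros(len(vocab))
        for tok, val in weights.items():
            w[vocab.index[tok]] = val
        return FittedClassifier(CFG, vocab, w, intercept, "cardiology")

    def test_zero_features_give_logistic_intercept(self):
        clf = self.make_clf({}, intercept=-1.3)
        assert predict_proba(clf, "totally out of vocabulary words") == pytest.approx(
            1 / (1 + np.exp(1.3)))

    def test_probability_in_open_interval(self, clean_labeled):
        clf = train_final(clean_labeled, "cardiology", CFG)
        for ln in clean_labeled[:50]:
            assert 0.0 < predict_proba(clf, ln.note.text) < 1.0

    def test_duplicated_text_moves_log_odds_away_from_zero(self):
        clf = self.make_clf({"angina": 0.7, "rash": -0.4}, intercept=0.0)
        for text in ("angina angina stent", "rash rash rash"):
            p1 = predict_proba(clf, text)
            p2 = predict_proba(clf, " ".join([text] * 2))
            z1 = np.log(p1 / (1 - p1))
            z2 = np.log(p2 / (1 - p2))
            assert z2 == pytest.approx(2 * z1)
            assert abs(z2) >= abs(z1)
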