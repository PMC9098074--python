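"""One-vs-rest logistic-regression grid with 5-fold cross-validation.

The hyperparameter grid crosses preprocessing (stem / no stem),
vectorization (count / tf-idf), penalty (ridge L2 / lasso L1), five
regularization values and two class weightings — 2*2*2*5*2 = 80 pipeline
configurations per target specialty. Each configuration is scored by
stratified 5-fold cross-validation of a binary (that specialty vs rest)
logistic regression; the vocabulary is rebuilt on each training fold so no
held-out text leaks into feature selection.

Regularization values are inverse penalty strengths (scikit-learn's ``C``:
larger = weaker penalty). Folds are stratified on the full multiclass gold
label, which preserves every specialty's positive rate in every fold and
lets all one-vs-rest tasks share one split.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import LabeledNote, canonical_specialty
from .features import COUNT, TFIDF, Vocabulary, build_vocabulary, design_matrix, normalize

DEFAULT_MIN_COUNT = 5
_SOLVER_TOL = 1e-6
_SOLVER_MAX_ITER = 5000

METRIC_NAMES = ("precision", "recall", "f1", "specificity", "npv", "brier")


@dataclass(frozen=True)
class GridSpec:
    """Axes of the hyperparameter grid (defaults give 80 configurations)."""

    stemming: tuple[bool, ...] = (False, True)
    vectorizers: tuple[str, ...] = (COUNT, TFIDF)
    penalties: tuple[str, ...] = ("l2", "l1")  # ridge, lasso
    regularization: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0)
    class_weights: tuple[str | None, ...] = (None, "balanced")

    def __post_init__(self) -> None:
        for name in ("stemming", "vectorizers", "penalties", "regularization", "class_weights"):
            if not getattr(self, name):
                raise ValueError(f"grid axis {name!r} is empty")


@dataclass(frozen=True)
class PipelineConfig:
    """One cell of the grid; ``index`` is its enumeration position."""

    index: int
    stem: bool
    vectorizer: str
    penalty: str
    C: float
    class_weight: str | None


def enumerate_configs(grid: GridSpec = GridSpec()) -> list[PipelineConfig]:
    """Cartesian product of the grid axes in deterministic order."""
    return [
        PipelineConfig(i, s, v, p, c, w)
        for i, (s, v, p, c, w) in enumerate(
            itertools.product(grid.stemming, grid.vectorizers, grid.penalties,
                              grid.regularization, grid.class_weights)
        )
    ]


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float
    specificity: float
    npv: float
    brier: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def confusion_metrics(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> MetricSet:
    """Threshold probabilities and compute the confusion-matrix metric set.

    A prediction is positive iff probability >= threshold. Metrics with a
    zero denominator are reported as 0.0 with their name in ``undefined``
    (matching the convention of printing 0.00 for degenerate cells).
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    npv = ratio(tn, tn + fn, "npv")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.add("f1")
        f1 = 0.0
    brier = float(np.mean((p - y) ** 2)) if len(y) else 0.0
    return MetricSet(precision, recall, f1, specificity, npv, brier, frozenset(undefined))


@dataclass
class CVMetrics:
    specialty: str
    config: PipelineConfig
    fold_metrics: list[MetricSet] = field(default_factory=list)
    skipped: bool = False

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.fold_metrics]))

    def std(self, metric: str) -> float:
        return float(np.std([getattr(m, metric) for m in self.fold_metrics]))

    def means(self) -> dict[str, float]:
        return {m: self.mean(m) for m in METRIC_NAMES}


@dataclass
class FittedClassifier:
    """A final one-vs-rest model: stored preprocessing + linear weights."""

    config: PipelineConfig
    vocabulary: Vocabulary
    weights: np.ndarray
    intercept: float
    specialty: str

    def decision(self, X: sp.csr_matrix) -> np.ndarray:
        return X @ self.weights + self.intercept


def _tokenized(labeled: Sequence[LabeledNote], stem: bool) -> list[list[str]]:
    return [normalize(ln.note.text, stem=stem) for ln in labeled]


def _gold_array(labeled: Sequence[LabeledNote]) -> np.ndarray:
    return np.array([canonical_specialty(ln.gold_specialty) for ln in labeled])


def _splits(gold: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    if k < 2:
        raise ValueError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(gold)), gold)]


def _fit_lr(config: PipelineConfig, X: sp.csr_matrix, y: np.ndarray, seed: int) -> LogisticRegression:
    clf = LogisticRegression(
        l1_ratio=1.0 if config.penalty == "l1" else 0.0,
        C=config.C,
        class_weight=config.class_weight,
        solver="liblinear",
        tol=_SOLVER_TOL,
        max_iter=_SOLVER_MAX_ITER,
        random_state=seed,
    )
    clf.fit(X, y)
    return clf


class _FoldCache:
    """Per-(stem, fold) vocabularies and design matrices, shared across the
    grid and across all one-vs-rest targets."""

    def __init__(self, labeled: Sequence[LabeledNote], k: int, seed: int,
                 min_count: int, stems: Sequence[bool]):
        self.gold = _gold_array(labeled)
        self.splits = _splits(self.gold, k, seed)
        self.tokens = {s: _tokenized(labeled, s) for s in set(stems)}
        self._matrices: dict[tuple[bool, str, int], tuple[sp.csr_matrix, sp.csr_matrix]] = {}
        self._vocabs: dict[tuple[bool, int], Vocabulary] = {}
        self.min_count = min_count

    def vocabulary(self, stem: bool, fold: int) -> Vocabulary:
        key = (stem, fold)
        if key not in self._vocabs:
            tr, _ = self.splits[fold]
            toks = self.tokens[stem]
            self._vocabs[key] = build_vocabulary([toks[i] for i in tr], self.min_count)
        return self._vocabs[key]

    def matrices(self, stem: bool, mode: str, fold: int) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        key = (stem, mode, fold)
        if key not in self._matrices:
            tr, te = self.splits[fold]
            vocab = self.vocabulary(stem, fold)
            toks = self.tokens[stem]
            Xtr = design_matrix([toks[i] for i in tr], vocab, mode)
            Xte = design_matrix([toks[i] for i in te], vocab, mode)
            self._matrices[key] = (Xtr, Xte)
        return self._matrices[key]


def _cv_one(cache: _FoldCache, specialty: str, config: PipelineConfig,
            k: int, threshold: float, seed: int) -> CVMetrics:
    spec = canonical_specialty(specialty)
    y_all = (cache.gold == spec).astype(int)
    if int(y_all.sum()) < k:
        return CVMetrics(spec, config, skipped=True)
    out = CVMetrics(spec, config)
    for fold, (tr, te) in enumerate(cache.splits):
        Xtr, Xte = cache.matrices(config.stem, config.vectorizer, fold)
        clf = _fit_lr(config, Xtr, y_all[tr], seed)
        probs = clf.predict_proba(Xte)[:, 1]
        out.fold_metrics.append(confusion_metrics(y_all[te], probs, threshold))
    return out


def cross_validate(
    labeled: Sequence[LabeledNote],
    specialty: str,
    config: PipelineConfig,
    k: int = 5,
    threshold: float = 0.5,
    seed: int = 0,
    min_count: int = DEFAULT_MIN_COUNT,
) -> CVMetrics:
    """Stratified k-fold cross-validation of one configuration for one
    specialty; returns ``skipped=True`` when the specialty has fewer
    positive examples than folds."""
    if not labeled:
        raise ValueError("empty corpus")
    cache = _FoldCache(labeled, k, seed, min_count, stems=[config.stem])
    return _cv_one(cache, specialty, config, k, threshold, seed)


def run_grid(
    labeled: Sequence[LabeledNote],
    specialties: Sequence[str],
    grid: GridSpec = GridSpec(),
    k: int = 5,
    threshold: float = 0.5,
    seed: int = 0,
    min_count: int = DEFAULT_MIN_COUNT,
) -> dict[str, list[CVMetrics]]:
    """Cross-validate every grid configuration for every specialty.

    Tokenization, fold splits, vocabularies and design matrices are shared
    across configurations and one-vs-rest targets, so the 80-model grid
    costs 80 logistic fits per specialty, not 80 featurizations.
    """
    if not labeled:
        raise ValueError("empty corpus")
    configs = enumerate_configs(grid)
    cache = _FoldCache(labeled, k, seed, min_count, stems=grid.stemming)
    results: dict[str, list[CVMetrics]] = {}
    for specialty in specialties:
        spec = canonical_specialty(specialty)
        results[spec] = [_cv_one(cache, spec, cfg, k, threshold, seed) for cfg in configs]
    return results


def cv_results_table(results: Mapping[str, list[CVMetrics]]):
    """Long-format table of grid results (one row per specialty x config)."""
    import pandas as pd

    rows = []
    for spec, cvs in results.items():
        for cv in cvs:
            row: dict[str, object] = {
                "specialty": spec,
                "config_index": cv.config.index,
                "stem": cv.config.stem,
                "vectorizer": cv.config.vectorizer,
                "penalty": cv.config.penalty,
                "C": cv.config.C,
                "class_weight": cv.config.class_weight or "none",
                "skipped": cv.skipped,
            }
            for m in METRIC_NAMES:
                row[f"{m}_mean"] = cv.mean(m) if not cv.skipped else math.nan
                row[f"{m}_std"] = cv.std(m) if not cv.skipped else math.nan
            rows.append(row)
    return pd.DataFrame(rows)


def train_final(
    labeled: Sequence[LabeledNote],
    specialty: str,
    config: PipelineConfig,
    min_count: int = DEFAULT_MIN_COUNT,
    seed: int = 0,
) -> FittedClassifier:
    """Fit the chosen configuration on the full gold corpus.

    Balanced class weighting assigns w_c = n_total / (2 * n_c) to class c.
    """
    spec = canonical_specialty(specialty)
    y = (_gold_array(labeled) == spec).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"corpus has a single class for specialty {spec!r}")
    tokens = _tokenized(labeled, config.stem)
    vocab = build_vocabulary(tokens, min_count)
    X = design_matrix(tokens, vocab, config.vectorizer)
    clf = _fit_lr(config, X, y, seed)
    return FittedClassifier(config, vocab, clf.coef_.ravel().copy(),
                            float(clf.intercept_[0]), spec)


def predict_proba(classifier: FittedClassifier, text: str) -> float:
    """Probability that ``text`` targets the classifier's specialty."""
    return float(predict_proba_batch(classifier, [text])[0])


def predict_proba_batch(classifier: FittedClassifier, texts: Sequence[str]) -> np.ndarray:
    tokens = [normalize(t, stem=classifier.config.stem) for t in texts]
    return predict_proba_tokens(classifier, tokens)


def predict_proba_tokens(
    classifier: FittedClassifier, token_lists: Sequence[Sequence[str]]
) -> np.ndarray:
    """Probabilities for already-tokenized texts (tokenized with the
    classifier's own stemming setting)."""
    X = design_matrix(token_lists, classifier.vocabulary, classifier.config.vectorizer)
    z = classifier.decision(X)
    return 1.0 / (1.0 + np.exp(-z))
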