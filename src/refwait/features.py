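"""Text normalization and document vectorization for referral notes.

Notes are lowercased, stripped of punctuation and digits, and split on
whitespace; optional Snowball stemming collapses inflectional variants.
Documents are represented either as raw unigram count vectors or as
smoothed tf-idf vectors (idf = ln((1+N)/(1+df)) + 1, Euclidean-normalized)
over a vocabulary restricted to tokens seen at least ``min_count`` times in
the corpus the vocabulary was built on.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .stemmer import stem as snowball_stem

COUNT = "count"
TFIDF = "tfidf"

_NON_LETTER = re.compile(r"[^a-z\s]")


def normalize(text: str, stem: bool = False) -> list[str]:
    """Tokenize note text: lowercase, drop punctuation/digits, split.

    Every character that is neither a (lowercased) letter nor whitespace is
    replaced by a space, so "r/o" tokenizes as ["r", "o"] and "2015." leaves
    nothing. With ``stem=True`` each token is replaced by its Snowball
    (English) stem.
    """
    tokens = _NON_LETTER.sub(" ", text.lower()).split()
    if stem:
        tokens = [snowball_stem(t) for t in tokens]
    return tokens


@dataclass
class Vocabulary:
    """Frequency-thresholded unigram vocabulary with document frequencies."""

    tokens: list[str]
    doc_freq: np.ndarray  # documents containing each token, in the build corpus
    n_docs: int           # size of the build corpus
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def idf(self) -> np.ndarray:
        return np.log((1.0 + self.n_docs) / (1.0 + self.doc_freq)) + 1.0

    def to_table(self) -> "list[tuple[str, int]]":
        return list(zip(self.tokens, self.doc_freq.tolist()))

    @classmethod
    def from_table(cls, rows: Iterable[tuple[str, int]], n_docs: int) -> "Vocabulary":
        toks, dfs = zip(*rows) if rows else ((), ())
        return cls(list(toks), np.asarray(dfs, dtype=np.int64), n_docs)


def build_vocabulary(token_lists: Sequence[Sequence[str]], min_count: int = 5) -> Vocabulary:
    """Build a vocabulary from tokenized documents.

    Keeps exactly the unigrams whose *total* corpus frequency is at least
    ``min_count`` (rarer tokens tend to be misspellings and hurt
    generalization), ordered lexicographically for determinism.
    """
    if len(token_lists) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    totals: Counter[str] = Counter()
    dfs: Counter[str] = Counter()
    for toks in token_lists:
        totals.update(toks)
        dfs.update(set(toks))
    kept = sorted(t for t, c in totals.items() if c >= min_count)
    df = np.array([dfs[t] for t in kept], dtype=np.int64)
    return Vocabulary(kept, df, n_docs=len(token_lists))


@dataclass
class DocumentVector:
    weights: dict[int, float]
    mode: str

    def dense(self, size: int) -> np.ndarray:
        v = np.zeros(size)
        for i, w in self.weights.items():
            v[i] = w
        return v


def vectorize(tokens: Sequence[str], vocab: Vocabulary, mode: str = COUNT) -> DocumentVector:
    """Vectorize one tokenized document against ``vocab``.

    Count mode gives raw occurrence counts (out-of-vocabulary tokens are
    ignored); tfidf mode multiplies counts by the smoothed idf and
    Euclidean-normalizes (all-zero documents stay all-zero).
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    if mode not in (COUNT, TFIDF):
        raise ValueError(f"unknown vectorization mode: {mode!r}")
    counts: dict[int, float] = {}
    for t in tokens:
        i = vocab.index.get(t)
        if i is not None:
            counts[i] = counts.get(i, 0.0) + 1.0
    if mode == COUNT:
        return DocumentVector(counts, COUNT)
    idf = vocab.idf()
    weights = {i: c * idf[i] for i, c in counts.items()}
    norm = np.sqrt(sum(w * w for w in weights.values()))
    if norm > 0:
        weights = {i: w / norm for i, w in weights.items()}
    return DocumentVector(weights, TFIDF)


def count_matrix(token_lists: Sequence[Sequence[str]], vocab: Vocabulary) -> sp.csr_matrix:
    """Sparse document-term count matrix for a tokenized corpus."""
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for toks in token_lists:
        row: dict[int, int] = {}
        for t in toks:
            i = vocab.index.get(t)
            if i is not None:
                row[i] = row.get(i, 0) + 1
        for i in sorted(row):
            indices.append(i)
            data.append(row[i])
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int32), np.asarray(indptr, dtype=np.int32)),
        shape=(len(token_lists), len(vocab)),
    )


def apply_tfidf(counts: sp.csr_matrix, vocab: Vocabulary) -> sp.csr_matrix:
    """Idf-weight and row-normalize a count matrix (rows with no
    in-vocabulary tokens remain zero)."""
    X = counts.multiply(vocab.idf()[None, :]).tocsr()
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    norms[norms == 0] = 1.0
    return sp.csr_matrix(X.multiply(1.0 / norms[:, None]))


def design_matrix(token_lists: Sequence[Sequence[str]], vocab: Vocabulary, mode: str) -> sp.csr_matrix:
    if mode == COUNT:
        return count_matrix(token_lists, vocab)
    if mode == TFIDF:
        return apply_tfidf(count_matrix(token_lists, vocab), vocab)
    raise ValueError(f"unknown vectorization mode: {mode!r}")
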