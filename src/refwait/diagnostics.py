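"""Diagnostic analyses: training-set size, note length, threshold sweep.

Three companion analyses to the main pipeline: (1) best F1 against the
number of gold notes per specialty; (2) mean classification accuracy as a
function of note length (with small-cell suppression of lengths carrying
fewer than five notes); (3) a confidence-threshold sweep showing the
precision/sensitivity trade-off alongside the wait-time medians it
implies, with a gold-only baseline median that uses no classifier at all.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ConsultClaim, LabeledNote, ReferralNote, count_tokens
from .grid import FittedClassifier, confusion_metrics, predict_proba_batch
from .selection import SelectionResult
from .waits import link_wait_times, WaitObservation

SUPPRESSION_MIN_NOTES = 5


def f1_vs_training_size(
    best_f1_selections: Mapping[str, SelectionResult],
    counts: Mapping[str, int],
) -> pd.DataFrame:
    """Join per-specialty gold-note counts with the best-F1 scheme's F1."""
    if set(best_f1_selections) != set(counts):
        raise ValueError(
            f"specialty sets differ: selections={sorted(best_f1_selections)} "
            f"counts={sorted(counts)}"
        )
    rows = [
        {"specialty": s, "n_notes": counts[s], "best_f1": best_f1_selections[s].f1}
        for s in sorted(best_f1_selections)
    ]
    return pd.DataFrame(rows)


@dataclass
class LengthAccuracyRow:
    token_count: int
    n_notes: int
    mean_accuracy: float | None  # None when suppressed
    suppressed: bool


def accuracy_by_note_length(
    classifiers: Mapping[str, FittedClassifier],
    gold_notes: Sequence[LabeledNote],
    min_notes: int = SUPPRESSION_MIN_NOTES,
    threshold: float = 0.5,
) -> list[LengthAccuracyRow]:
    """Mean binary accuracy by note length across specialties' classifiers.

    For each token count L, each specialty's classifier is scored on all
    gold notes of length L (positive = the note's gold label is that
    specialty; accuracy = (TP+TN)/n), then accuracies are averaged
    unweighted across classifiers. Lengths with fewer than ``min_notes``
    notes are emitted as suppressed rows with no accuracy value.
    """
    lengths = np.array([count_tokens(ln.note.text) for ln in gold_notes])
    texts = [ln.note.text for ln in gold_notes]
    gold = np.array([ln.gold_specialty for ln in gold_notes])

    preds: dict[str, np.ndarray] = {
        spec: predict_proba_batch(clf, texts) >= threshold
        for spec, clf in classifiers.items()
    }

    rows: list[LengthAccuracyRow] = []
    for length in sorted(set(lengths.tolist())):
        mask = lengths == length
        n = int(mask.sum())
        if n < min_notes:
            rows.append(LengthAccuracyRow(length, n, None, True))
            continue
        accs = [
            float(np.mean((gold[mask] == spec) == preds[spec][mask]))
            for spec in sorted(classifiers)
        ]
        rows.append(LengthAccuracyRow(length, n, float(np.mean(accs)), False))
    return rows


def length_accuracy_table(rows: Sequence[LengthAccuracyRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "token_count": r.token_count,
                "n_notes": r.n_notes if not r.suppressed else f"<{SUPPRESSION_MIN_NOTES}",
                "mean_accuracy": r.mean_accuracy if not r.suppressed else "",
                "suppressed": r.suppressed,
            }
            for r in rows
        ]
    )


def threshold_sweep(
    classifiers: Mapping[str, FittedClassifier],
    gold_notes: Sequence[LabeledNote],
    full_notes: Sequence[ReferralNote],
    claims: Sequence[ConsultClaim],
    thresholds: Sequence[float],
    study_year: int,
) -> pd.DataFrame:
    """Per-specialty sweep of the confidence threshold.

    For each (specialty, threshold): precision (PPV) and sensitivity on
    the gold set, plus the median wait from deploying at that threshold on
    the full note stream and linking to claims. The ``baseline_median``
    column is the gold-only wait median — patients in the gold set, linked
    by their gold label with no classifier — and is constant across
    thresholds. Rows where a quantity is undefined (no predicted
    positives, no linked observations) carry NaN with a flag.
    """
    thresholds = list(thresholds)
    if any(not 0 < t < 1 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending within (0, 1)")

    gold_texts = [ln.note.text for ln in gold_notes]
    gold_labels = {spec: np.array([ln.gold_specialty == spec for ln in gold_notes], dtype=int)
                   for spec in classifiers}
    gold_probs = {spec: predict_proba_batch(clf, gold_texts)
                  for spec, clf in classifiers.items()}
    full_probs = {spec: predict_proba_batch(clf, [n.text for n in full_notes])
                  for spec, clf in classifiers.items()}

    # gold-only baseline: link gold pairs by their inferred label, no classifier
    baseline_positives = [(ln.note.note_id, ln.gold_specialty) for ln in gold_notes]
    gold_note_objs = [ln.note for ln in gold_notes]
    baseline_obs = link_wait_times(baseline_positives, gold_note_objs, claims, study_year)
    baseline_median: dict[str, float] = {}
    by_spec: dict[str, list[WaitObservation]] = defaultdict(list)
    for o in baseline_obs:
        by_spec[o.specialty].append(o)
    for spec in classifiers:
        obs = by_spec.get(spec, [])
        baseline_median[spec] = float(np.median([o.wait for o in obs])) if obs else np.nan

    rows = []
    for spec in sorted(classifiers):
        for t in thresholds:
            m = confusion_metrics(gold_labels[spec], gold_probs[spec], t)
            pos = [(n.note_id, spec) for n, p in zip(full_notes, full_probs[spec]) if p >= t]
            obs = link_wait_times(pos, full_notes, claims, study_year)
            waits = [o.wait for o in obs if o.specialty == spec]
            rows.append({
                "specialty": spec,
                "threshold": t,
                "ppv": m.precision,
                "sensitivity": m.recall,
                "n_positive": len(pos),
                "n_linked": len(waits),
                "median_wait": float(np.median(waits)) if waits else np.nan,
                "baseline_median": baseline_median[spec],
                "undefined_ppv": "precision" in m.undefined,
                "undefined_median": not waits,
            })
    return pd.DataFrame(rows)
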