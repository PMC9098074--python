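"""Constrained model selection and the deployment gate.

Three optimization schemes pick one grid configuration per specialty:

* ``precision-floor`` — highest mean precision among configurations with
  mean recall >= 0.3 (a near-useless high-precision/zero-recall model is
  easy to find otherwise); if none qualifies, the globally most precise
  configuration is returned with ``fallback=True``.
* ``recall-floor`` — the mirror image: highest recall subject to
  precision >= 0.3.
* ``best-f1`` — highest mean F1, unconstrained.

Wait times are only estimated for specialties whose precision-floor model
clears the deployment gate (precision >= 0.70 and recall >= 0.30): below
that, contamination from wrong-specialty matches makes the estimates
untrustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .grid import CVMetrics, PipelineConfig

PRECISION_FLOOR = "precision-floor"
RECALL_FLOOR = "recall-floor"
BEST_F1 = "best-f1"
SCHEMES = (PRECISION_FLOOR, RECALL_FLOOR, BEST_F1)

DEFAULT_FLOOR = 0.3
GATE_MIN_PRECISION = 0.70
GATE_MIN_RECALL = 0.30


@dataclass
class SelectionResult:
    specialty: str
    scheme: str
    config: PipelineConfig
    precision: float
    recall: float
    f1: float
    fallback: bool = False
    eligible: bool | None = None


def _argmax(
    candidates: Sequence[CVMetrics], primary: str
) -> CVMetrics:
    # ties: higher mean precision, then lower enumeration index
    return max(
        candidates,
        key=lambda cv: (cv.mean(primary), cv.mean("precision"), -cv.config.index),
    )


def select_model(
    cv_results: Sequence[CVMetrics], scheme: str, floor: float = DEFAULT_FLOOR
) -> SelectionResult:
    """Pick one configuration for one specialty under ``scheme``."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme: {scheme!r}")
    usable = [cv for cv in cv_results if not cv.skipped]
    if not usable:
        raise ValueError("all configurations were skipped for this specialty")
    specialty = usable[0].specialty

    fallback = False
    if scheme == BEST_F1:
        chosen = _argmax(usable, "f1")
    elif scheme == PRECISION_FLOOR:
        qualifying = [cv for cv in usable if cv.mean("recall") >= floor]
        if qualifying:
            chosen = _argmax(qualifying, "precision")
        else:
            chosen = _argmax(usable, "precision")
            fallback = True
    else:  # RECALL_FLOOR
        qualifying = [cv for cv in usable if cv.mean("precision") >= floor]
        if qualifying:
            chosen = _argmax(qualifying, "recall")
        else:
            chosen = _argmax(usable, "recall")
            fallback = True

    return SelectionResult(
        specialty=specialty,
        scheme=scheme,
        config=chosen.config,
        precision=chosen.mean("precision"),
        recall=chosen.mean("recall"),
        f1=chosen.mean("f1"),
        fallback=fallback,
    )


def select_all(
    results_by_specialty: Mapping[str, Sequence[CVMetrics]],
    schemes: Iterable[str] = SCHEMES,
    floor: float = DEFAULT_FLOOR,
) -> dict[str, dict[str, SelectionResult]]:
    """Selection table: specialty -> scheme -> chosen configuration.

    Specialties whose every configuration was skipped (fewer positive
    examples than folds) are omitted.
    """
    out: dict[str, dict[str, SelectionResult]] = {}
    for spec, cvs in results_by_specialty.items():
        if all(cv.skipped for cv in cvs):
            continue
        out[spec] = {sch: select_model(cvs, sch, floor) for sch in schemes}
    return out


@dataclass
class SummaryMetrics:
    """Grid-result summary reconstructed from a saved long-format table.

    Duck-type compatible with :class:`refwait.grid.CVMetrics` for the
    purposes of selection (``specialty``, ``config``, ``skipped``,
    ``mean``)."""

    specialty: str
    config: PipelineConfig
    means: Mapping[str, float]
    skipped: bool = False

    def mean(self, metric: str) -> float:
        return float(self.means[metric])


def results_from_table(df: pd.DataFrame) -> dict[str, list[SummaryMetrics]]:
    """Rebuild per-specialty grid summaries from a ``cv_results`` table."""
    out: dict[str, list[SummaryMetrics]] = {}
    for row in df.itertuples():
        cfg = PipelineConfig(
            index=int(row.config_index),
            stem=bool(row.stem),
            vectorizer=str(row.vectorizer),
            penalty=str(row.penalty),
            C=float(row.C),
            class_weight=None if str(row.class_weight) == "none" else str(row.class_weight),
        )
        means = {m: getattr(row, f"{m}_mean")
                 for m in ("precision", "recall", "f1", "specificity", "npv", "brier")}
        out.setdefault(str(row.specialty), []).append(
            SummaryMetrics(str(row.specialty), cfg, means, skipped=bool(row.skipped))
        )
    return out


def gate_specialties(
    precision_floor_results: Mapping[str, SelectionResult],
    min_precision: float = GATE_MIN_PRECISION,
    min_recall: float = GATE_MIN_RECALL,
) -> set[str]:
    """Specialties whose precision-floor model is trustworthy enough to
    deploy for wait-time estimation.

    Eligibility requires mean precision >= min_precision, mean recall >=
    min_recall, and a genuinely constraint-satisfying (non-fallback)
    selection; fallback selections have sub-floor recall by construction.
    """
    eligible: set[str] = set()
    for spec, res in precision_floor_results.items():
        ok = (not res.fallback
              and res.precision >= min_precision
              and res.recall >= min_recall)
        res.eligible = ok
        if ok:
            eligible.add(spec)
    return eligible


def selection_table(
    selections: Mapping[str, Mapping[str, SelectionResult]]
) -> pd.DataFrame:
    """Flat per-specialty-per-scheme table (mirrors a three-scheme report)."""
    rows = []
    for spec in sorted(selections):
        for scheme, res in selections[spec].items():
            rows.append({
                "specialty": spec,
                "scheme": scheme,
                "config_index": res.config.index,
                "stem": res.config.stem,
                "vectorizer": res.config.vectorizer,
                "penalty": res.config.penalty,
                "C": res.config.C,
                "class_weight": res.config.class_weight or "none",
                "precision": res.precision,
                "recall": res.recall,
                "f1": res.f1,
                "fallback": res.fallback,
                "eligible": res.eligible,
            })
    return pd.DataFrame(rows)
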