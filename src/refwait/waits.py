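"""Wait-time estimation: deploy gated classifiers, link notes to claims,
and bootstrap quantile confidence intervals.

The wait for a (patient, specialty) pair is the calendar-day difference
between the patient's first positively-predicted referral note in the
study year and the first consult claim of that specialty on or after it
(claims may fall in the study year or the next, so late-December referrals
keep their consults). Quantiles (median, 75th, 90th percentile) get 95%
percentile-bootstrap confidence intervals, and a prior-period point value
is called a *substantial* change exactly when it lies outside the current
95% CI.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ConsultClaim, ReferralNote, canonical_specialty
from .grid import FittedClassifier, predict_proba_batch

DEFAULT_THRESHOLD = 0.5
DEFAULT_QUANTILES = (0.5, 0.75, 0.9)
DEFAULT_BOOTSTRAP = 1000

SUBSTANTIAL_INCREASE = "substantial increase"
SUBSTANTIAL_DECREASE = "substantial decrease"
NON_SUBSTANTIAL = "non-substantial change"


@dataclass(frozen=True)
class WaitObservation:
    patient_id: str
    specialty: str
    referral_date: Date
    consult_date: Date

    @property
    def wait(self) -> int:
        return (self.consult_date - self.referral_date).days


@dataclass(frozen=True)
class QuantileEstimate:
    level: float
    point: float
    ci_low: float
    ci_high: float


@dataclass
class WaitTimeEstimate:
    specialty: str
    n: int
    quantiles: dict[float, QuantileEstimate]
    bootstrap_replicates: int
    seed: int


def deploy(
    classifiers: Mapping[str, FittedClassifier],
    notes: Sequence[ReferralNote],
    threshold: float = DEFAULT_THRESHOLD,
) -> set[tuple[str, str]]:
    """Run every eligible specialty's classifier over every note.

    Returns the set of positive (note_id, specialty) pairs; a note may be
    claimed by several specialties, or by none. ``notes`` must already be
    short-note filtered, as in training.
    """
    positives: set[tuple[str, str]] = set()
    texts = [n.text for n in notes]
    for spec, clf in classifiers.items():
        spec = canonical_specialty(spec)
        probs = predict_proba_batch(clf, texts)
        for note, p in zip(notes, probs):
            if p >= threshold:
                positives.add((note.note_id, spec))
    return positives


def link_wait_times(
    positives: Iterable[tuple[str, str]],
    notes: Sequence[ReferralNote],
    claims: Sequence[ConsultClaim],
    study_year: int,
) -> list[WaitObservation]:
    """Pair each patient's first predicted referral per specialty with the
    first matching consult claim.

    Per (patient, specialty): the earliest positively-predicted note dated
    in the study year (date ties broken by note_id) is the referral; the
    consult is the earliest claim of that specialty dated on or after the
    referral and within [study_year, study_year + 1]. Patients with no
    qualifying claim contribute nothing.
    """
    positive_set = {(nid, canonical_specialty(s)) for nid, s in positives}
    note_by_id = {n.note_id: n for n in notes}

    first_note: dict[tuple[str, str], ReferralNote] = {}
    for nid, spec in positive_set:
        note = note_by_id.get(nid)
        if note is None or note.date.year != study_year:
            continue
        key = (note.patient_id, spec)
        cur = first_note.get(key)
        if cur is None or (note.date, note.note_id) < (cur.date, cur.note_id):
            first_note[key] = note

    claims_by_key: dict[tuple[str, str], list[Date]] = defaultdict(list)
    for c in claims:
        if c.date.year in (study_year, study_year + 1):
            claims_by_key[(c.patient_id, canonical_specialty(c.specialty))].append(c.date)

    observations: list[WaitObservation] = []
    for (pid, spec), note in first_note.items():
        dates = [d for d in claims_by_key.get((pid, spec), []) if d >= note.date]
        if dates:
            observations.append(WaitObservation(pid, spec, note.date, min(dates)))
    observations.sort(key=lambda o: (o.specialty, o.patient_id))
    return observations


def summarize_waits(
    observations: Sequence[WaitObservation],
    quantile_levels: Sequence[float] = DEFAULT_QUANTILES,
    B: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> WaitTimeEstimate:
    """Empirical quantiles with 95% percentile-bootstrap CIs for one
    specialty's wait observations."""
    if not observations:
        raise ValueError("no wait observations to summarize")
    if B < 1:
        raise ValueError("B must be >= 1")
    specialty = observations[0].specialty
    waits = np.array([o.wait for o in observations], dtype=float)
    rng = np.random.default_rng(seed)
    resamples = waits[rng.integers(0, len(waits), size=(B, len(waits)))]
    quantiles: dict[float, QuantileEstimate] = {}
    for q in quantile_levels:
        point = float(np.quantile(waits, q))
        boot = np.quantile(resamples, q, axis=1)
        lo, hi = np.quantile(boot, [0.025, 0.975])
        # the percentile CI is clipped to bracket the point estimate
        quantiles[q] = QuantileEstimate(q, point, float(min(lo, point)), float(max(hi, point)))
    return WaitTimeEstimate(specialty, len(waits), quantiles, B, seed)


def summarize_by_specialty(
    observations: Sequence[WaitObservation],
    quantile_levels: Sequence[float] = DEFAULT_QUANTILES,
    B: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> dict[str, WaitTimeEstimate]:
    by_spec: dict[str, list[WaitObservation]] = defaultdict(list)
    for o in observations:
        by_spec[o.specialty].append(o)
    return {
        spec: summarize_waits(obs, quantile_levels, B, seed)
        for spec, obs in sorted(by_spec.items())
    }


def compare_periods(estimate: QuantileEstimate, prior_value: float) -> str:
    """Classify the change from a prior-period point value.

    The change is substantial exactly when the prior value falls outside
    the closed 95% CI of the current estimate; direction follows the sign
    of (current point - prior value).
    """
    if estimate.ci_low <= prior_value <= estimate.ci_high:
        return NON_SUBSTANTIAL
    if estimate.point > prior_value:
        return SUBSTANTIAL_INCREASE
    if estimate.point < prior_value:
        return SUBSTANTIAL_DECREASE
    return NON_SUBSTANTIAL


def wait_table(estimates: Mapping[str, WaitTimeEstimate]) -> pd.DataFrame:
    """Delimited-table form of the per-specialty estimates (the tabular
    analogue of a median/p75/p90 error-bar figure)."""
    rows = []
    for spec in sorted(estimates):
        est = estimates[spec]
        row: dict[str, object] = {"specialty": spec, "n": est.n}
        for q, qe in est.quantiles.items():
            tag = f"p{int(round(q * 100))}"
            row[tag] = qe.point
            row[f"{tag}_ci_low"] = qe.ci_low
            row[f"{tag}_ci_high"] = qe.ci_high
        rows.append(row)
    return pd.DataFrame(rows)
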