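"""Weakly supervised gold labels from referral-note / consult-claim linkage.

A referral note carries no trustworthy specialty label, but a patient who
had exactly one referral note and exactly one specialist consult claim in
the study year almost certainly saw the specialist the note was written
for. Pairing those two events yields a "gold" specialty label for the
note's text without manual abstraction. Notes with fewer than six tokens
are discarded first (they are stubs — a name and a date — not true
referrals), and specialties whose scope overlaps too many others (by
default "internal" medicine) are excluded.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .features import normalize

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOKENS = 6
DEFAULT_EXCLUDED = frozenset({"internal"})
SUPPRESSION_THRESHOLD = 5
SUPPRESSED = "<5"


def canonical_specialty(code: str) -> str:
    """Specialty codes are free strings matched case-insensitively after trimming."""
    return code.strip().lower()


@dataclass(frozen=True)
class ReferralNote:
    patient_id: str
    note_id: str
    date: Date
    text: str


@dataclass(frozen=True)
class ConsultClaim:
    patient_id: str
    specialty: str
    date: Date


@dataclass(frozen=True)
class LabeledNote:
    note: ReferralNote
    gold_specialty: str


def count_tokens(text: str) -> int:
    """Token count under the same normalization as vectorization (no stemming)."""
    return len(normalize(text, stem=False))


def filter_short_notes(
    notes: Sequence[ReferralNote], min_tokens: int = DEFAULT_MIN_TOKENS
) -> list[ReferralNote]:
    """Drop uninformative notes with fewer than ``min_tokens`` tokens."""
    if min_tokens < 1:
        raise ValueError("min_tokens must be >= 1")
    kept = [n for n in notes if count_tokens(n.text) >= min_tokens]
    logger.info("short-note filter: removed %d of %d notes", len(notes) - len(kept), len(notes))
    return kept


def derive_gold_pairs(
    notes: Sequence[ReferralNote],
    claims: Sequence[ConsultClaim],
    study_year: int,
    excluded_specialties: Iterable[str] = DEFAULT_EXCLUDED,
) -> list[LabeledNote]:
    """Label notes of patients with exactly one note and one claim in the year.

    ``notes`` must already have passed the short-note filter. Patients with
    any other event multiplicity are ambiguous (k notes x k claims admit up
    to k! pairings) and contribute nothing. Pairs whose claim specialty is
    excluded are dropped.
    """
    seen_ids: set[str] = set()
    for n in notes:
        if n.note_id in seen_ids:
            raise ValueError(f"duplicate note_id: {n.note_id!r}")
        seen_ids.add(n.note_id)
    excluded = {canonical_specialty(s) for s in excluded_specialties}

    notes_by_patient: dict[str, list[ReferralNote]] = defaultdict(list)
    for n in notes:
        if n.date.year == study_year:
            notes_by_patient[n.patient_id].append(n)
    claims_by_patient: dict[str, list[ConsultClaim]] = defaultdict(list)
    for c in claims:
        if c.date.year == study_year:
            claims_by_patient[c.patient_id].append(c)

    labeled: list[LabeledNote] = []
    for pid, pnotes in notes_by_patient.items():
        pclaims = claims_by_patient.get(pid, [])
        if len(pnotes) == 1 and len(pclaims) == 1:
            spec = canonical_specialty(pclaims[0].specialty)
            if spec not in excluded:
                labeled.append(LabeledNote(pnotes[0], spec))
    labeled.sort(key=lambda ln: ln.note.note_id)
    logger.info("gold pairs: %d labeled notes from %d patients with notes",
                len(labeled), len(notes_by_patient))
    return labeled


def specialty_counts(
    labeled: Sequence[LabeledNote], suppression_threshold: int = SUPPRESSION_THRESHOLD
) -> pd.DataFrame:
    """Per-specialty note counts with small-cell suppression.

    Counts below ``suppression_threshold`` are rendered as the string
    ``"<5"`` (privacy suppression of small cells); the true value is never
    emitted. Zero-count specialties appear as no row at all. Rows are
    ordered by descending true count, ties lexicographic.
    """
    counts = Counter(ln.gold_specialty for ln in labeled)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    display = [
        (s, c if c >= suppression_threshold else f"<{suppression_threshold}")
        for s, c in rows
    ]
    return pd.DataFrame(display, columns=["specialty", "n_notes"])
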