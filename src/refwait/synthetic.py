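"""Synthetic EMR referral notes and consult claims with known ground truth.

Emulates the statistical structure the downstream pipeline assumes: each
specialty has a private keyword vocabulary embedded in shared clinical
filler text; note lengths vary and include uninformative stubs shorter
than six tokens; most patients have exactly one referral and one consult
in the study year while a configurable fraction carry extra confounding
events; waits from referral to consult are log-normal with a known
per-specialty median, so recovery of that median is checkable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .cohort import ConsultClaim, ReferralNote

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "TruthTable",
    "generate_cohort",
    "sample_note_text",
    "sample_wait_days",
]

# Token-count mixture for note lengths. Mass below six tokens exercises the
# short-note filter; the bulk sits in the informative 25-100 token range.
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    3: 0.02, 4: 0.02, 5: 0.03, 8: 0.05, 15: 0.08, 25: 0.12,
    40: 0.18, 60: 0.20, 80: 0.15, 100: 0.08, 125: 0.04, 150: 0.03,
}


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration is internally inconsistent."""


def _alpha(i: int) -> str:
    """Deterministic purely-alphabetic word for index i ('aa', 'ab', ...)."""
    letters = []
    i, r = divmod(i, 26)
    letters.append(chr(ord("a") + r))
    while i > 0:
        i, r = divmod(i, 26)
        letters.append(chr(ord("a") + r))
    while len(letters) < 2:
        letters.append("a")
    return "".join(reversed(letters))


@dataclass(frozen=True)
class TruthRecord:
    specialty: str
    wait_days: int | None  # None for confounder notes with no paired consult


@dataclass
class TruthTable:
    """note_id -> (true specialty, true wait in days or None)."""

    records: dict[str, TruthRecord] = field(default_factory=dict)

    def add(self, note_id: str, record: TruthRecord) -> None:
        if note_id in self.records:
            raise ValueError(f"note {note_id!r} already recorded")
        self.records[note_id] = record

    def __getitem__(self, note_id: str) -> TruthRecord:
        return self.records[note_id]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, note_id: str) -> bool:
        return note_id in self.records


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a three-specialty desk-scale cohort that is separable
    (disjoint keyword vocabularies, 60% of tokens drawn from the note's
    specialty vocabulary) with wait medians of 30/60/90 days — small enough
    to run in seconds, structured enough to exercise every pipeline stage.
    """

    specialties: tuple[str, ...] = ("cardiology", "dermatology", "gastroenterology")
    notes_per_specialty: int = 500
    keyword_vocab_size: int = 40
    shared_vocab_size: int = 400
    keyword_rate: float = 0.6
    note_length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    wait_median_days: Mapping[str, float] = field(
        default_factory=lambda: {"cardiology": 30.0, "dermatology": 60.0,
                                 "gastroenterology": 90.0}
    )
    wait_dispersion: float = 0.5
    multi_event_rate: float = 0.2
    study_year: int = 2015
    seed: int = 0
    keyword_vocabularies: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        if len(self.specialties) < 2:
            raise ConfigurationError("need at least 2 specialties")
        if self.notes_per_specialty < 1:
            raise ConfigurationError("notes_per_specialty must be >= 1")
        if not 0.0 <= self.keyword_rate <= 1.0:
            raise ConfigurationError("keyword_rate must lie in [0, 1]")
        if not 0.0 <= self.multi_event_rate <= 1.0:
            raise ConfigurationError("multi_event_rate must lie in [0, 1]")
        if self.wait_dispersion < 0:
            raise ConfigurationError("wait_dispersion must be non-negative")
        missing = [s for s in self.specialties if s not in self.wait_median_days]
        if missing:
            raise ConfigurationError(f"no wait median configured for {missing}")
        if any(self.wait_median_days[s] <= 0 for s in self.specialties):
            raise ConfigurationError("wait medians must be positive")
        lengths = self.note_length_distribution
        if not lengths or any(l < 1 for l in lengths):
            raise ConfigurationError("note lengths must be positive integers")
        vocabs = self.specialty_vocabularies()
        seen: set[str] = set()
        for spec, words in vocabs.items():
            overlap = seen.intersection(words)
            if overlap or len(set(words)) < len(list(words)):
                raise ConfigurationError(
                    f"keyword vocabularies are not disjoint (specialty {spec!r})"
                )
            seen.update(words)
        if seen.intersection(self.shared_vocabulary()):
            raise ConfigurationError("keyword vocabularies overlap the shared vocabulary")

    def specialty_vocabularies(self) -> dict[str, list[str]]:
        if self.keyword_vocabularies is not None:
            return {s: list(v) for s, v in self.keyword_vocabularies.items()}
        return {
            s: [f"{s}{_alpha(i)}" for i in range(self.keyword_vocab_size)]
            for s in self.specialties
        }

    def shared_vocabulary(self) -> list[str]:
        return [f"filler{_alpha(i)}" for i in range(self.shared_vocab_size)]


def sample_note_text(
    config: SyntheticConfig, specialty: str, length: int, rng: np.random.Generator
) -> str:
    """Draw a note of ``length`` tokens: a keyword_rate mixture of the
    specialty's keyword vocabulary and the shared filler vocabulary."""
    if length < 1:
        raise ValueError("length must be >= 1")
    vocabs = config.specialty_vocabularies()
    if specialty not in vocabs:
        raise KeyError(f"unknown specialty: {specialty!r}")
    kw = vocabs[specialty]
    shared = config.shared_vocabulary()
    from_kw = rng.random(length) < config.keyword_rate
    tokens = [
        kw[rng.integers(len(kw))] if is_kw else shared[rng.integers(len(shared))]
        for is_kw in from_kw
    ]
    return " ".join(tokens)


def sample_wait_days(
    config: SyntheticConfig, specialty: str, rng: np.random.Generator
) -> int:
    """Log-normal wait with median ``wait_median_days[specialty]`` and
    log-scale sigma ``wait_dispersion``, rounded to whole days."""
    median = config.wait_median_days[specialty]
    if config.wait_dispersion == 0:
        return int(round(median))
    draw = math.exp(math.log(median) + config.wait_dispersion * rng.standard_normal())
    return int(round(draw))


def _uniform_date(year: int, rng: np.random.Generator) -> Date:
    start = Date(year, 1, 1).toordinal()
    end = Date(year, 12, 31).toordinal()
    return Date.fromordinal(int(rng.integers(start, end + 1)))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[ReferralNote], list[ConsultClaim], TruthTable]:
    """Generate one cohort of notes, claims and ground truth.

    Every patient receives one referral note (date uniform over the study
    year) and one consult claim of the same specialty at referral date +
    drawn wait (which may spill into the following year). A
    ``multi_event_rate`` fraction of patients additionally receive one or
    two confounding events — extra notes and/or extra claims with uniformly
    drawn specialties and dates — which disqualifies them from the
    single-note/single-claim gold-pair rule downstream.
    """
    rng = np.random.default_rng(config.seed)
    lengths = sorted(config.note_length_distribution)
    probs = np.array([config.note_length_distribution[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()

    notes: list[ReferralNote] = []
    claims: list[ConsultClaim] = []
    truth = TruthTable()
    counter = 0
    for spec in config.specialties:
        for _ in range(config.notes_per_specialty):
            pid = f"p{counter:06d}"
            nid = f"n{counter:06d}"
            counter += 1
            length = int(lengths[rng.choice(len(lengths), p=probs)])
            text = sample_note_text(config, spec, length, rng)
            ref_date = _uniform_date(config.study_year, rng)
            wait = sample_wait_days(config, spec, rng)
            notes.append(ReferralNote(pid, nid, ref_date, text))
            claims.append(ConsultClaim(pid, spec, ref_date + timedelta(days=wait)))
            truth.add(nid, TruthRecord(spec, wait))

            if rng.random() < config.multi_event_rate:
                for _ in range(int(rng.integers(1, 3))):
                    other = config.specialties[rng.integers(len(config.specialties))]
                    if rng.random() < 0.5:
                        xid = f"n{counter:06d}x"
                        counter += 1
                        xlen = int(lengths[rng.choice(len(lengths), p=probs)])
                        xtext = sample_note_text(config, other, xlen, rng)
                        notes.append(ReferralNote(pid, xid, _uniform_date(config.study_year, rng), xtext))
                        truth.add(xid, TruthRecord(other, None))
                    else:
                        claims.append(ConsultClaim(pid, other, _uniform_date(config.study_year, rng)))
    return notes, claims, truth
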