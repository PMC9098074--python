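"""Readers and writers for the pipeline's plain-text interchange formats.

Notes and claims travel as JSON-lines or delimited (CSV) tables; the
synthetic truth table as JSON-lines. Dates are ISO-8601 throughout.
Delimited outputs may carry leading ``#`` header lines recording run
metadata (seeds, stage parameters); readers skip them.
"""

from __future__ import annotations

import json
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import ConsultClaim, ReferralNote
from .synthetic import TruthRecord, TruthTable


def _header_lines(header: Mapping[str, object] | None) -> str:
    if not header:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in header.items())


# ---------------------------------------------------------------- notes

def write_notes_jsonl(notes: Sequence[ReferralNote], path: str | Path) -> None:
    with open(path, "w") as fh:
        for n in notes:
            fh.write(json.dumps({
                "patient_id": n.patient_id, "note_id": n.note_id,
                "date": n.date.isoformat(), "text": n.text,
            }) + "\n")


def read_notes_jsonl(path: str | Path) -> list[ReferralNote]:
    notes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            notes.append(ReferralNote(d["patient_id"], d["note_id"],
                                      Date.fromisoformat(d["date"]), d["text"]))
    return notes


def write_notes_csv(notes: Sequence[ReferralNote], path: str | Path,
                    header: Mapping[str, object] | None = None) -> None:
    df = pd.DataFrame(
        [(n.patient_id, n.note_id, n.date.isoformat(), n.text) for n in notes],
        columns=["patient_id", "note_id", "date", "text"],
    )
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        df.to_csv(fh, index=False)


def read_notes_csv(path: str | Path) -> list[ReferralNote]:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    return [ReferralNote(r.patient_id, r.note_id, Date.fromisoformat(r.date), r.text)
            for r in df.itertuples()]


# ---------------------------------------------------------------- claims

def write_claims_jsonl(claims: Sequence[ConsultClaim], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in claims:
            fh.write(json.dumps({
                "patient_id": c.patient_id, "specialty": c.specialty,
                "date": c.date.isoformat(),
            }) + "\n")


def read_claims_jsonl(path: str | Path) -> list[ConsultClaim]:
    claims = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            claims.append(ConsultClaim(d["patient_id"], d["specialty"],
                                       Date.fromisoformat(d["date"])))
    return claims


def write_claims_csv(claims: Sequence[ConsultClaim], path: str | Path,
                     header: Mapping[str, object] | None = None) -> None:
    df = pd.DataFrame(
        [(c.patient_id, c.specialty, c.date.isoformat()) for c in claims],
        columns=["patient_id", "specialty", "date"],
    )
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        df.to_csv(fh, index=False)


def read_claims_csv(path: str | Path) -> list[ConsultClaim]:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    return [ConsultClaim(r.patient_id, r.specialty, Date.fromisoformat(r.date))
            for r in df.itertuples()]


# ---------------------------------------------------------------- truth

def write_truth_jsonl(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for note_id, rec in truth.records.items():
            fh.write(json.dumps({
                "note_id": note_id, "specialty": rec.specialty,
                "wait_days": rec.wait_days,
            }) + "\n")


def read_truth_jsonl(path: str | Path) -> TruthTable:
    truth = TruthTable()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            truth.add(d["note_id"], TruthRecord(d["specialty"], d["wait_days"]))
    return truth


# ---------------------------------------------------------------- tables

def write_table(df: pd.DataFrame, path: str | Path,
                header: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
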