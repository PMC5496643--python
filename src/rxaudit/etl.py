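"""Prescription ETL: raw outpatient records → per-visit drug transactions.

One unit of analysis is a patient-day visit: the hospital number and the
prescription date are joined into a visit key, drug codes are collapsed to
their 4-character stems, and only visits prescribing at least two distinct
study-class drugs (antacids, peptic-ulcer/GORD drugs, NSAIDs) on the same
day are retained for rule mining.  Visit-level audit context (age, sex,
diagnosis codes, dose schedules, aspirin exposure) is assembled here as
well, for the downstream guideline audit.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import (
    ASPIRIN_STEMS,
    MINED_CLASSES,
    AtcClass,
    DrugEntry,
    classify_atc,
    load_catalog,
)

logger = logging.getLogger(__name__)

#: Inclusive ICD-10 ranges defining gastrointestinal complications,
#: dot-stripped (K20–K29.9, K30–K38.9, K90–K93.8).
GI_RANGES: tuple[tuple[str, str], ...] = (
    ("K20", "K299"),
    ("K30", "K389"),
    ("K90", "K938"),
)

_ICD_RE = re.compile(r"^[A-Z]\d{2}\d*$")
_DOSE_RE = re.compile(r"^(\d+)(CAP|TAB)(AM|PM|BID)(.*)$")


class InvalidDrugCodeError(ValueError):
    """Raised for drug codes too short to carry a 4-character stem."""


class IcdCodeError(ValueError):
    """Raised for diagnosis codes that do not look like ICD-10."""


@dataclass(frozen=True)
class PrescriptionRow:
    patient_id: str
    date: _dt.date
    raw_code: str
    dose_freq_code: str = ""
    clinic_code: str = ""


@dataclass(frozen=True)
class Transaction:
    """A patient-day visit and the set of drug stems prescribed on it."""

    visit_key: str
    items: frozenset[str]


@dataclass(frozen=True)
class TransactionSet:
    transactions: tuple[Transaction, ...]

    @property
    def n(self) -> int:
        return len(self.transactions)

    def __iter__(self):
        return iter(self.transactions)

    def item_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t.items
        return frozenset(out)


class DoseUnit(str, enum.Enum):
    CAP = "CAP"
    TAB = "TAB"
    OTHER = "other"


@dataclass(frozen=True)
class DoseSchedule:
    """Parsed dose/frequency code, e.g. ``1CAPAM`` = one capsule each morning.

    ``BID`` means twice a day (morning and evening). Unrecognised trailing
    text (such as the hospital's ``SD`` suffix, undocumented in the source
    data) is preserved verbatim in ``modifier``.
    """

    quantity: int
    unit: DoseUnit
    meals: frozenset[str]  # subset of {"morning", "evening"}
    modifier: str = ""


@dataclass(frozen=True)
class VisitContext:
    """Audit facts for one visit: demographics, diagnoses, aspirin, schedules."""

    visit_key: str
    age_years: int
    sex: str  # "male" | "female"
    dx_codes: frozenset[str]
    aspirin: bool
    per_drug: Mapping[str, tuple[DoseSchedule, str]] = field(default_factory=dict)


def make_visit_key(patient_id: str, date: _dt.date | str) -> str:
    """Visit key ``HN|YYYY-MM-DD`` — unambiguous and sortable."""
    if isinstance(date, _dt.date):
        date = date.isoformat()
    return f"{patient_id}|{date}"


def normalize_drug_code(raw_code: str) -> str:
    """First 4 characters of a drug code: the compound stem.

    Collapses strength and form variants (``IBUP1T-``, ``IBUP2T-``,
    ``IBUP-S-``) onto one stem (``IBUP``). Idempotent on 4-character input.
    """
    if len(raw_code) < 4:
        raise InvalidDrugCodeError(
            f"drug code {raw_code!r} is shorter than the 4-character stem"
        )
    return raw_code[:4]


def build_transactions(
    rows: Iterable[PrescriptionRow],
    catalog: Sequence[DrugEntry] | None = None,
) -> tuple[TransactionSet, int]:
    """Group prescriptions into per-visit stem sets and apply the study filter.

    Keeps only drugs classifying into the mined ATC classes, deduplicates
    stems within a patient-day, and drops patient-days left with fewer than
    two distinct stems.  Returns the retained transactions (sorted by visit
    key) and the number of omitted patient-days; retained + omitted equals
    the number of distinct patient-days in the input.
    """
    catalog_t = tuple(catalog) if catalog is not None else load_catalog()
    stem_class = {e.stem: e.atc_class for e in reversed(catalog_t)}

    visits: dict[str, set[str]] = {}
    for row in rows:
        stem = normalize_drug_code(row.raw_code)
        key = make_visit_key(row.patient_id, row.date)
        bucket = visits.setdefault(key, set())
        if stem_class.get(stem, AtcClass.OTHER) in MINED_CLASSES:
            bucket.add(stem)

    kept = [
        Transaction(key, frozenset(items))
        for key, items in visits.items()
        if len(items) >= 2
    ]
    kept.sort(key=lambda t: t.visit_key)
    omitted = len(visits) - len(kept)
    logger.info(
        "build_transactions: %d patient-days in, %d retained, %d omitted",
        len(visits), len(kept), omitted,
    )
    return TransactionSet(tuple(kept)), omitted


def parse_dose_freq(code: str) -> DoseSchedule:
    """Parse a dose/frequency code like ``1CAPAM`` / ``1TABBID`` / ``2TABPMSD``.

    Unparseable codes are never fatal: they yield a schedule with empty
    meals and the full code kept in ``modifier`` (and a logged warning), so
    the audit can continue on partial data.
    """
    m = _DOSE_RE.match(code)
    if m is None:
        logger.warning("unparseable dose/frequency code %r", code)
        return DoseSchedule(0, DoseUnit.OTHER, frozenset(), modifier=code)
    qty, unit, sched, residue = m.groups()
    meals = {
        "AM": frozenset({"morning"}),
        "PM": frozenset({"evening"}),
        "BID": frozenset({"morning", "evening"}),
    }[sched]
    return DoseSchedule(int(qty), DoseUnit(unit), meals, modifier=residue)


def schedules_overlap(a: DoseSchedule, b: DoseSchedule) -> bool:
    """True when two schedules share at least one meal slot."""
    return bool(a.meals & b.meals)


def _icd_key(code: str, frac_width: int = 4) -> tuple[str, int, str]:
    if not _ICD_RE.match(code):
        raise IcdCodeError(f"malformed ICD-10 code {code!r} (dot-stripped form expected)")
    return code[0], int(code[1:3]), code[3:].ljust(frac_width, "0")


def icd_in_ranges(code: str, ranges: Sequence[tuple[str, str]] = GI_RANGES) -> bool:
    """Test a dot-stripped ICD-10 code against inclusive dot-stripped ranges.

    ``K29.7`` is stored as ``K297``; its numeric part reads as 29.7, so it
    falls inside K20–K29.9 while K93.9 falls just above the K90–K93.8 bound.
    """
    key = _icd_key(code)
    for low, high in ranges:
        if _icd_key(low) <= key <= _icd_key(high):
            return True
    return False


# ---------------------------------------------------------------------------
# Tabular input / output


def read_prescriptions(path: str | Path) -> list[PrescriptionRow]:
    """Read ``prescriptions.csv`` (patient_id,date,drug_code,dose_freq,clinic)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        PrescriptionRow(
            patient_id=r.patient_id,
            date=_dt.date.fromisoformat(r.date),
            raw_code=r.drug_code,
            dose_freq_code=r.dose_freq,
            clinic_code=r.clinic,
        )
        for r in df.itertuples(index=False)
    ]


def build_contexts(
    rows: Sequence[PrescriptionRow],
    diagnoses: pd.DataFrame,
    patients: pd.DataFrame,
    aspirin_window_days: int = 0,
) -> dict[str, VisitContext]:
    """Join demographics, diagnoses and dose schedules onto each patient-day.

    ``diagnoses`` needs columns patient_id,date,icd10 (codes stored
    dot-stripped); ``patients`` needs patient_id,birth_date,sex.  A visit is
    aspirin-exposed when an aspirin stem is prescribed for the same patient
    within ``aspirin_window_days`` days of the visit (0 = same day).  Age is
    completed years at the visit date.
    """
    birth = {
        r.patient_id: _dt.date.fromisoformat(r.birth_date)
        for r in patients.itertuples(index=False)
    }
    sex = {r.patient_id: r.sex for r in patients.itertuples(index=False)}

    dx_by_visit: dict[str, set[str]] = {}
    for r in diagnoses.itertuples(index=False):
        code = str(r.icd10).replace(".", "")
        dx_by_visit.setdefault(make_visit_key(r.patient_id, str(r.date)), set()).add(code)

    aspirin_dates: dict[str, set[_dt.date]] = {}
    per_visit_rows: dict[str, list[PrescriptionRow]] = {}
    for row in rows:
        key = make_visit_key(row.patient_id, row.date)
        per_visit_rows.setdefault(key, []).append(row)
        if normalize_drug_code(row.raw_code) in ASPIRIN_STEMS:
            aspirin_dates.setdefault(row.patient_id, set()).add(row.date)

    contexts: dict[str, VisitContext] = {}
    for key, vrows in per_visit_rows.items():
        pid, date_s = key.split("|")
        date = _dt.date.fromisoformat(date_s)
        if pid not in birth:
            continue  # no demographics: context withheld, audit reports it
        b = birth[pid]
        age = date.year - b.year - ((date.month, date.day) < (b.month, b.day))
        window = _dt.timedelta(days=aspirin_window_days)
        aspirin = any(
            abs(d - date) <= window for d in aspirin_dates.get(pid, ())
        )
        per_drug = {
            normalize_drug_code(r.raw_code): (parse_dose_freq(r.dose_freq_code), r.clinic_code)
            for r in vrows
        }
        contexts[key] = VisitContext(
            visit_key=key,
            age_years=age,
            sex=str(sex[pid]),
            dx_codes=frozenset(dx_by_visit.get(key, set())),
            aspirin=aspirin,
            per_drug=per_drug,
        )
    return contexts


def write_contexts_csv(contexts: Mapping[str, VisitContext], path: str | Path) -> None:
    """Serialize visit contexts; dx codes ';'-joined, schedules ``STEM=CODE@CLINIC``."""
    rows = []
    for key in sorted(contexts):
        ctx = contexts[key]
        sched = "|".join(
            f"{stem}={_dose_code(ds)}@{clinic}"
            for stem, (ds, clinic) in sorted(ctx.per_drug.items())
        )
        rows.append({
            "visit_key": ctx.visit_key,
            "age_years": ctx.age_years,
            "sex": ctx.sex,
            "dx_codes": ";".join(sorted(ctx.dx_codes)),
            "aspirin": int(ctx.aspirin),
            "drug_schedules": sched,
        })
    pd.DataFrame(rows, columns=[
        "visit_key", "age_years", "sex", "dx_codes", "aspirin", "drug_schedules",
    ]).to_csv(path, index=False)


def _dose_code(ds: DoseSchedule) -> str:
    if ds.unit is DoseUnit.OTHER:
        return ds.modifier
    sched = {frozenset({"morning"}): "AM", frozenset({"evening"}): "PM",
             frozenset({"morning", "evening"}): "BID"}.get(ds.meals, "")
    return f"{ds.quantity}{ds.unit.value}{sched}{ds.modifier}"


def read_contexts_csv(path: str | Path) -> dict[str, VisitContext]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    contexts: dict[str, VisitContext] = {}
    for r in df.itertuples(index=False):
        per_drug = {}
        if r.drug_schedules:
            for part in r.drug_schedules.split("|"):
                stem, rest = part.split("=", 1)
                code, clinic = rest.rsplit("@", 1)
                per_drug[stem] = (parse_dose_freq(code), clinic)
        contexts[r.visit_key] = VisitContext(
            visit_key=r.visit_key,
            age_years=int(r.age_years),
            sex=r.sex,
            dx_codes=frozenset(c for c in r.dx_codes.split(";") if c),
            aspirin=bool(int(r.aspirin)),
            per_drug=per_drug,
        )
    return contexts


def write_transactions_jsonl(txns: TransactionSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in txns:
            fh.write(json.dumps({"visit_key": t.visit_key, "items": sorted(t.items)}) + "\n")


def read_transactions_jsonl(path: str | Path) -> TransactionSet:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                obj = json.loads(line)
                out.append(Transaction(obj["visit_key"], frozenset(obj["items"])))
    return TransactionSet(tuple(out))
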