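"""Guideline audit of flagged co-prescription patterns.

Two co-prescription patterns are screened:

* **H2RA + PPI** (ranitidine with a proton pump inhibitor): recommended only
  for gastro-oesophageal reflux disease (GORD, ICD-10 K21.x).  A visit is
  guideline-concordant exactly when a GORD diagnosis is recorded.
* **COX-2 inhibitor + PPI** (etoricoxib/celecoxib with a PPI): recommended
  only for patients at elevated gastrointestinal risk — age ≥ 60 years, a
  GI complication (ICD-10 K20–K29.9, K30–K38.9, K90–K93.8), or aspirin
  co-therapy.  A visit is discordant exactly when it meets none of the three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .arm import round_ratio
from .catalog import ASPIRIN_STEMS, COX2_STEMS, H2RA_STEMS, PPI_STEMS
from .etl import (
    GI_RANGES,
    TransactionSet,
    VisitContext,
    icd_in_ranges,
    schedules_overlap,
)

import logging

logger = logging.getLogger(__name__)

GORD_PREFIX = "K21"

H2RA_PPI = "H2RA_PPI"
COX2_PPI = "COX2_PPI"

CONCORDANT = "concordant"
DISCORDANT = "discordant"


@dataclass(frozen=True)
class AuditFinding:
    """One flagged visit with the per-criterion facts and the verdict."""

    visit_key: str
    pattern: str
    drugs: frozenset[str]
    criteria: Mapping[str, bool]
    verdict: str
    age_years: int | None = None
    dx_codes: frozenset[str] = frozenset()
    context_missing: bool = False


@dataclass(frozen=True)
class AuditSummary:
    """Category counts and 1-dp percents for one audited pattern.

    ``sections`` maps a partition name (e.g. ``"age"``) to ordered
    label→count pairs; ``percents`` mirrors it with 100·count/total rounded
    half-away-from-zero to one decimal.  Findings without context are
    excluded from ``total`` and reported in ``missing_context``.
    """

    pattern: str
    total: int
    sections: Mapping[str, Mapping[str, int]]
    percents: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    missing_context: int = 0


def _meal_clinic_flags(
    drugs_a: frozenset[str], drugs_b: frozenset[str], ctx: VisitContext
) -> tuple[bool, bool]:
    """Same-meal / same-clinic overlap between any drug of class a and b."""
    same_meal = same_clinic = False
    for a in drugs_a & ctx.per_drug.keys():
        sched_a, clinic_a = ctx.per_drug[a]
        for b in drugs_b & ctx.per_drug.keys():
            sched_b, clinic_b = ctx.per_drug[b]
            if schedules_overlap(sched_a, sched_b):
                same_meal = True
            if clinic_a == clinic_b and clinic_a != "":
                same_clinic = True
    return same_meal, same_clinic


def _missing_finding(visit_key: str, pattern: str, drugs: frozenset[str]) -> AuditFinding:
    logger.warning("no visit context for flagged visit %s", visit_key)
    return AuditFinding(visit_key, pattern, drugs, {}, DISCORDANT, context_missing=True)


def find_h2ra_ppi_visits(
    txns: TransactionSet, contexts: Mapping[str, VisitContext]
) -> list[AuditFinding]:
    """Audit every visit co-prescribing an H2RA and a PPI.

    Concordant iff a K21.x (GORD) diagnosis is present at the visit.
    Visits missing context are emitted flagged and default-discordant; the
    summary excludes them from percentage denominators.
    """
    findings = []
    for t in txns:
        h2ra = t.items & H2RA_STEMS
        ppi = t.items & PPI_STEMS
        if not (h2ra and ppi):
            continue
        drugs = frozenset(h2ra | ppi)
        ctx = contexts.get(t.visit_key)
        if ctx is None:
            findings.append(_missing_finding(t.visit_key, H2RA_PPI, drugs))
            continue
        gord = any(c.startswith(GORD_PREFIX) for c in ctx.dx_codes)
        same_meal, same_clinic = _meal_clinic_flags(h2ra, ppi, ctx)
        criteria = {
            "gord_dx": gord,
            "same_meal": same_meal,
            "same_clinic": same_clinic,
        }
        findings.append(
            AuditFinding(
                t.visit_key, H2RA_PPI, drugs, criteria,
                CONCORDANT if gord else DISCORDANT,
                age_years=ctx.age_years,
                dx_codes=ctx.dx_codes,
            )
        )
    return findings


def find_cox2_ppi_visits(
    txns: TransactionSet, contexts: Mapping[str, VisitContext]
) -> list[AuditFinding]:
    """Audit every visit co-prescribing a COX-2 inhibitor and a PPI.

    Discordant iff the patient is under 60 with no GI complication diagnosis
    and no aspirin exposure (same-visit aspirin stem or a caller-supplied
    co-therapy flag in the context).
    """
    findings = []
    for t in txns:
        cox2 = t.items & COX2_STEMS
        ppi = t.items & PPI_STEMS
        if not (cox2 and ppi):
            continue
        drugs = frozenset(cox2 | ppi)
        ctx = contexts.get(t.visit_key)
        if ctx is None:
            findings.append(_missing_finding(t.visit_key, COX2_PPI, drugs))
            continue
        age_ge_60 = ctx.age_years >= 60
        gi = any(icd_in_ranges(c, GI_RANGES) for c in ctx.dx_codes)
        aspirin = ctx.aspirin or bool(t.items & ASPIRIN_STEMS)
        same_meal, same_clinic = _meal_clinic_flags(cox2, ppi, ctx)
        criteria = {
            "age_ge_60": age_ge_60,
            "gi_complication": gi,
            "aspirin": aspirin,
            "same_meal": same_meal,
            "same_clinic": same_clinic,
        }
        discordant = not (age_ge_60 or gi or aspirin)
        findings.append(
            AuditFinding(
                t.visit_key, COX2_PPI, drugs, criteria,
                DISCORDANT if discordant else CONCORDANT,
                age_years=ctx.age_years,
                dx_codes=ctx.dx_codes,
            )
        )
    return findings


def _gi_dx_label(dx_codes: frozenset[str]) -> str:
    """Label a visit by one GI-related diagnosis (GORD codes first)."""
    gord = sorted(c for c in dx_codes if c.startswith(GORD_PREFIX))
    if gord:
        return gord[0]
    gi = sorted(c for c in dx_codes if c[0] == "K" and icd_in_ranges(c, GI_RANGES))
    return gi[0] if gi else "no GI diagnosis"


def summarize_audit(findings: Sequence[AuditFinding], pattern: str) -> AuditSummary:
    """Partition the findings of one pattern into the report categories.

    For COX2_PPI: age bands (≥60 / 50–59 / <50), GI complication yes/no,
    aspirin yes/no, and the joint discordance category.  For H2RA_PPI:
    GORD vs non-GORD plus a per-diagnosis frequency breakdown.
    """
    if any(f.pattern != pattern for f in findings):
        raise ValueError("summarize_audit: findings of mixed patterns")
    valid = [f for f in findings if not f.context_missing]
    missing = len(findings) - len(valid)
    total = len(valid)
    sections: dict[str, dict[str, int]] = {}

    if pattern == COX2_PPI:
        age: dict[str, int] = {">=60": 0, "50-59": 0, "<50": 0}
        for f in valid:
            assert f.age_years is not None
            if f.age_years >= 60:
                age[">=60"] += 1
            elif f.age_years >= 50:
                age["50-59"] += 1
            else:
                age["<50"] += 1
        sections["age"] = age
        sections["gi_complication"] = {
            "yes": sum(f.criteria["gi_complication"] for f in valid),
            "no": sum(not f.criteria["gi_complication"] for f in valid),
        }
        sections["aspirin"] = {
            "yes": sum(f.criteria["aspirin"] for f in valid),
            "no": sum(not f.criteria["aspirin"] for f in valid),
        }
        sections["discordant"] = {
            "yes": sum(f.verdict == DISCORDANT for f in valid),
            "no": sum(f.verdict != DISCORDANT for f in valid),
        }
    elif pattern == H2RA_PPI:
        sections["gord"] = {
            "GORD": sum(f.criteria["gord_dx"] for f in valid),
            "non-GORD": sum(not f.criteria["gord_dx"] for f in valid),
        }
        dx: dict[str, int] = {}
        for f in valid:
            label = _gi_dx_label(f.dx_codes)
            dx[label] = dx.get(label, 0) + 1
        if dx:
            sections["diagnosis"] = dict(
                sorted(dx.items(), key=lambda kv: (-kv[1], kv[0]))
            )
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    percents = {
        name: {
            label: round_ratio(100 * count, total, 1) if total else 0.0
            for label, count in cats.items()
        }
        for name, cats in sections.items()
        if total
    }
    return AuditSummary(pattern, total, sections, percents, missing_context=missing)
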