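"""Synthetic outpatient cohorts and deterministic reconstruction fixtures.

The hospital records behind the published analysis are not shareable, so
this module provides two substitutes:

* a **stochastic cohort generator** emulating the study's data sources —
  per-visit drug sets with tunable pairwise co-prescription structure
  (the configured boost of a pair is, by construction, the expected lift of
  the corresponding mined rule), diagnosis codes correlated with
  gastro-protective prescribing, and demographics matching the study's
  printed descriptives (mean age 48.4 ± 21.4 years, 34% male,
  4.7 ± 4.4 visits/person/year);

* **deterministic fixtures** that reconstruct printed rule statistics and
  audit tables exactly: an integer-count inversion oracle recovers the
  transaction counts behind a rounded support/confidence pair, and block
  designs realise those counts as concrete transaction sets.

All randomness flows through a single integer seed; identical parameters
and seed give byte-identical output files.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .arm import round_ratio
from .catalog import PPI_STEMS, raw_code_for_stem
from .etl import Transaction, TransactionSet, make_visit_key, parse_dose_freq, VisitContext


class ParameterError(ValueError):
    """Cohort parameters imply an invalid joint distribution."""


class InversionError(ValueError):
    """No integer counts reproduce the printed rounded statistics."""

    def __init__(self, message: str, nearest: "PairCounts | None" = None):
        super().__init__(message)
        self.nearest = nearest


class FixtureError(ValueError):
    """A requested fixture is internally inconsistent or infeasible."""


# ---------------------------------------------------------------------------
# Integer-count inversion of printed rule statistics


@dataclass(frozen=True)
class PairCounts:
    """Integer transaction counts behind a two-item rule X → Y."""

    n: int
    count_x: int
    count_y: int
    count_xy: int

    def __post_init__(self) -> None:
        if self.count_xy > min(self.count_x, self.count_y):
            raise ValueError("joint count exceeds a marginal count")
        if self.count_x + self.count_y - self.count_xy > self.n:
            raise ValueError("union of X and Y exceeds n")


def invert_printed_rule(
    support_4dp: float,
    confidence_fwd_4dp: float | None = None,
    confidence_rev_4dp: float | None = None,
    *,
    n: int,
    decimals: int = 4,
) -> list[PairCounts]:
    """Recover integer counts whose exact ratios round to printed statistics.

    Exhaustively searches joint counts in [0, n] for those rounding
    (half-away-from-zero, ``decimals`` places) to the printed support; when
    forward/reverse confidences are given, antecedent/consequent totals are
    searched the same way.  Returns every consistent solution; raises
    :class:`InversionError` carrying the nearest miss when none exists —
    rounded published tables are not always internally consistent.
    """
    joint_candidates = [
        c for c in range(n + 1) if round_ratio(c, n, decimals) == support_4dp
    ]
    if not joint_candidates:
        nearest_joint = min(range(n + 1), key=lambda c: abs(c / n - support_4dp))
        raise InversionError(
            f"no integer joint count in [0, {n}] rounds to support "
            f"{support_4dp}; nearest is {nearest_joint} "
            f"({nearest_joint / n:.5f})",
            nearest=_nearest_counts(nearest_joint, confidence_fwd_4dp,
                                    confidence_rev_4dp, n),
        )

    solutions: list[PairCounts] = []
    near: PairCounts | None = None
    for cxy in joint_candidates:
        xs = _marginal_candidates(cxy, confidence_fwd_4dp, n, decimals)
        ys = _marginal_candidates(cxy, confidence_rev_4dp, n, decimals)
        if not xs or not ys:
            near = near or _nearest_counts(cxy, confidence_fwd_4dp,
                                           confidence_rev_4dp, n)
            continue
        for cx in xs:
            for cy in ys:
                if cx + cy - cxy <= n:
                    solutions.append(PairCounts(n, cx, cy, cxy))
    if not solutions:
        raise InversionError(
            f"support {support_4dp} admits joint counts {joint_candidates} but "
            "no marginal count reproduces the printed confidence",
            nearest=near,
        )
    return solutions


def _marginal_candidates(
    cxy: int, confidence_4dp: float | None, n: int, decimals: int = 4
) -> list[int]:
    if confidence_4dp is None:
        return [cxy]  # no constraint: smallest valid marginal
    if cxy == 0:
        return []
    return [
        cm for cm in range(max(cxy, 1), n + 1)
        if round_ratio(cxy, cm, decimals) == confidence_4dp
    ]


def _nearest_counts(
    cxy: int, conf_fwd: float | None, conf_rev: float | None, n: int
) -> PairCounts:
    def nearest_marginal(conf: float | None) -> int:
        if conf is None or cxy == 0:
            return cxy
        return min(range(max(cxy, 1), n + 1), key=lambda cm: abs(cxy / cm - conf))

    cx, cy = nearest_marginal(conf_fwd), nearest_marginal(conf_rev)
    if cx + cy - cxy > n:
        cy = n - cx + cxy
    return PairCounts(n, cx, cy, cxy)


# ---------------------------------------------------------------------------
# Deterministic block-design fixtures


class _FillerPool:
    """Inert filler items, each used fewer than ``cap`` times so no filler
    can reach the mining support threshold."""

    def __init__(self, cap: int):
        if cap < 1:
            raise FixtureError("filler cap below 1: fixture infeasible")
        self.cap = cap
        self._idx = 0
        self._used = 0

    def next(self) -> str:
        if self._used >= self.cap:
            self._idx += 1
            self._used = 0
        self._used += 1
        return f"FIL{self._idx:03d}"


def make_pair_fixture(
    counts: PairCounts, x: str, y: str, min_support: float = 0.01
) -> TransactionSet:
    """Realise exact pair counts as a transaction set of two-item visits.

    Emits ``count_xy`` transactions {x, y}, ``count_x − count_xy`` of
    {x, filler}, ``count_y − count_xy`` of {y, filler}, then inert filler
    pairs up to ``n``.  Every filler item stays strictly below the support
    threshold, so mining at ``min_support`` sees exactly the x/y structure.
    (When n·min_support ≤ 1 no count can sit below the threshold; fillers
    are then single-use, the closest feasible design.)
    """
    cap = max(1, int(np.ceil(min_support * counts.n)) - 1)
    pool = _FillerPool(cap)
    txns: list[frozenset[str]] = []
    txns += [frozenset({x, y})] * counts.count_xy
    txns += [frozenset({x, pool.next()}) for _ in range(counts.count_x - counts.count_xy)]
    txns += [frozenset({y, pool.next()}) for _ in range(counts.count_y - counts.count_xy)]
    remaining = counts.n - len(txns)
    for _ in range(remaining):
        txns.append(frozenset({f"A{pool.next()}", f"B{pool.next()}"}))
    return TransactionSet(tuple(
        Transaction(f"F{i:06d}|fixture", items) for i, items in enumerate(txns)
    ))


#: Antecedent stems of the published demonstration's NSAID/antacid→PPI rules.
TABLE2_ANTECEDENTS = (
    "NAPX", "MELO", "IBUP", "DICF", "ASPT", "ASA.", "CELB", "MOBC", "ARCX", "ANTC",
)


def make_table2_fixture() -> TransactionSet:
    """Deterministic 6,168-transaction block design yielding exactly 12 rules.

    Blocks: 2,600 × {OMPZ, XAND}; per antecedent stem 70 × {stem, OMPZ} and
    50 × {stem, filler}; 2,000 × {XAND, filler}; 368 filler-only pairs.
    Every filler item occurs fewer than 62 times (< 1% of 6,168), so at
    support ≥ 1% and confidence ≥ 50% the only surviving single-item rules
    are OMPZ↔XAND plus the ten stem→OMPZ rules: 12 in all.
    """
    pool = _FillerPool(61)
    txns: list[frozenset[str]] = []
    txns += [frozenset({"OMPZ", "XAND"})] * 2600
    for stem in TABLE2_ANTECEDENTS:
        txns += [frozenset({stem, "OMPZ"})] * 70
        txns += [frozenset({stem, pool.next()}) for _ in range(50)]
    txns += [frozenset({"XAND", pool.next()}) for _ in range(2000)]
    txns += [frozenset({f"A{pool.next()}", f"B{pool.next()}"}) for _ in range(368)]
    assert len(txns) == 6168
    return TransactionSet(tuple(
        Transaction(f"T{i:06d}|fixture", items) for i, items in enumerate(txns)
    ))


# ---------------------------------------------------------------------------
# Audit fixtures (diagnosis / demographic reconstruction)

_FIXTURE_DATE = "2014-06-15"
_FIXTURE_CLINIC = "ORP11"


def h2ra_audit_spec() -> list[tuple[int, str | None]]:
    """Published diagnosis breakdown of the 340 H2RA+PPI visits:
    (count, dot-stripped ICD-10 code or None for no GI diagnosis)."""
    return [
        (221, "K219"), (1, "K210"), (38, "K30"), (9, "K279"), (5, "K297"),
        (2, "K922"), (1, "K921"), (1, "K319"), (1, "K254"), (1, "K259"),
        (1, "K20"), (59, None),
    ]


def cox2_audit_spec() -> list[tuple[int, int, bool, bool]]:
    """A joint (count, age, GI dx, aspirin) layout consistent with the
    published 828-visit category table: 498/233/97 by age band, 141 GI
    complications, 11 aspirin-exposed, 295 jointly discordant."""
    return [
        (11, 65, False, True),
        (106, 65, True, False),
        (381, 65, False, False),
        (25, 55, True, False),
        (208, 55, False, False),
        (10, 45, True, False),
        (87, 45, False, False),
    ]


def make_audit_fixture(
    pattern: str,
    spec: list[tuple] | None = None,
) -> tuple[TransactionSet, dict[str, VisitContext]]:
    """Deterministic visits with exactly the requested audit attributes.

    ``pattern`` is ``"H2RA_PPI"`` (spec rows ``(count, dx_code_or_None)``,
    default :func:`h2ra_audit_spec`) or ``"COX2_PPI"`` (rows
    ``(count, age_years, gi_dx, aspirin)``, default :func:`cox2_audit_spec`).
    """
    txns: list[Transaction] = []
    contexts: dict[str, VisitContext] = {}
    i = 0

    def add_visit(items: frozenset[str], age: int, dx: frozenset[str], aspirin: bool):
        nonlocal i
        key = make_visit_key(f"AUD{i:05d}", _FIXTURE_DATE)
        i += 1
        per_drug = {
            stem: (
                parse_dose_freq("1CAPAM" if stem in PPI_STEMS else "1TABBID"),
                _FIXTURE_CLINIC,
            )
            for stem in items
        }
        txns.append(Transaction(key, items))
        contexts[key] = VisitContext(key, age, "female", dx, aspirin, per_drug)

    if pattern == "H2RA_PPI":
        rows = spec if spec is not None else h2ra_audit_spec()
        for count, dx_code in rows:
            if count < 0:
                raise FixtureError("negative category count")
            dx = frozenset() if dx_code is None else frozenset({dx_code})
            for _ in range(count):
                add_visit(frozenset({"OMPZ", "XAND"}), 50, dx, False)
    elif pattern == "COX2_PPI":
        rows = spec if spec is not None else cox2_audit_spec()
        for count, age, gi, aspirin in rows:
            if count < 0 or age < 0:
                raise FixtureError("invalid category cell")
            dx = frozenset({"K297"}) if gi else frozenset()
            for _ in range(count):
                add_visit(frozenset({"CELB", "OMPZ"}), age, dx, aspirin)
    else:
        raise FixtureError(f"unknown audit fixture pattern {pattern!r}")
    return TransactionSet(tuple(txns)), contexts


# ---------------------------------------------------------------------------
# Stochastic cohort generation

#: Default per-visit prescription probabilities over the study stems.
DEFAULT_PREVALENCE: dict[str, float] = {
    "OMPZ": 0.10, "XAND": 0.05, "ANTC": 0.02, "ALHY": 0.015, "GAVD": 0.01,
    "NAPX": 0.02, "IBUP": 0.02, "DICF": 0.015, "MELO": 0.015, "MEFN": 0.01,
    "ASPT": 0.015, "ASA.": 0.03, "CELB": 0.02, "ARCX": 0.02, "NEXM": 0.015,
    "COTL": 0.01, "PRVF": 0.01,
}

_GI_DX_CODES = ("K219", "K30", "K297", "K279", "K259")
_CLINICS = ("ORP11", "PMD02", "OGY11", "OPS01", "PET01")


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for a synthetic outpatient cohort.

    Demographic defaults follow the study population the pipeline is
    designed for: mean age 48.4 (SD 21.4) years, 34% male, 4.7 (SD 4.4)
    outpatient visits per person-year, 1.8% background GI-complication and
    0.74% arthritis coding rates.  ``pair_boost[(x, y)] = b`` multiplies the
    joint prescription probability of stems x and y to b·P(x)·P(y), making
    b the expected mined lift of x→y.
    """

    n_patients: int = 1000
    mean_visits_per_year: float = 4.7
    visit_rate_sd: float = 4.4
    male_fraction: float = 0.34
    age_mean: float = 48.4
    age_sd: float = 21.4
    drug_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    pair_boost: dict[tuple[str, str], float] = field(default_factory=dict)
    gi_dx_prob_given_ppi: float = 0.30
    background_gi_dx_prob: float = 0.018
    arthritis_dx_prob: float = 0.0074
    years: int = 2
    seed: int = 0

    def validate(self) -> None:
        for stem, p in self.drug_prevalence.items():
            if not 0 <= p <= 1:
                raise ParameterError(f"prevalence of {stem} outside [0, 1]")
        for p in (self.male_fraction, self.gi_dx_prob_given_ppi,
                  self.background_gi_dx_prob, self.arthritis_dx_prob):
            if not 0 <= p <= 1:
                raise ParameterError("probability parameter outside [0, 1]")
        seen: set[str] = set()
        for (x, y), b in self.pair_boost.items():
            if b < 0:
                raise ParameterError(f"negative boost for pair ({x}, {y})")
            if x == y or {x, y} & seen:
                raise ParameterError(
                    "boosted pairs must be disjoint (sequential sampling "
                    f"cannot honour overlapping pairs; offending pair ({x}, {y}))"
                )
            seen |= {x, y}
            px = self.drug_prevalence.get(x)
            py = self.drug_prevalence.get(y)
            if px is None or py is None:
                raise ParameterError(f"boosted pair ({x}, {y}) not in prevalence map")
            joint = b * px * py
            if joint > min(px, py) or (py - joint) / (1 - px) > 1:
                raise ParameterError(
                    f"boost {b} for ({x}, {y}) implies joint probability "
                    f"{joint:.4f} exceeding a marginal"
                )


def sample_visit_itemsets(
    params: CohortParams, n_visits: int, rng: np.random.Generator
) -> list[set[str]]:
    """Draw per-visit drug sets: independent Bernoulli inclusion per stem,
    except boosted pairs, sampled sequentially so that the pair's joint
    probability is exactly boost × product of marginals."""
    params.validate()
    stems = sorted(params.drug_prevalence)
    boosted: dict[str, tuple[str, float]] = {}
    for (x, y), b in params.pair_boost.items():
        boosted[x] = (y, b)

    cols: dict[str, np.ndarray] = {}
    for stem in stems:
        if stem in cols:
            continue
        px = params.drug_prevalence[stem]
        if stem in boosted:
            y, b = boosted[stem]
            py = params.drug_prevalence[y]
            joint = b * px * py
            has_x = rng.random(n_visits) < px
            p_y = np.where(has_x, joint / px if px else 0.0,
                           (py - joint) / (1 - px) if px < 1 else 0.0)
            cols[stem] = has_x
            cols[y] = rng.random(n_visits) < p_y
        else:
            cols[stem] = rng.random(n_visits) < px
    matrix = np.column_stack([cols[s] for s in stems])
    return [set(np.array(stems)[row]) for row in matrix]


def _visits_per_patient(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """Per-patient visit totals: negative binomial matching the target
    per-year mean and SD (overdispersed, as outpatient utilisation is)."""
    mean, var = params.mean_visits_per_year, params.visit_rate_sd**2
    if var <= mean:  # fall back to Poisson when not overdispersed
        per_year = rng.poisson(mean, size=(params.n_patients, params.years))
    else:
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        per_year = rng.negative_binomial(r, p, size=(params.n_patients, params.years))
    return per_year.sum(axis=1)


def generate_cohort(
    params: CohortParams, out_dir: str | Path
) -> dict[str, Path]:
    """Write ``prescriptions.csv``, ``diagnoses.csv`` and ``patients.csv``.

    Fully reproducible: the same parameters and seed yield byte-identical
    files.  Ages are truncated-normal (≥ 0); visit dates fall uniformly in
    a two-year window; drug sets come from :func:`sample_visit_itemsets`;
    GI / GORD diagnosis codes attach with elevated probability when a PPI
    is prescribed at the visit.
    """
    params.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    n = params.n_patients
    pids = [f"P{i:06d}" for i in range(n)]
    a = (0 - params.age_mean) / params.age_sd
    ages = stats.truncnorm.rvs(a, np.inf, loc=params.age_mean,
                               scale=params.age_sd, size=n, random_state=rng)
    sexes = np.where(rng.random(n) < params.male_fraction, "male", "female")
    ref = _dt.date(2014, 10, 1)
    births = [ref - _dt.timedelta(days=float(age) * 365.25) for age in ages]

    visit_counts = _visits_per_patient(params, rng)
    window_days = 365 * params.years
    start = _dt.date(2013, 10, 1)

    visit_pid: list[str] = []
    visit_date: list[_dt.date] = []
    for pid, k in zip(pids, visit_counts):
        offsets = sorted(set(rng.integers(0, window_days, size=int(k)).tolist()))
        for off in offsets:  # same patient-day collapses to one visit
            visit_pid.append(pid)
            visit_date.append(start + _dt.timedelta(days=off))

    itemsets = sample_visit_itemsets(params, len(visit_pid), rng)

    rx_rows, dx_rows = [], []
    for pid, date, items in zip(visit_pid, visit_date, itemsets):
        clinic = _CLINICS[int(rng.integers(0, len(_CLINICS)))]
        for stem in sorted(items):
            rx_rows.append((
                pid, date.isoformat(), raw_code_for_stem(stem),
                "1CAPAM" if stem in PPI_STEMS else "1TABBID", clinic,
            ))
        p_gi = (params.gi_dx_prob_given_ppi if items & PPI_STEMS
                else params.background_gi_dx_prob)
        if rng.random() < p_gi:
            code = _GI_DX_CODES[int(rng.integers(0, len(_GI_DX_CODES)))]
            dx_rows.append((pid, date.isoformat(), code))
        if rng.random() < params.arthritis_dx_prob:
            dx_rows.append((pid, date.isoformat(), "M139"))

    paths = {
        "prescriptions": out_dir / "prescriptions.csv",
        "diagnoses": out_dir / "diagnoses.csv",
        "patients": out_dir / "patients.csv",
    }
    pd.DataFrame(
        rx_rows, columns=["patient_id", "date", "drug_code", "dose_freq", "clinic"]
    ).sort_values(["patient_id", "date", "drug_code"], kind="stable").to_csv(
        paths["prescriptions"], index=False)
    pd.DataFrame(
        dx_rows, columns=["patient_id", "date", "icd10"]
    ).sort_values(["patient_id", "date", "icd10"], kind="stable").to_csv(
        paths["diagnoses"], index=False)
    pd.DataFrame(
        {"patient_id": pids,
         "birth_date": [b.isoformat() for b in births],
         "sex": sexes}
    ).to_csv(paths["patients"], index=False)
    return paths
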