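"""Prescription normalization, visit grouping, dose parsing, ICD-10 ranges."""

import datetime as dt
import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxaudit.catalog import AtcClass, classify_atc, load_catalog
from rxaudit.etl import (
    GI_RANGES,
    DoseUnit,
    IcdCodeError,
    InvalidDrugCodeError,
    PrescriptionRow,
    build_contexts,
    build_transactions,
    icd_in_ranges,
    normalize_drug_code,
    parse_dose_freq,
    read_contexts_csv,
    read_transactions_jsonl,
    schedules_overlap,
    write_contexts_csv,
    write_transactions_jsonl,
)
from tests.conftest import make_txns


def rows(*specs):
    return [
        PrescriptionRow(pid, dt.date.fromisoformat(d), code)
        for pid, d, code in specs
    ]


class TestNormalizeDrugCode:
    @pytest.mark.parametrize(
        "raw,stem",
        [("IBUP1T-", "IBUP"), ("IBUP-S-", "IBUP"), ("OMPZ-C-", "OMPZ"),
         ("ASA.1T-", "ASA."), ("XAND", "XAND")],
    )
    def test_first_four_characters(self, raw, stem):
        assert normalize_drug_code(raw) == stem

    def test_idempotent_on_own_output(self):
        for raw in ("IBUP1T-", "MELO-T-", "ARCX4T-"):
            stem = normalize_drug_code(raw)
            assert normalize_drug_code(stem) == stem

    def test_short_code_raises_naming_the_code(self):
        with pytest.raises(InvalidDrugCodeError, match="'OMP'"):
            normalize_drug_code("OMP")


class TestClassifyAtc:
    @pytest.mark.parametrize(
        "stem,expected",
        [("ARCX", AtcClass.M01A_COX2), ("XAND", AtcClass.A02B),
         ("OMPZ", AtcClass.A02B), ("ANTC", AtcClass.A02A),
         ("NAPX", AtcClass.M01A_CONVENTIONAL), ("MOBC", AtcClass.M01A_CONVENTIONAL),
         ("ZZZZ", AtcClass.OTHER)],
    )
    def test_catalog_classes(self, stem, expected):
        assert classify_atc(stem) is expected

    def test_catalog_stems_are_code_prefixes(self):
        for entry in load_catalog():
            assert entry.stem == entry.raw_code[:4]
            assert len(entry.stem) == 4


class TestBuildTransactions:
    def test_groups_dedupes_and_filters(self):
        data = rows(
            ("p1", "2014-01-01", "OMPZ-C-"),
            ("p1", "2014-01-01", "XAND-T-"),
            ("p1", "2014-01-01", "NAPX-T-"),
            ("p2", "2014-01-01", "IBUP1T-"),   # single stem: omitted
            ("p3", "2014-01-01", "IBUP1T-"),   # two codes, same stem: omitted
            ("p3", "2014-01-01", "IBUP2T-"),
        )
        txns, omitted = build_transactions(data)
        assert txns.n == 1 and omitted == 2
        assert txns.transactions[0].items == frozenset({"OMPZ", "XAND", "NAPX"})
        assert txns.transactions[0].visit_key == "p1|2014-01-01"

    def test_off_catalog_drugs_do_not_make_a_visit_multidrug(self):
        data = rows(("p1", "2014-01-01", "OMPZ-C-"),
                    ("p1", "2014-01-01", "ZZZZ-X-"))
        txns, omitted = build_transactions(data)
        assert txns.n == 0 and omitted == 1

    def test_conservation_and_order_invariance(self):
        random.seed(4)
        data = []
        for i in range(300):
            pid = f"p{random.randrange(60)}"
            day = f"2014-02-{random.randrange(1, 28):02d}"
            code = random.choice(
                ["OMPZ-C-", "XAND-T-", "NAPX-T-", "IBUP1T-", "ZZZZ-X-"])
            data.append(rows((pid, day, code))[0])
        txns, omitted = build_transactions(data)
        distinct_days = len({(r.patient_id, r.date) for r in data})
        assert txns.n + omitted == distinct_days
        shuffled = data[:]
        random.shuffle(shuffled)
        txns2, omitted2 = build_transactions(shuffled)
        assert txns2 == txns and omitted2 == omitted

    def test_empty_input(self):
        txns, omitted = build_transactions([])
        assert txns.n == 0 and omitted == 0


class TestDoseSchedules:
    @pytest.mark.parametrize(
        "code,qty,unit,meals,modifier",
        [
            ("1CAPAM", 1, DoseUnit.CAP, {"morning"}, ""),
            ("1TABBID", 1, DoseUnit.TAB, {"morning", "evening"}, ""),
            ("2TABPMSD", 2, DoseUnit.TAB, {"evening"}, "SD"),
            ("1CAPAMSD", 1, DoseUnit.CAP, {"morning"}, "SD"),
        ],
    )
    def test_parse(self, code, qty, unit, meals, modifier):
        ds = parse_dose_freq(code)
        assert (ds.quantity, ds.unit, set(ds.meals), ds.modifier) == (
            qty, unit, meals, modifier)

    def test_unparseable_is_nonfatal(self):
        ds = parse_dose_freq("PRN-STAT")
        assert ds.meals == frozenset() and ds.modifier == "PRN-STAT"

    @pytest.mark.parametrize(
        "a,b,expected",
        [("1CAPAM", "1TABBID", True), ("1CAPAM", "2TABPMSD", False),
         ("1CAPBID", "1TABBID", True), ("PRN", "1TABBID", False)],
    )
    def test_overlap(self, a, b, expected):
        assert schedules_overlap(parse_dose_freq(a), parse_dose_freq(b)) is expected


class TestIcdRanges:
    @pytest.mark.parametrize(
        "code,inside",
        [("K297", True), ("K40", False), ("K939", False), ("K20", True),
         ("K299", True), ("K30", True), ("K389", True), ("K39", False),
         ("K90", True), ("K938", True), ("K254", True), ("K21", True),
         ("A20", False)],
    )
    def test_gi_membership(self, code, inside):
        assert icd_in_ranges(code, GI_RANGES) is inside

    def test_malformed_code(self):
        with pytest.raises(IcdCodeError):
            icd_in_ranges("297", GI_RANGES)

    def test_agrees_with_lexicographic_brute_force(self):
        # within one letter and 2-digit-major codes, dot-stripped ICD-10
        # order is plain string order; enumerate every K000-K999
        def brute(code):
            return any(low <= code <= high for low, high in GI_RANGES)

        for i in range(1000):
            code = f"K{i:03d}"
            assert icd_in_ranges(code, GI_RANGES) is brute(code), code


class TestContexts:
    def test_age_is_completed_years_and_dx_joined(self):
        data = [PrescriptionRow("p1", dt.date(2014, 6, 1), "OMPZ-C-",
                                "1CAPAM", "ORP11")]
        dx = pd.DataFrame({"patient_id": ["p1"], "date": ["2014-06-01"],
                           "icd10": ["K21.9"]})
        patients = pd.DataFrame({"patient_id": ["p1"],
                                 "birth_date": ["1954-06-02"],
                                 "sex": ["female"]})
        ctx = build_contexts(data, dx, patients)["p1|2014-06-01"]
        assert ctx.age_years == 59  # birthday is tomorrow
        assert ctx.dx_codes == frozenset({"K219"})  # dot-stripped
        assert ctx.per_drug["OMPZ"][1] == "ORP11"

    def test_aspirin_window(self):
        data = [
            PrescriptionRow("p1", dt.date(2014, 6, 1), "OMPZ-C-"),
            PrescriptionRow("p1", dt.date(2014, 6, 3), "ASA.1T-"),
        ]
        patients = pd.DataFrame({"patient_id": ["p1"],
                                 "birth_date": ["1950-01-01"], "sex": ["male"]})
        dx = pd.DataFrame(columns=["patient_id", "date", "icd10"])
        same_day = build_contexts(data, dx, patients, aspirin_window_days=0)
        windowed = build_contexts(data, dx, patients, aspirin_window_days=3)
        assert not same_day["p1|2014-06-01"].aspirin
        assert windowed["p1|2014-06-01"].aspirin

    def test_missing_demographics_gives_no_context(self):
        data = [PrescriptionRow("ghost", dt.date(2014, 6, 1), "OMPZ-C-")]
        patients = pd.DataFrame(columns=["patient_id", "birth_date", "sex"])
        dx = pd.DataFrame(columns=["patient_id", "date", "icd10"])
        assert build_contexts(data, dx, patients) == {}


class TestRoundTrips:
    def test_transactions_jsonl(self, tmp_path):
        txns = make_txns([{"OMPZ", "XAND"}, {"NAPX", "OMPZ", "ANTC"}])
        path = tmp_path / "t.jsonl"
        write_transactions_jsonl(txns, path)
        assert read_transactions_jsonl(path) == txns

    def test_contexts_csv(self, tmp_path):
        data = [PrescriptionRow("p1", dt.date(2014, 6, 1), "OMPZ-C-",
                                "1CAPAMSD", "ORP11"),
                PrescriptionRow("p1", dt.date(2014, 6, 1), "XAND-T-",
                                "1TABBID", "PMD02")]
        dx = pd.DataFrame({"patient_id": ["p1"], "date": ["2014-06-01"],
                           "icd10": ["K30"]})
        patients = pd.DataFrame({"patient_id": ["p1"],
                                 "birth_date": ["1960-01-01"], "sex": ["male"]})
        contexts = build_contexts(data, dx, patients)
        path = tmp_path / "c.csv"
        write_contexts_csv(contexts, path)
        back = read_contexts_csv(path)
        assert back == contexts


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(
    st.sampled_from(["p1", "p2", "p3"]),
    st.sampled_from(["2014-01-01", "2014-01-02"]),
    st.sampled_from(["OMPZ-C-", "XAND-T-", "NAPX-T-", "IBUP1T-", "IBUP2T-"]),
), max_size=30))
def test_filter_conservation_property(specs):
    """Retained + omitted always equals distinct patient-days, and every
    retained transaction has at least two distinct stems."""
    data = rows(*specs)
    txns, omitted = build_transactions(data)
    assert txns.n + omitted == len({(r.patient_id, r.date) for r in data})
    assert all(len(t.items) >= 2 for t in txns)
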