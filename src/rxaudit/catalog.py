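"""Hospital drug catalog: raw code → 4-character stem → ATC class.

The packaged catalog reproduces the hospital's master drug list for the
three drug classes under study: antacids (ATC A02A), peptic-ulcer / GORD
drugs (A02B, which contains both the H2-receptor antagonist ranitidine and
all proton pump inhibitors), and NSAIDs (M01A, split here into conventional
agents and the selective COX-2 inhibitors M01AH). Hospital drug codes encode
strength and form in their tail (e.g. ``IBUP1T-`` 200 mg tablet, ``IBUP-S-``
syrup); the 4-character stem identifies the compound itself.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass
from functools import lru_cache


class AtcClass(str, enum.Enum):
    """Drug class of a catalog stem; ``OTHER`` for anything off-catalog."""

    A02A = "A02A"
    A02B = "A02B"
    M01A_CONVENTIONAL = "M01A_conventional"
    M01A_COX2 = "M01A_cox2"
    OTHER = "other"


#: Classes retained when building transactions for rule mining.
MINED_CLASSES = frozenset(
    {AtcClass.A02A, AtcClass.A02B, AtcClass.M01A_CONVENTIONAL, AtcClass.M01A_COX2}
)

#: Stems of gastro-protective H2-receptor antagonists (ranitidine).
H2RA_STEMS = frozenset({"XAND"})
#: Stems of proton pump inhibitors.
PPI_STEMS = frozenset({"COTL", "DEXI", "LOSC", "NEXM", "OMPZ", "PARI", "PRVF"})
#: Stems of selective COX-2 inhibitors (etoricoxib, celecoxib).
COX2_STEMS = frozenset({"ARCX", "CELB"})
#: Stems of acetylsalicylic acid products counted as aspirin co-therapy.
ASPIRIN_STEMS = frozenset({"ASPT", "ASA.", "CAPN"})


@dataclass(frozen=True)
class DrugEntry:
    """One catalog record.

    ``stem`` is always the first 4 characters of ``raw_code``; one compound
    may appear under several raw codes (different strengths/forms) that all
    share a stem.
    """

    raw_code: str
    stem: str
    generic_name: str
    atc_class: AtcClass

    def __post_init__(self) -> None:
        if len(self.stem) != 4 or self.raw_code[:4] != self.stem:
            raise ValueError(
                f"catalog entry {self.raw_code!r}: stem {self.stem!r} must be "
                "its first 4 characters"
            )


@lru_cache(maxsize=1)
def load_catalog() -> tuple[DrugEntry, ...]:
    """Load the packaged drug catalog (immutable, cached)."""
    text = (
        importlib.resources.files("rxaudit.data")
        .joinpath("table1_catalog.csv")
        .read_text(encoding="utf-8")
    )
    entries = []
    lines = text.strip().splitlines()
    for line in lines[1:]:  # header: raw_code,stem,generic_name,atc_class
        raw_code, stem, name, atc = line.split(",")
        entries.append(DrugEntry(raw_code, stem, name, AtcClass(atc)))
    return tuple(entries)


def classify_atc(stem: str, catalog: tuple[DrugEntry, ...] | None = None) -> AtcClass:
    """Return the ATC class of the first catalog entry matching ``stem``.

    Unknown stems classify as :attr:`AtcClass.OTHER`; this is never an error
    because real prescription extracts contain drugs outside the study scope.
    """
    for entry in catalog if catalog is not None else load_catalog():
        if entry.stem == stem:
            return entry.atc_class
    return AtcClass.OTHER


def stems_for_class(atc_class: AtcClass) -> frozenset[str]:
    """All catalog stems belonging to one ATC class."""
    return frozenset(e.stem for e in load_catalog() if e.atc_class == atc_class)


def raw_code_for_stem(stem: str) -> str:
    """A representative raw code for a stem (first catalog occurrence)."""
    for entry in load_catalog():
        if entry.stem == stem:
            return entry.raw_code
    raise KeyError(f"stem {stem!r} not in catalog")
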