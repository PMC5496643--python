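"""Association rule mining on prescription transactions.

Level-wise Apriori frequent-itemset search with the three classical rule
statistics.  With transactions P = {P1..Pn} (each a set of drug stems) and
disjoint itemsets X (antecedent) and Y (consequent):

    support(X→Y)    = P(X ∪ Y)            joint frequency of both sets
    confidence(X→Y) = P(Y | X)            conditional frequency
    lift(X→Y)       = P(X,Y) / P(X)·P(Y)  1 = independence, >1 positive

All statistics are kept as exact integer counts internally; rounding
(half-away-from-zero, 4 decimals by default) happens only at report time.
A brute-force oracle (`brute_force_rules`) enumerates the full itemset
lattice on small inputs and exists solely as an independent cross-check of
the Apriori path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

from .etl import Transaction, TransactionSet


class EmptyTransactionSetError(ValueError):
    """Support is undefined over zero transactions."""


class UndefinedLiftError(ValueError):
    """Lift is undefined when an antecedent or consequent never occurs."""


def round_ratio(numerator: int, denominator: int, decimals: int = 4) -> float:
    """Round the exact ratio of two non-negative integers, half away from zero.

    Operating on integers avoids binary-float ties (e.g. 669/687 must round
    to 0.9738, not whatever ``round()`` makes of the nearest double).
    """
    if denominator == 0:
        raise ZeroDivisionError("round_ratio: zero denominator")
    scale = 10**decimals
    q, r = divmod(numerator * scale, denominator)
    if 2 * r >= denominator:
        q += 1
    return q / scale


@dataclass(frozen=True)
class MiningConfig:
    min_support: float = 0.01
    min_confidence: float = 0.50
    max_rule_items: int = 2
    rounding_decimals: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1 and 0 < self.min_confidence <= 1):
            raise ValueError("min_support and min_confidence must be in (0, 1]")
        if self.max_rule_items < 2:
            raise ValueError("max_rule_items must be at least 2")


@dataclass(frozen=True)
class ItemSet:
    items: frozenset[str]
    support_count: int

    def sorted_items(self) -> tuple[str, ...]:
        return tuple(sorted(self.items))


@dataclass(frozen=True)
class AssociationRule:
    """A directed rule X → Y with exact counts over n transactions."""

    lhs: frozenset[str]
    rhs: frozenset[str]
    joint_count: int
    lhs_count: int
    rhs_count: int
    n: int
    decimals: int = field(default=4, compare=False)

    @property
    def support(self) -> Fraction:
        return Fraction(self.joint_count, self.n)

    @property
    def confidence(self) -> Fraction:
        return Fraction(self.joint_count, self.lhs_count)

    @property
    def lift(self) -> Fraction:
        if self.lhs_count == 0 or self.rhs_count == 0:
            raise UndefinedLiftError("lift undefined for zero marginal")
        return Fraction(self.joint_count * self.n, self.lhs_count * self.rhs_count)

    # rounded, report-scale values
    @property
    def support_r(self) -> float:
        return round_ratio(self.joint_count, self.n, self.decimals)

    @property
    def confidence_r(self) -> float:
        return round_ratio(self.joint_count, self.lhs_count, self.decimals)

    @property
    def lift_r(self) -> float:
        return round_ratio(self.joint_count * self.n, self.lhs_count * self.rhs_count,
                           self.decimals)

    def key(self) -> tuple:
        return (tuple(sorted(self.lhs)), tuple(sorted(self.rhs)))


def itemset_support(items: Iterable[str], txns: TransactionSet) -> tuple[int, float]:
    """Count transactions containing every item; return (count, proportion)."""
    if txns.n == 0:
        raise EmptyTransactionSetError("support is undefined on an empty transaction set")
    needle = frozenset(items)
    count = sum(1 for t in txns if needle <= t.items)
    return count, count / txns.n


def _count_candidates(
    candidates: list[tuple[str, ...]], txns: TransactionSet
) -> dict[tuple[str, ...], int]:
    counts = dict.fromkeys(candidates, 0)
    cand_sets = [(c, frozenset(c)) for c in candidates]
    for t in txns:
        for c, cs in cand_sets:
            if cs <= t.items:
                counts[c] += 1
    return counts


def frequent_itemsets(txns: TransactionSet, config: MiningConfig) -> list[ItemSet]:
    """Level-wise Apriori search for all itemsets with support ≥ min_support.

    Candidate k-itemsets are joined from frequent (k−1)-itemsets sharing
    their first k−2 items and pruned when any (k−1)-subset is infrequent
    (support is anti-monotone).  Output is sorted by size then items, so
    identical inputs always mine identically.
    """
    if txns.n == 0:
        return []
    # smallest integer count c with c/n >= min_support
    ms = Fraction(config.min_support).limit_denominator(10**9)
    min_count = max(1, math.ceil(ms * txns.n))

    item_counts: dict[str, int] = {}
    for t in txns:
        for it in t.items:
            item_counts[it] = item_counts.get(it, 0) + 1
    level = sorted((it,) for it, c in item_counts.items() if c >= min_count)
    counts: dict[tuple[str, ...], int] = {
        c: item_counts[c[0]] for c in level
    }
    result = [ItemSet(frozenset(c), counts[c]) for c in level]

    while level:
        prev = set(level)
        candidates = []
        for a, b in itertools.combinations(level, 2):
            if a[:-1] == b[:-1]:  # share first k-2 items (lists are sorted)
                cand = a + (b[-1],)
                if all(
                    cand[:i] + cand[i + 1:] in prev for i in range(len(cand))
                ):
                    candidates.append(cand)
        if not candidates:
            break
        cand_counts = _count_candidates(candidates, txns)
        level = sorted(c for c in candidates if cand_counts[c] >= min_count)
        result.extend(ItemSet(frozenset(c), cand_counts[c]) for c in level)

    result.sort(key=lambda s: (len(s.items), s.sorted_items()))
    return result


def derive_rules(
    frequents: list[ItemSet], txns: TransactionSet, config: MiningConfig
) -> list[AssociationRule]:
    """All directed rules from frequent itemsets passing the confidence bar.

    Both directions of a pair are distinct rules (they share support and
    lift but not confidence).  ``max_rule_items`` caps the total item count
    of a rule; at the default 2 only single-item→single-item rules emerge.
    Sorted by descending lift, then descending support, then antecedent.
    """
    count_of: dict[frozenset[str], int] = {s.items: s.support_count for s in frequents}
    min_conf = Fraction(config.min_confidence).limit_denominator(10**9)
    rules: list[AssociationRule] = []
    for s in frequents:
        if len(s.items) < 2 or len(s.items) > config.max_rule_items:
            continue
        items = s.sorted_items()
        for r in range(1, len(items)):
            for lhs in itertools.combinations(items, r):
                lhs_f = frozenset(lhs)
                rhs_f = s.items - lhs_f
                # subsets of a frequent set are frequent, so counts exist
                rule = AssociationRule(
                    lhs=lhs_f,
                    rhs=rhs_f,
                    joint_count=s.support_count,
                    lhs_count=count_of[lhs_f],
                    rhs_count=count_of[rhs_f],
                    n=txns.n,
                    decimals=config.rounding_decimals,
                )
                if rule.confidence >= min_conf:
                    rules.append(rule)
    rules.sort(key=lambda r: (-r.lift, -r.support, tuple(sorted(r.lhs)),
                              tuple(sorted(r.rhs))))
    return rules


def mine(txns: TransactionSet, config: MiningConfig | None = None) -> list[AssociationRule]:
    """Frequent-itemset search plus rule derivation in one call."""
    config = config or MiningConfig()
    return derive_rules(frequent_itemsets(txns, config), txns, config)


def brute_force_rules(
    txns: TransactionSet, config: MiningConfig, max_items: int = 12
) -> list[AssociationRule]:
    """Exhaustive-enumeration oracle: every subset of the item universe is
    counted directly, every ordered partition becomes a candidate rule.

    Deliberately independent of the Apriori code path; only for testing,
    guarded against exponential blow-up.
    """
    universe = sorted(txns.item_universe())
    if len(universe) > max_items:
        raise ValueError(
            f"brute_force_rules: {len(universe)} distinct items exceeds the "
            f"guard of {max_items}"
        )
    if txns.n == 0:
        return []
    counts: dict[frozenset[str], int] = {}
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            fs = frozenset(combo)
            counts[fs] = sum(1 for t in txns if fs <= t.items)
    min_sup = Fraction(config.min_support).limit_denominator(10**9)
    min_conf = Fraction(config.min_confidence).limit_denominator(10**9)
    rules = []
    for fs, c in counts.items():
        if len(fs) < 2 or len(fs) > config.max_rule_items:
            continue
        if Fraction(c, txns.n) < min_sup:
            continue
        items = sorted(fs)
        for r in range(1, len(items)):
            for lhs in itertools.combinations(items, r):
                lhs_f = frozenset(lhs)
                rhs_f = fs - lhs_f
                if Fraction(c, counts[lhs_f]) >= min_conf:
                    rules.append(
                        AssociationRule(lhs_f, rhs_f, c, counts[lhs_f],
                                        counts[rhs_f], txns.n,
                                        decimals=config.rounding_decimals)
                    )
    rules.sort(key=lambda r: (-r.lift, -r.support, tuple(sorted(r.lhs)),
                              tuple(sorted(r.rhs))))
    return rules
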