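import pytest

from rxaudit.etl import Transaction, TransactionSet


def make_txns(itemsets) -> TransactionSet:
    """TransactionSet from an iterable of item collections."""
    return TransactionSet(tuple(
        Transaction(f"V{i:05d}|test", frozenset(items))
        for i, items in enumerate(itemsets)
    ))


@pytest.fixture
def toy_txns() -> TransactionSet:
    """Five transactions: AB, AB, AC, BC, A (classic small mining example)."""
    return make_txns(["AB", "AB", "AC", "BC", "A"])
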