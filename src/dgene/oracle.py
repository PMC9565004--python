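"""Brute-force frequent-itemset reference miner.

Counts the support of every non-empty itemset over the observed alphabet
directly from the raw transaction list — no compression, trimming or
accumulation tricks — so it serves as an independent cross-check for the
three-phase miner. Deliberately naive: its cost is 2^|alphabet| scans, so
it refuses alphabets larger than a small guard.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List

from .miner import FrequentItemsetResult, MinsupThreshold
from .transactions import Itemset, TransactionDataset

ALPHABET_GUARD = 20


def oracle_mine(
    dataset: TransactionDataset, fraction: float, guard: int = ALPHABET_GUARD
) -> FrequentItemsetResult:
    """Exhaustively count support for every itemset over the observed alphabet."""
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot mine an empty dataset")
    if not 0 < fraction <= 1:
        raise ValueError(f"minsup fraction must lie in (0, 1], got {fraction}")
    alphabet = sorted({c for row in dataset for c in row})
    if len(alphabet) > guard:
        raise ValueError(
            f"alphabet of {len(alphabet)} items exceeds the brute-force guard "
            f"({guard}); use the three-phase miner instead"
        )
    # same rounding convention, computed independently of the miner module
    threshold = max(1, math.floor(fraction * n + 0.5))

    rows = [frozenset(row) for row in dataset]
    counts: Dict[Itemset, int] = {}
    for r in range(1, len(alphabet) + 1):
        for candidate in itertools.combinations(alphabet, r):
            want = frozenset(candidate)
            counts[candidate] = sum(1 for row in rows if want <= row)
    frequent = {s: v for s, v in counts.items() if v >= threshold}
    return FrequentItemsetResult(
        itemsets=frequent,
        threshold=MinsupThreshold(fraction=fraction, absolute=threshold),
        total=n,
        candidate_supports=counts,
    )
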