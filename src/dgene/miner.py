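"""Three-phase frequent-itemset miner over compressed transaction tables.

The miner works against a minimum-support threshold minsup, given as a
fraction of the dataset size and converted to an absolute count by
round-half-up. Phase 1 compresses the dataset to distinct patterns (done
upstream by :mod:`dgene.transactions`) and tallies per-item supports to
extract the frequent single items. Phase 2 intersects every distinct
pattern with the frequent-item set, discarding empty intersections and
merging patterns that become identical, summing their multiplicities.
Phase 3 enumerates the powerset of every trimmed pattern (its "ITTL",
the list of all its non-empty subsets) and accumulates each subset's
support across patterns; subsets reaching the threshold form the frequent
family, reported with their exact fully-accumulated supports.

Because trimming only removes globally infrequent items, every itemset of
frequent items has exactly the same support before and after phase 2, so
the three-phase result coincides with brute-force counting over raw rows
(the antimonotone property guarantees no frequent itemset is lost).
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Tuple

from .transactions import CompressedDataset, Itemset, as_itemset


def absolute_threshold(total: int, fraction: float) -> int:
    """Convert a minsup fraction into an absolute count: round-half-up, min 1."""
    if total < 1:
        raise ValueError(f"dataset total must be >= 1, got {total}")
    if not 0 < fraction <= 1:
        raise ValueError(f"minsup fraction must lie in (0, 1], got {fraction}")
    return max(1, math.floor(fraction * total + 0.5))


@dataclass(frozen=True)
class MinsupThreshold:
    fraction: float
    absolute: int

    @classmethod
    def from_fraction(cls, total: int, fraction: float) -> "MinsupThreshold":
        return cls(fraction=fraction, absolute=absolute_threshold(total, fraction))


@dataclass
class SingletonSupportTable:
    """Phase-1 output: cumulative per-item supports and the frequent items."""

    supports: Dict[int, int]
    frequent_items: Tuple[int, ...]
    threshold: int


@dataclass
class TrimmedDataset:
    """Phase-2 output: patterns restricted to frequent items, merged."""

    counts: Dict[Itemset, int]


@dataclass
class FrequentItemsetResult:
    """Frequent itemsets with exact supports, plus all accumulated candidates.

    ``itemsets`` maps each frequent itemset to its exact support count;
    ``candidate_supports`` additionally retains the exact support of every
    subset enumerated in phase 3 (frequent or not), which is what a
    full support tally of the powerset accumulation reports.
    """

    itemsets: Dict[Itemset, int]
    threshold: MinsupThreshold
    total: int
    candidate_supports: Dict[Itemset, int] = field(default_factory=dict)

    @property
    def family(self) -> Tuple[Itemset, ...]:
        """Frequent itemsets ordered by (size, lexicographic)."""
        return tuple(sorted(self.itemsets, key=lambda s: (len(s), s)))

    def support(self, itemset: Iterable[int]) -> int:
        """Exact accumulated support of an itemset (frequent or candidate)."""
        key = as_itemset(itemset)
        if key in self.itemsets:
            return self.itemsets[key]
        return self.candidate_supports[key]

    def percentage(self, itemset: Iterable[int]) -> int:
        """Floor integer percentage support, as reported in ladder tables."""
        return (100 * self.support(itemset)) // self.total


def frequent_singletons(compressed: CompressedDataset, threshold: int) -> SingletonSupportTable:
    """Phase 1: tally each item's support over the compressed keys."""
    supports: Dict[int, int] = defaultdict(int)
    for key, mult in compressed.counts.items():
        for item in key:
            supports[item] += mult
    frequent = tuple(sorted(i for i, s in supports.items() if s >= threshold))
    return SingletonSupportTable(dict(supports), frequent, threshold)


def trim_and_merge(compressed: CompressedDataset, frequent_items: Iterable[int]) -> TrimmedDataset:
    """Phase 2: intersect keys with the frequent items, merge identical results.

    Patterns whose intersection is empty are dropped; their multiplicity is
    not represented in the trimmed table (but still counts toward the
    dataset total used for percentage supports).
    """
    keep: FrozenSet[int] = frozenset(frequent_items)
    merged: Dict[Itemset, int] = defaultdict(int)
    for key, mult in compressed.counts.items():
        trimmed = tuple(c for c in key if c in keep)
        if trimmed:
            merged[trimmed] += mult
    return TrimmedDataset(dict(merged))


def accumulate_powersets(trimmed: TrimmedDataset, threshold: int, total: int) -> FrequentItemsetResult:
    """Phase 3: accumulate every trimmed pattern's powerset against minsup.

    Every non-empty subset of every trimmed key receives the key's
    multiplicity; the accumulated value is therefore the exact support of
    that subset. The frequent family is the set of subsets whose fully
    accumulated support reaches the threshold — the result cannot depend
    on the order keys are processed in.
    """
    acc: Dict[Itemset, int] = defaultdict(int)
    for key, mult in trimmed.counts.items():
        for r in range(1, len(key) + 1):
            for subset in itertools.combinations(key, r):
                acc[subset] += mult
    frequent = {s: v for s, v in acc.items() if v >= threshold}
    return FrequentItemsetResult(
        itemsets=frequent,
        threshold=MinsupThreshold(fraction=threshold / total, absolute=threshold),
        total=total,
        candidate_supports=dict(acc),
    )


def mine(compressed: CompressedDataset, fraction: float) -> FrequentItemsetResult:
    """Run the full three-phase miner at the given minsup fraction.

    Singleton supports come from phase 1, so frequent single items are
    reported even when no trimmed pattern survives to phase 3.
    """
    total = compressed.total
    if total == 0:
        raise ValueError("cannot mine an empty dataset")
    threshold = MinsupThreshold.from_fraction(total, fraction)
    singles = frequent_singletons(compressed, threshold.absolute)
    trimmed = trim_and_merge(compressed, singles.frequent_items)
    result = accumulate_powersets(trimmed, threshold.absolute, total)
    result.threshold = threshold
    # Phase-1 singleton supports are authoritative (identical by conservation,
    # but phase 3 never runs when no item is frequent). Keep every singleton
    # tally visible among the candidates, including infrequent items.
    for item, support in singles.supports.items():
        result.candidate_supports.setdefault((item,), support)
    for item in singles.frequent_items:
        result.itemsets[(item,)] = singles.supports[item]
    return result
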