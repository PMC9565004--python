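"""Minsup-ladder sweeps, percentage supports and two-population contrasts.

Sweeping the minimum-support threshold downward over a grid of integer
percentages yields a nested "ladder" of frequent-itemset families: each
higher-minsup family is contained in every lower one. Supports are quoted
as floor integer percentages of the dataset size, the convention used when
reporting survey shares (4425/6243 reads as 70%, not 71%).

The disparity report aligns co-occurring itemsets (size >= 2 by default)
across two populations — e.g. husbands vs wives — and tabulates each
population's percentage support and the difference. Either side may be a
mined result or a transcribed {itemset: percent} table when only published
percentages are available for that population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .miner import FrequentItemsetResult, mine
from .transactions import (
    CompressedDataset,
    DataFormatError,
    ItemCodebook,
    Itemset,
    as_itemset,
    format_itemset,
)


def percentage_support(support: int, total: int) -> int:
    """Integer percentage of transactions containing an itemset (floor)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= support <= total:
        raise ValueError(f"support {support} outside [0, {total}]")
    return (100 * support) // total


@dataclass
class LadderRow:
    percent: int
    result: FrequentItemsetResult

    @property
    def family(self) -> Tuple[Itemset, ...]:
        return self.result.family


@dataclass
class MinsupLadder:
    """Frequent families at a descending grid of minsup percentages."""

    rows: List[LadderRow]

    def family_at(self, percent: int) -> Tuple[Itemset, ...]:
        for row in self.rows:
            if row.percent == percent:
                return row.family
        raise KeyError(f"no ladder row at minsup {percent}%")


def sweep(compressed: CompressedDataset, minsup_percents: Sequence[int]) -> MinsupLadder:
    """Mine the dataset once per grid value; rows sorted by descending minsup."""
    if not minsup_percents:
        raise ValueError("minsup grid must be non-empty")
    for p in minsup_percents:
        if not 0 < p <= 100:
            raise ValueError(f"minsup percent must lie in (0, 100], got {p}")
    rows = [
        LadderRow(percent=p, result=mine(compressed, p / 100))
        for p in sorted(set(minsup_percents), reverse=True)
    ]
    return MinsupLadder(rows)


ResultLike = Union[FrequentItemsetResult, Mapping[Itemset, int]]


@dataclass
class DisparityRecord:
    itemset: Itemset
    percent_a: Optional[int]
    percent_b: Optional[int]

    @property
    def delta(self) -> Optional[int]:
        if self.percent_a is None or self.percent_b is None:
            return None
        return self.percent_b - self.percent_a


@dataclass
class DisparityTable:
    records: List[DisparityRecord]
    label_a: str
    label_b: str


def _itemsets_of(result: ResultLike) -> Tuple[Itemset, ...]:
    if isinstance(result, FrequentItemsetResult):
        return result.family
    return tuple(sorted((as_itemset(k) for k in result), key=lambda s: (len(s), s)))


def _percent_of(result: ResultLike, itemset: Itemset) -> Optional[int]:
    if isinstance(result, FrequentItemsetResult):
        if itemset in result.itemsets or itemset in result.candidate_supports:
            return result.percentage(itemset)
        return None
    value = result.get(itemset)
    return None if value is None else int(value)


def disparity(
    result_a: ResultLike,
    result_b: ResultLike,
    min_size: int = 2,
    label_a: str = "A",
    label_b: str = "B",
) -> DisparityTable:
    """Align itemsets of size >= min_size across two populations.

    The union of itemsets frequent in either population is tabulated; a
    percentage is drawn from each population's own supports when available
    (even for an itemset only frequent on the other side), otherwise the
    cell is marked absent and no delta is computed.
    """
    union = {s for s in _itemsets_of(result_a) if len(s) >= min_size}
    union |= {s for s in _itemsets_of(result_b) if len(s) >= min_size}
    records = [
        DisparityRecord(
            itemset=s,
            percent_a=_percent_of(result_a, s),
            percent_b=_percent_of(result_b, s),
        )
        for s in sorted(union, key=lambda s: (len(s), s))
    ]
    return DisparityTable(records, label_a, label_b)


def _gloss(itemset: Itemset, codebook: ItemCodebook) -> str:
    return " AND ".join(codebook.label(c) for c in itemset)


def _format_family(
    family: Tuple[Itemset, ...],
    codebook: Optional[ItemCodebook],
    expand_reasons: bool,
) -> str:
    if not family:
        return "(none)"
    if expand_reasons:
        if codebook is None:
            raise DataFormatError("a codebook is required to expand reasons")
        return "; ".join(_gloss(s, codebook) for s in family)
    return ", ".join(format_itemset(s) for s in family)


def render_ladder(
    ladder: MinsupLadder,
    codebook: Optional[ItemCodebook] = None,
    expand_reasons: bool = False,
) -> str:
    """Plain-text ladder table: one row per minsup, descending."""
    lines = ["minsup%\tfrequent itemsets"]
    for row in ladder.rows:
        lines.append(f"{row.percent}\t{_format_family(row.family, codebook, expand_reasons)}")
    return "\n".join(lines)


def render_disparity(
    table: DisparityTable,
    codebook: Optional[ItemCodebook] = None,
    expand_reasons: bool = False,
) -> str:
    """Plain-text contrast table: itemset, %A, %B, delta (B - A)."""
    header = f"itemset\t{table.label_a}%\t{table.label_b}%\tdelta"
    lines = [header]
    for rec in table.records:
        if expand_reasons:
            if codebook is None:
                raise DataFormatError("a codebook is required to expand reasons")
            name = _gloss(rec.itemset, codebook)
        else:
            name = format_itemset(rec.itemset)
        pa = "-" if rec.percent_a is None else str(rec.percent_a)
        pb = "-" if rec.percent_b is None else str(rec.percent_b)
        delta = "-" if rec.delta is None else f"{rec.delta:+d}"
        lines.append(f"{name}\t{pa}\t{pb}\t{delta}")
    return "\n".join(lines)


def render(
    obj: Union[MinsupLadder, DisparityTable],
    codebook: Optional[ItemCodebook] = None,
    expand_reasons: bool = False,
) -> str:
    if isinstance(obj, MinsupLadder):
        return render_ladder(obj, codebook, expand_reasons)
    if isinstance(obj, DisparityTable):
        return render_disparity(obj, codebook, expand_reasons)
    raise TypeError(f"cannot render object of type {type(obj).__name__}")
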