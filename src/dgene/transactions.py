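"""Transaction data model and I/O for reason-endorsement surveys.

A *transaction* is one respondent's non-empty set of endorsed reason codes
(positive integers drawn from a codebook). A dataset of such transactions
is the input to frequent-itemset mining: the support of an itemset S is the
number of transactions containing every code of S. Because only a handful
of distinct response patterns exist (2^k - 1 for k survey items), datasets
compress losslessly into a multiset of distinct patterns with multiplicities;
all mining here operates on that compressed form.

The canonical in-memory representation of an itemset is a sorted tuple of
integer codes, which gives deterministic dictionary keys and stable output
ordering throughout the package.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

Itemset = Tuple[int, ...]


class DataFormatError(ValueError):
    """Raised when an input file or record violates the expected format."""


def as_itemset(codes: Iterable[int]) -> Itemset:
    """Canonicalise a collection of codes into a sorted, de-duplicated tuple."""
    out = tuple(sorted({int(c) for c in codes}))
    if any(c <= 0 for c in out):
        raise DataFormatError(f"item codes must be positive integers, got {out}")
    return out


@dataclass(frozen=True)
class ItemCodebook:
    """Maps integer item codes to the survey reason they encode."""

    entries: Mapping[int, str]

    def __post_init__(self) -> None:
        texts = list(self.entries.values())
        if any(not isinstance(c, int) or c <= 0 for c in self.entries):
            raise DataFormatError("codebook codes must be positive integers")
        if any(not t for t in texts):
            raise DataFormatError("codebook reason texts must be non-empty")
        if len(set(texts)) != len(texts):
            raise DataFormatError("codebook reason texts must be unique")

    def __contains__(self, code: int) -> bool:
        return code in self.entries

    @property
    def codes(self) -> Tuple[int, ...]:
        return tuple(sorted(self.entries))

    def label(self, code: int) -> str:
        try:
            return self.entries[code]
        except KeyError:
            raise DataFormatError(f"code {code} not present in codebook") from None

    @classmethod
    def synthetic(cls, codes: Iterable[int]) -> "ItemCodebook":
        """Placeholder codebook ("item <code>") for data without labels."""
        return cls({int(c): f"item {int(c)}" for c in sorted(set(codes))})


#: The five wife-beating justification items of the MICS attitude module,
#: in their standard coding.
STUDY_REASONS: Dict[int, str] = {
    1: "If she goes out without telling him",
    2: "If she neglects the children",
    3: "If she argues with him",
    4: "If she refuses to have sex with him",
    5: "If she burns the food",
}


def study_codebook() -> ItemCodebook:
    """The canonical five-item codebook of the IPV-attitude survey module."""
    return ItemCodebook(dict(STUDY_REASONS))


@dataclass
class TransactionDataset:
    """An ordered list of respondent transactions plus their codebook."""

    transactions: List[Itemset]
    codebook: ItemCodebook

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self) -> Iterator[Itemset]:
        return iter(self.transactions)


@dataclass
class CompressedDataset:
    """Distinct transactions with multiplicities (the miner's D1 table)."""

    counts: Dict[Itemset, int]
    codebook: ItemCodebook

    def __post_init__(self) -> None:
        for key, mult in self.counts.items():
            if not key:
                raise DataFormatError("compressed keys must be non-empty itemsets")
            if key != as_itemset(key):
                raise DataFormatError(f"key {key} is not a canonical sorted tuple")
            if mult < 1:
                raise DataFormatError(f"multiplicity of {key} must be >= 1, got {mult}")

    @property
    def total(self) -> int:
        """Number of raw transactions represented (sum of multiplicities)."""
        return sum(self.counts.values())

    def support(self, itemset: Iterable[int]) -> int:
        """Exact support of an itemset: multiplicity-weighted superset count."""
        want = frozenset(as_itemset(itemset))
        if not want:
            raise DataFormatError("support is defined for non-empty itemsets only")
        return sum(m for key, m in self.counts.items() if want <= frozenset(key))


def compress(dataset: TransactionDataset) -> CompressedDataset:
    """Collapse repeated transactions into (pattern, multiplicity) pairs."""
    return CompressedDataset(dict(Counter(dataset.transactions)), dataset.codebook)


def expand(compressed: CompressedDataset) -> TransactionDataset:
    """Inverse of :func:`compress` with a deterministic row order.

    Keys are emitted in sorted order, each repeated its multiplicity times,
    so re-compressing reproduces identical counts.
    """
    rows: List[Itemset] = []
    for key in sorted(compressed.counts):
        rows.extend([key] * compressed.counts[key])
    return TransactionDataset(rows, compressed.codebook)


def _parse_row(
    raw: str, delimiter: str, row_no: int, codebook: Optional[ItemCodebook]
) -> Itemset:
    tokens = [t.strip() for t in raw.split(delimiter)]
    tokens = [t for t in tokens if t != ""] if raw.strip() else []
    if not tokens:
        raise DataFormatError(f"row {row_no} is empty: every respondent must endorse at least one reason")
    codes = []
    for col, tok in enumerate(tokens, start=1):
        try:
            codes.append(int(tok))
        except ValueError:
            raise DataFormatError(f"row {row_no}, column {col}: non-integer token {tok!r}") from None
    itemset = as_itemset(codes)
    if codebook is not None:
        for c in itemset:
            if c not in codebook:
                raise DataFormatError(f"row {row_no}: code {c} absent from codebook")
    return itemset


def load_transactions(
    path: str | Path,
    delimiter: str = ",",
    codebook: Optional[ItemCodebook] = None,
) -> TransactionDataset:
    """Read a transaction file: one respondent per line, delimited codes.

    Duplicate codes within a row collapse silently; an empty row is an
    error (the study design excludes respondents endorsing nothing).
    Lines starting with ``#`` are provenance comments and are skipped.
    When no codebook is given, a synthetic one is attached from the
    observed codes.
    """
    rows: List[Itemset] = []
    with open(path, "r", encoding="utf-8") as handle:
        for row_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.lstrip().startswith("#"):
                continue
            rows.append(_parse_row(line, delimiter, row_no, codebook))
    if codebook is None:
        observed = sorted({c for row in rows for c in row})
        codebook = ItemCodebook.synthetic(observed) if observed else ItemCodebook({})
    return TransactionDataset(rows, codebook)


def write_transactions(
    dataset: TransactionDataset,
    path: str | Path,
    delimiter: str = ",",
    header_comment: Optional[str] = None,
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        for row in dataset.transactions:
            handle.write(delimiter.join(str(c) for c in row) + "\n")


def format_itemset(itemset: Itemset) -> str:
    """Render an itemset as "+"-joined sorted codes, e.g. ``1+2+3``."""
    return "+".join(str(c) for c in itemset)


def parse_itemset(text: str) -> Itemset:
    try:
        return as_itemset(int(tok) for tok in text.strip().split("+"))
    except ValueError:
        raise DataFormatError(f"malformed itemset field {text!r}") from None


def load_compressed(
    path: str | Path,
    delimiter: str = ",",
    codebook: Optional[ItemCodebook] = None,
) -> CompressedDataset:
    """Read a two-column (itemset, multiplicity) table; header line required."""
    counts: Dict[Itemset, int] = {}
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        try:
            next(reader)  # header
        except StopIteration:
            raise DataFormatError(f"{path}: compressed file requires a header line") from None
        for row_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise DataFormatError(f"{path} row {row_no}: expected 2 columns, got {len(row)}")
            key = parse_itemset(row[0])
            try:
                mult = int(row[1])
            except ValueError:
                raise DataFormatError(f"{path} row {row_no}: non-integer multiplicity {row[1]!r}") from None
            if key in counts:
                raise DataFormatError(f"{path} row {row_no}: duplicate itemset {format_itemset(key)}")
            counts[key] = mult
    if codebook is None:
        observed = sorted({c for key in counts for c in key})
        codebook = ItemCodebook.synthetic(observed) if observed else ItemCodebook({})
    return CompressedDataset(counts, codebook)


def write_compressed(
    compressed: CompressedDataset, path: str | Path, delimiter: str = ","
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(["itemset", "count"])
        for key in sorted(compressed.counts, key=lambda k: (len(k), k)):
            writer.writerow([format_itemset(key), compressed.counts[key]])


def load_codebook(path: str | Path, delimiter: str = ",") -> ItemCodebook:
    """Read a two-column (code, reason text) codebook file."""
    entries: Dict[int, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        for row_no, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise DataFormatError(f"{path} row {row_no}: expected code and reason text")
            try:
                code = int(row[0])
            except ValueError:
                raise DataFormatError(f"{path} row {row_no}: non-integer code {row[0]!r}") from None
            entries[code] = delimiter.join(row[1:]).strip() if len(row) > 2 else row[1].strip()
    return ItemCodebook(entries)


def write_codebook(codebook: ItemCodebook, path: str | Path, delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        for code in codebook.codes:
            writer.writerow([code, codebook.label(code)])
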