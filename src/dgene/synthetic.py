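"""Synthetic survey-response generator and the embedded husbands' dataset.

Real attitude-survey endorsements are positively associated: a respondent
inclined to accept one justification tends to accept others. The generator
emulates this with a latent-propensity model. Each respondent draws a
standard-normal factor z; item j is endorsed independently given z with
probability sigmoid(base_logit_j + scale * z). Marginalising z (by
Gauss-Hermite quadrature) and conditioning on at least one endorsement —
the survey keeps only respondents answering yes to some item — yields an
explicit probability for each of the 2^k - 1 non-empty response patterns.
Every downstream support therefore has a closed-form expectation, which is
what makes the miner testable without any external data.

The module also ships the complete husbands' dataset (6,243 respondents
over the five study items) as an embedded compressed table of its 31
distinct response patterns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

from .transactions import (
    CompressedDataset,
    DataFormatError,
    ItemCodebook,
    Itemset,
    TransactionDataset,
    as_itemset,
    format_itemset,
    parse_itemset,
    study_codebook,
)

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class PropensityParams:
    """Latent-factor endorsement model: logit_j(z) = base_logits[j] + scale*z."""

    k: int
    base_logits: Tuple[float, ...]
    propensity_scale: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if len(self.base_logits) != self.k:
            raise ValueError(f"need {self.k} base logits, got {len(self.base_logits)}")
        if self.propensity_scale < 0:
            raise ValueError("propensity_scale must be non-negative")

    @classmethod
    def homogeneous(cls, k: int, base_logit: float = 0.0, propensity_scale: float = 0.0) -> "PropensityParams":
        return cls(k, (base_logit,) * k, propensity_scale)


@dataclass(frozen=True)
class SubsetDistribution:
    """A probability law over the 2^k - 1 non-empty response patterns."""

    k: int
    probabilities: Mapping[Itemset, float]

    def __post_init__(self) -> None:
        if len(self.probabilities) != 2**self.k - 1:
            raise ValueError(
                f"expected {2**self.k - 1} non-empty patterns for k={self.k}, "
                f"got {len(self.probabilities)}"
            )
        total = 0.0
        for key, p in self.probabilities.items():
            if not key or key != as_itemset(key) or any(c > self.k for c in key):
                raise ValueError(f"invalid pattern key {key} for k={self.k}")
            if p < 0:
                raise ValueError(f"negative probability for {key}")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern probabilities sum to {total}, not 1")

    @property
    def patterns(self) -> Tuple[Itemset, ...]:
        return tuple(sorted(self.probabilities))

    @classmethod
    def from_compressed(cls, compressed: CompressedDataset) -> "SubsetDistribution":
        """Empirical pattern distribution of a compressed dataset."""
        if not compressed.counts:
            raise ValueError("cannot form a distribution from an empty dataset")
        k = max(c for key in compressed.counts for c in key)
        total = compressed.total
        probs: Dict[Itemset, float] = {
            pattern: 0.0 for pattern in _nonempty_subsets(k)
        }
        for key, mult in compressed.counts.items():
            probs[key] = mult / total
        return cls(k, probs)


def _nonempty_subsets(k: int) -> Iterable[Itemset]:
    items = range(1, k + 1)
    for r in range(1, k + 1):
        yield from itertools.combinations(items, r)


def to_subset_distribution(params: PropensityParams, resolution: int = 31) -> SubsetDistribution:
    """Marginalise the latent factor and condition on >=1 endorsement.

    The standard-normal latent factor is integrated with ``resolution``-node
    Gauss-Hermite quadrature (probabilists' convention), so the result is
    deterministic for fixed inputs. With propensity_scale = 0 the items are
    independent and the quadrature is exact.
    """
    if resolution < 1:
        raise ValueError("quadrature resolution must be >= 1")
    nodes, weights = np.polynomial.hermite_e.hermegauss(resolution)
    weights = weights / weights.sum()
    logits = np.asarray(params.base_logits, dtype=float)

    k = params.k
    patterns = list(_nonempty_subsets(k))
    # membership[i, j] == True iff pattern i endorses item j+1
    membership = np.zeros((len(patterns), k), dtype=bool)
    for i, pat in enumerate(patterns):
        membership[i, [c - 1 for c in pat]] = True

    pattern_mass = np.zeros(len(patterns))
    empty_mass = 0.0
    for z, w in zip(nodes, weights):
        # sigmoid via tanh: stable for extreme logits
        p = 0.5 * (1.0 + np.tanh(0.5 * (logits + params.propensity_scale * z)))
        per_item = np.where(membership, p, 1.0 - p)
        pattern_mass += w * per_item.prod(axis=1)
        empty_mass += w * float(np.prod(1.0 - p))

    nonempty = pattern_mass.sum()
    if nonempty <= _PROB_TOL:
        raise ValueError(
            "empty response pattern has probability 1: nothing to condition on"
        )
    pattern_mass /= nonempty
    return SubsetDistribution(k, dict(zip(patterns, pattern_mass.tolist())))


def expected_support(dist: SubsetDistribution, itemset: Iterable[int]) -> float:
    """Population support of an itemset: P(pattern contains every item of S)."""
    want = as_itemset(itemset)
    if not want:
        raise ValueError("expected_support is defined for non-empty itemsets")
    if any(c > dist.k for c in want):
        raise ValueError(f"itemset {want} is outside the alphabet 1..{dist.k}")
    want_set = frozenset(want)
    return sum(p for pat, p in dist.probabilities.items() if want_set <= frozenset(pat))


def sample(dist: SubsetDistribution, n: int, seed: int) -> TransactionDataset:
    """Draw n i.i.d. response patterns by inverse CDF over the sorted patterns.

    The same (dist, n, seed) always yields an identical dataset.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    patterns = dist.patterns
    cdf = np.cumsum([dist.probabilities[p] for p in patterns])
    cdf[-1] = 1.0  # guard against floating-point shortfall
    rng = np.random.default_rng(seed)
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    idx = np.minimum(idx, len(patterns) - 1)
    rows = [patterns[i] for i in idx]
    return TransactionDataset(rows, ItemCodebook.synthetic(range(1, dist.k + 1)))


# Complete husbands' dataset: the 31 distinct response patterns over the
# five justification items and their multiplicities (sum 6,243).
_HUSBANDS_ROWS: Tuple[Tuple[Itemset, int], ...] = (
    ((1,), 456),
    ((2,), 302),
    ((3,), 640),
    ((4,), 179),
    ((5,), 128),
    ((1, 2), 315),
    ((1, 3), 239),
    ((1, 4), 68),
    ((1, 5), 24),
    ((2, 3), 282),
    ((2, 4), 95),
    ((2, 5), 44),
    ((3, 4), 225),
    ((3, 5), 59),
    ((4, 5), 36),
    ((1, 2, 3), 586),
    ((1, 2, 4), 73),
    ((1, 2, 5), 45),
    ((1, 3, 4), 104),
    ((1, 3, 5), 40),
    ((1, 4, 5), 13),
    ((2, 3, 4), 156),
    ((2, 3, 5), 47),
    ((2, 4, 5), 17),
    ((3, 4, 5), 51),
    ((1, 2, 3, 4), 515),
    ((1, 2, 3, 5), 147),
    ((1, 2, 4, 5), 23),
    ((1, 3, 4, 5), 35),
    ((2, 3, 4, 5), 82),
    ((1, 2, 3, 4, 5), 1217),
)


def husbands_fixture() -> CompressedDataset:
    """The husbands' dataset (6,243 respondents) in compressed form."""
    return CompressedDataset(dict(_HUSBANDS_ROWS), study_codebook())


def write_distribution(dist: SubsetDistribution, path: str | Path) -> None:
    """Serialise a SubsetDistribution as plain-text key=value lines."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"k={dist.k}\n")
        for pat in dist.patterns:
            handle.write(f"{format_itemset(pat)}={dist.probabilities[pat]!r}\n")


def read_distribution(path: str | Path) -> SubsetDistribution:
    k = None
    probs: Dict[Itemset, float] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            if key == "k":
                k = int(value)
            else:
                probs[parse_itemset(key)] = float(value)
    if k is None:
        raise DataFormatError(f"{path}: missing 'k=' line")
    return SubsetDistribution(k, probs)


def write_params(params: PropensityParams, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"k={params.k}\n")
        handle.write("base_logits=" + ",".join(repr(b) for b in params.base_logits) + "\n")
        handle.write(f"propensity_scale={params.propensity_scale!r}\n")


def read_params(path: str | Path) -> PropensityParams:
    fields: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key] = value
    try:
        return PropensityParams(
            k=int(fields["k"]),
            base_logits=tuple(float(b) for b in fields["base_logits"].split(",")),
            propensity_scale=float(fields["propensity_scale"]),
        )
    except KeyError as missing:
        raise DataFormatError(f"{path}: missing field {missing}") from None
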