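"""Three-phase miner: phase tallies, composition and algebraic invariants."""

import itertools
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dgene import (
    CompressedDataset,
    ItemCodebook,
    TransactionDataset,
    absolute_threshold,
    accumulate_powersets,
    compress,
    expand,
    frequent_singletons,
    mine,
    oracle_mine,
    trim_and_merge,
)
from dgene.miner import TrimmedDataset

from expected_tables import (
    HUSBANDS_ACCUMULATED_38,
    HUSBANDS_SINGLETON_SUPPORTS,
    HUSBANDS_TRIMMED_38,
)

itemsets = st.sets(st.integers(1, 6), min_size=1, max_size=6).map(lambda s: tuple(sorted(s)))
compressed_counts = st.dictionaries(itemsets, st.integers(1, 30), min_size=1, max_size=20)


def _compressed(counts):
    return CompressedDataset(dict(counts), ItemCodebook.synthetic(range(1, 7)))


def _random_dataset(rng, k_max=6, n_max=200):
    k = rng.randint(2, k_max)
    n = rng.randint(1, n_max)
    rows = []
    for _ in range(n):
        size = rng.randint(1, k)
        rows.append(tuple(sorted(rng.sample(range(1, k + 1), size))))
    return TransactionDataset(rows, ItemCodebook.synthetic(range(1, k + 1)))


class TestAbsoluteThreshold:
    @pytest.mark.parametrize(
        "total,fraction,expected",
        [
            (6243, 0.38, 2372),
            (100, 0.50, 50),
            (6243, 0.26, 1623),
            (10, 0.25, 3),  # 2.5 rounds half-up
            (3, 0.01, 1),  # floor would give 0; minimum is 1
        ],
    )
    def test_round_half_up(self, total, fraction, expected):
        assert absolute_threshold(total, fraction) == expected

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_fraction_out_of_range_rejected(self, fraction):
        with pytest.raises(ValueError):
            absolute_threshold(100, fraction)


class TestPhase1:
    def test_husbands_singleton_supports(self, husbands):
        table = frequent_singletons(husbands, 2372)
        assert table.supports == HUSBANDS_SINGLETON_SUPPORTS
        assert table.frequent_items == (1, 2, 3, 4)

    def test_single_row(self):
        table = frequent_singletons(_compressed({(1,): 1}), 1)
        assert table.supports == {1: 1}
        assert table.frequent_items == (1,)

    def test_matches_direct_recount_on_random_rows(self):
        rng = random.Random(2024)
        ds = _random_dataset(rng, n_max=50)
        table = frequent_singletons(compress(ds), 1)
        for item, support in table.supports.items():
            assert support == sum(1 for row in ds if item in row)


class TestPhase2:
    def test_husbands_trim_to_frequent_items(self, husbands):
        trimmed = trim_and_merge(husbands, (1, 2, 3, 4))
        assert trimmed.counts == HUSBANDS_TRIMMED_38
        assert len(trimmed.counts) == 15

    def test_all_items_frequent_is_identity(self, husbands):
        trimmed = trim_and_merge(husbands, (1, 2, 3, 4, 5))
        assert trimmed.counts == husbands.counts

    def test_no_items_frequent_gives_empty_table(self, husbands):
        assert trim_and_merge(husbands, ()).counts == {}

    @given(counts=compressed_counts, keep=st.sets(st.integers(1, 6)))
    def test_conservation_of_supports_over_kept_items(self, counts, keep):
        comp = _compressed(counts)
        trimmed = trim_and_merge(comp, keep)
        # any itemset of kept items has identical support before and after
        for r in range(1, len(keep) + 1):
            for u in itertools.combinations(sorted(keep), r):
                before = sum(m for k, m in comp.counts.items() if set(u) <= set(k))
                after = sum(m for k, m in trimmed.counts.items() if set(u) <= set(k))
                assert before == after
        assert sum(trimmed.counts.values()) <= comp.total


class TestPhase3:
    def test_husbands_accumulated_supports_and_family(self, husbands):
        trimmed = trim_and_merge(husbands, (1, 2, 3, 4))
        result = accumulate_powersets(trimmed, 2372, husbands.total)
        assert result.candidate_supports == HUSBANDS_ACCUMULATED_38
        assert set(result.family) == {
            (1,), (2,), (3,), (4,), (1, 2), (1, 3), (2, 3), (3, 4), (1, 2, 3),
        }

    def test_single_key(self):
        result = accumulate_powersets(TrimmedDataset({(1, 2): 1}), 1, 1)
        assert result.itemsets == {(1,): 1, (2,): 1, (1, 2): 1}

    def test_threshold_one_equals_brute_force(self):
        rng = random.Random(5)
        ds = _random_dataset(rng, n_max=60)
        comp = compress(ds)
        result = mine(comp, 1 / len(ds))
        oracle = oracle_mine(ds, 1 / len(ds))
        assert result.itemsets == oracle.itemsets


class TestMine:
    def test_husbands_at_seventy_percent(self, husbands):
        result = mine(husbands, 0.70)
        assert result.itemsets == {(3,): 4425}

    def test_husbands_at_thirty_eight_percent(self, husbands):
        result = mine(husbands, 0.38)
        assert result.threshold.absolute == 2372
        expected = {
            s: v for s, v in HUSBANDS_ACCUMULATED_38.items() if v >= 2372
        }
        assert result.itemsets == expected

    def test_full_support_limit(self):
        comp = compress(
            TransactionDataset([(1, 2), (1, 2, 3), (1, 2)], ItemCodebook.synthetic([1, 2, 3]))
        )
        result = mine(comp, 1.0)
        assert result.itemsets == {(1,): 3, (2,): 3, (1, 2): 3}

    def test_no_itemset_in_every_transaction_gives_empty_family(self):
        comp = compress(TransactionDataset([(1,), (2,)], ItemCodebook.synthetic([1, 2])))
        assert mine(comp, 1.0).itemsets == {}

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            mine(CompressedDataset({}, ItemCodebook({})), 0.5)

    def test_order_invariance(self, husbands):
        shuffled_keys = list(husbands.counts)
        random.Random(3).shuffle(shuffled_keys)
        permuted = CompressedDataset(
            {k: husbands.counts[k] for k in shuffled_keys}, husbands.codebook
        )
        assert mine(permuted, 0.38).itemsets == mine(husbands, 0.38).itemsets

    @given(counts=compressed_counts, f=st.floats(0.05, 1.0))
    def test_monotone_in_minsup(self, counts, f):
        comp = _compressed(counts)
        lo = mine(comp, f / 2)
        hi = mine(comp, f)
        assert set(hi.itemsets) <= set(lo.itemsets)
        for s, v in hi.itemsets.items():
            assert lo.itemsets[s] == v

    @given(counts=compressed_counts, f=st.floats(0.05, 1.0))
    def test_downward_closure(self, counts, f):
        result = mine(_compressed(counts), f)
        for s, v in result.itemsets.items():
            for r in range(1, len(s)):
                for sub in itertools.combinations(s, r):
                    assert sub in result.itemsets
                    assert result.itemsets[sub] >= v


class TestOracleEquivalence:
    def test_two_hundred_random_datasets(self):
        rng = random.Random(20240915)
        for _ in range(200):
            ds = _random_dataset(rng)
            fraction = rng.uniform(0.01, 1.0)
            fast = mine(compress(ds), fraction)
            slow = oracle_mine(ds, fraction)
            assert fast.itemsets == slow.itemsets
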