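"""Frequency filtering of near-identical low-abundance sequences."""

import numpy as np
import pytest

from pyroclean import ClusterParams, UniqueSequence, frequency_filter
from pyroclean.iupac import LengthError


def variant(seq: str, positions, rng=None) -> str:
    chars = list(seq)
    for p in positions:
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    return "".join(chars)


@pytest.fixture(scope="module")
def base_seq():
    rng = np.random.default_rng(5)
    return "".join(rng.choice(list("ACGT"), size=220))


class TestFrequencyFilter:
    def test_low_frequency_close_variant_removed(self, base_seq):
        pool = [
            UniqueSequence("v", 1000, base_seq),
            UniqueSequence("u", 50, variant(base_seq, [10])),
        ]
        retained, removed = frequency_filter(pool, ClusterParams(0.01, 0.10))
        assert [u.name for u in retained] == ["v"]
        assert removed[0].name == "u" and removed[0].distance == 1

    def test_frequent_variant_retained(self, base_seq):
        pool = [
            UniqueSequence("v", 1000, base_seq),
            UniqueSequence("u", 200, variant(base_seq, [10])),
        ]
        retained, _ = frequency_filter(pool, ClusterParams(0.01, 0.10))
        assert {u.name for u in retained} == {"v", "u"}

    def test_distant_variant_retained_regardless_of_count(self, base_seq):
        # 3 mismatches > floor(0.01 * 220) = 2
        pool = [
            UniqueSequence("v", 1000, base_seq),
            UniqueSequence("u", 2, variant(base_seq, [10, 50, 90])),
        ]
        retained, _ = frequency_filter(pool, ClusterParams(0.01, 0.10))
        assert {u.name for u in retained} == {"v", "u"}

    def test_two_mismatches_within_threshold(self, base_seq):
        pool = [
            UniqueSequence("v", 1000, base_seq),
            UniqueSequence("u", 50, variant(base_seq, [10, 50])),
        ]
        retained, _ = frequency_filter(pool, ClusterParams(0.01, 0.10))
        assert [u.name for u in retained] == ["v"]

    def test_most_frequent_sequence_always_retained(self, base_seq, rng):
        pool = [UniqueSequence("top", 500, base_seq)] + [
            UniqueSequence(f"s{i}", int(rng.integers(1, 400)),
                           variant(base_seq, rng.choice(220, size=int(rng.integers(1, 5)), replace=False)))
            for i in range(20)
        ]
        retained, _ = frequency_filter(pool)
        assert any(u.name == "top" for u in retained)

    def test_no_chained_removal_below_removed_sequence(self, base_seq):
        # w is close to u (removed) but not to v: it must survive, because
        # comparisons are against retained sequences only
        u = variant(base_seq, [10, 50])
        w = variant(base_seq, [10, 50, 51, 52])
        pool = [
            UniqueSequence("v", 1000, base_seq),
            UniqueSequence("u", 40, u),
            UniqueSequence("w", 30, w),
        ]
        retained, removed = frequency_filter(pool, ClusterParams(0.01, 0.10))
        assert {x.name for x in retained} == {"v", "w"}
        assert [x.name for x in removed] == ["u"]

    def test_order_invariance(self, base_seq, rng):
        pool = [
            UniqueSequence(f"s{i}", int(rng.integers(1, 1000)),
                           variant(base_seq, rng.choice(220, size=int(rng.integers(0, 4)), replace=False)))
            for i in range(25)
        ]
        ref = frequency_filter(pool)[0]
        for _ in range(3):
            perm = list(pool)
            rng.shuffle(perm)
            assert frequency_filter(perm)[0] == ref

    def test_retained_set_monotone_in_parameters(self, base_seq, rng):
        pool = [
            UniqueSequence(f"s{i}", int(rng.integers(1, 1000)),
                           variant(base_seq, rng.choice(220, size=int(rng.integers(0, 6)), replace=False)))
            for i in range(30)
        ]
        for grid, make in [
            ((0.0, 0.01, 0.02, 0.05), lambda x: ClusterParams(x, 0.10)),
            ((0.01, 0.05, 0.10, 0.5), lambda x: ClusterParams(0.01, x)),
        ]:
            previous = None
            for x in grid:
                names = {u.name for u in frequency_filter(pool, make(x))[0]}
                if previous is not None:
                    assert names <= previous
                previous = names

    def test_unequal_lengths_rejected(self):
        with pytest.raises(LengthError):
            frequency_filter(
                [UniqueSequence("a", 2, "AAAA"), UniqueSequence("b", 1, "AAA")]
            )

    def test_injected_numts_all_removed_no_parents_lost(self, base_seq, rng):
        """Numts at <10% of parent frequency and <=2 mismatches are all
        removed while every parent survives."""
        parents = {}
        seq = base_seq
        for i in range(5):
            seq = variant(seq, rng.choice(220, size=10, replace=False))
            parents[f"p{i}"] = seq
        pool = [UniqueSequence(n, 1000, s) for n, s in parents.items()]
        numts = {}
        for n, s in parents.items():
            numt = variant(s, rng.choice(220, size=int(rng.integers(1, 3)), replace=False))
            numts[f"{n}_numt"] = numt
            pool.append(UniqueSequence(f"{n}_numt", int(rng.integers(10, 90)), numt))
        retained, removed = frequency_filter(pool)
        retained_names = {u.name for u in retained}
        assert retained_names == set(parents)
        assert {r.name for r in removed} == set(numts)
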