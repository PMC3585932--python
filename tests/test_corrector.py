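"""Homopolymer error correction against the consensus reference.

The independent oracle for single-indel repairs enumerates every possible
one-base deletion and one-base insertion of a read and scores each candidate
by plain character mismatches to the truth template (length differences
count as mismatches); the corrector must restore the template exactly and
never do worse than the oracle's optimum.
"""

import pytest

from pyroclean import (
    ConsensusReference,
    CorrectionParams,
    UniqueSequence,
    correct_read,
    correct_uniques,
    fix_compensated_indels,
    fix_deletions,
    fix_insertions,
)
from pyroclean.iupac import hamming
from pyroclean.simulate import _homopolymer_runs


def plain_distance(a: str, b: str) -> int:
    """Character mismatches plus length difference (no ambiguity awareness)."""
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def single_indel_oracle(read: str, template: str) -> int:
    """Best achievable distance to the template over all single-indel repairs."""
    best = plain_distance(read, template)
    for i in range(len(read)):
        best = min(best, plain_distance(read[:i] + read[i + 1 :], template))
    for i in range(len(read) + 1):
        for b in "ACGT":
            best = min(best, plain_distance(read[:i] + b + read[i:], template))
    return best


def inject_single_hp_indel(template: str, rng, margin: int = 30):
    """Insert or delete one base in a homopolymer run >= margin nt from the 3' end."""
    runs = [r for r in _homopolymer_runs(template) if r[0] <= len(template) - margin]
    if not runs:
        return None
    start, end = runs[rng.integers(0, len(runs))]
    if rng.random() < 0.5:
        return template[:start] + template[start] + template[start:]
    return template[:start] + template[start + 1 :]


class TestFixInsertions:
    def test_removes_surplus_homopolymer_base(self):
        out, ev = fix_insertions("ATTTGCA", ConsensusReference("ATTGCA"))
        assert out == "ATTGCA"
        assert [e.kind for e in ev] == ["insertion_removed"]

    def test_identical_read_untouched(self):
        out, ev = fix_insertions("ATTGCA", ConsensusReference("ATTGCA"))
        assert out == "ATTGCA" and ev == []

    def test_requires_preceding_homopolymer(self):
        out, ev = fix_insertions("ACTG", ConsensusReference("ACCG"))
        assert out == "ACTG" and ev == []

    def test_duplicated_single_base_run(self):
        out, ev = fix_insertions("AATG", ConsensusReference("ATGC"))
        assert out == "ATG"


class TestFixDeletions:
    def test_extends_adjacent_homopolymer(self):
        out, ev = fix_deletions("ATGCA", ConsensusReference("ATTGCA"))
        assert out == "ATTGCA"
        assert [e.kind for e in ev] == ["deletion_filled"]

    def test_falls_back_to_consensus_symbol(self):
        out, ev = fix_deletions("AGCA", ConsensusReference("ATGCA"))
        assert out == "ATGCA"

    def test_ambiguous_consensus_symbol_written_into_read(self):
        # no extendable homopolymer; the gap takes the consensus code itself
        out, ev = fix_deletions("TC", ConsensusReference("TRC"))
        assert out == "TRC"
        assert len(ev) == 1

    def test_growth_capped_at_max_length(self):
        out, _ = fix_deletions("ATGCA", ConsensusReference("ATTGCA"), max_length=5)
        assert out == "ATTGC"


class TestFixCompensatedIndels:
    def test_paired_indel_restored_by_homopolymer_extension(self):
        out, ev = fix_compensated_indels("AAAGCTGCC", ConsensusReference("AAGCTTGCC"))
        assert out == "AAGCTTGCC"
        assert [e.kind for e in ev] == ["compensation"]

    def test_pure_substitutions_left_alone(self):
        # two true substitutions: no paired indel explains them
        out, ev = fix_compensated_indels("ATCGATCG", ConsensusReference("ATCCATGG"))
        assert out == "ATCGATCG" and ev == []

    def test_tied_flanks_get_joint_ambiguity_code(self):
        # frozen regression: gap flanked by A and G, neither/both consistent,
        # so the joint code R = {A,G} is written
        out, ev = fix_compensated_indels("ATAGACAGG", ConsensusReference("AWACCATCA"))
        assert len(ev) == 1
        assert "R" in out
        cons = ConsensusReference("AWACCATCA")
        assert hamming(out, cons.sequence) < hamming("ATAGACAGG", cons.sequence)


class TestCorrectRead:
    def test_error_free_read_unchanged(self, templates, template_consensus):
        seq = next(iter(templates.values()))
        res = correct_read(seq, template_consensus)
        assert res.sequence == seq and res.events == ()

    def test_edit_cap_flagged(self):
        res = correct_read(
            "ATTTGGGA", ConsensusReference("ATTGGACC"), CorrectionParams(edit_cap=1)
        )
        assert res.cap_hit

    def test_mismatch_total_never_increases(self, rng):
        bases = list("ACGT")
        for _ in range(200):
            n = int(rng.integers(10, 60))
            cons_seq = "".join(rng.choice(bases, size=n))
            read = "".join(rng.choice(bases, size=int(rng.integers(5, n))))
            cons = ConsensusReference(cons_seq)
            res = correct_read(read, cons)
            before = hamming(read, cons_seq[: len(read)])
            after = hamming(res.sequence, cons_seq[: len(res.sequence)])
            assert after <= before
            assert "-" not in res.sequence

    def test_idempotent(self, templates, template_consensus, small_simulation):
        reads, _ = small_simulation
        for r in reads[:150]:
            once = correct_read(r.sequence, template_consensus)
            twice = correct_read(once.sequence, template_consensus)
            if not once.cap_hit:
                assert twice.sequence == once.sequence
                assert twice.events == ()

    def test_single_indel_reads_recovered_and_oracle_optimal(self, rng):
        """Reads with one homopolymer indel >=30 nt from the 3' end are
        restored to their template; no repair beats the brute-force oracle."""
        n_reads, n_exact = 300, 0
        made = 0
        while made < n_reads:
            template = "".join(rng.choice(list("ACGT"), size=220))
            read = inject_single_hp_indel(template, rng)
            if read is None:
                continue
            made += 1
            cons = ConsensusReference(template)
            res = correct_read(read, cons, CorrectionParams(max_length=220))
            if res.sequence == template:
                n_exact += 1
            oracle_best = single_indel_oracle(read, template)
            achieved = plain_distance(res.sequence, template)
            assert achieved <= oracle_best
        assert n_exact / n_reads >= 0.99

    def test_edlib_confirms_exact_restoration(self, rng):
        edlib = pytest.importorskip("edlib")
        restored = 0
        for _ in range(50):
            template = "".join(rng.choice(list("ACGT"), size=220))
            read = inject_single_hp_indel(template, rng)
            if read is None:
                continue
            res = correct_read(read, ConsensusReference(template))
            restored += edlib.align(res.sequence, template)["editDistance"] == 0
        assert restored >= 45


class TestCorrectUniques:
    def test_collisions_merge_and_counts_conserved(self, template_consensus, templates):
        t = next(iter(templates.values()))
        # two distinct corrupted forms of the same template plus the template
        u = [
            UniqueSequence("a", 5, t),
            UniqueSequence("b", 2, t[:50] + t[50] + t[50:]),  # hp insertion
            UniqueSequence("c", 1, t[:100] + t[101:]),  # hp-adjacent deletion
        ]
        corrected, events, n_capped = correct_uniques(
            u, template_consensus, CorrectionParams(max_length=220)
        )
        assert sum(x.count for x in corrected) == 8
        assert corrected[0].sequence == t and corrected[0].count >= 7
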