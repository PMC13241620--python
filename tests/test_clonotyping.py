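"""Clonotyping unit and property tests, including the independent
all-pairs single-linkage brute-force oracle."""

import numpy as np
import pytest

from immunorep import clonotyping
from immunorep.clonotyping import (
    Clone,
    ClonotypingConfig,
    assign_clones,
    cdr3_identity,
    gene_name,
    partition_group,
)

from conftest import make_record, make_repertoire

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Independent oracle: breadth-first search over the all-pairs identity graph.

def oracle_identity(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x == y and x != "N") / len(a)


def oracle_components(seqs: list[str], threshold: float) -> set[frozenset]:
    n = len(seqs)
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            k = frontier.pop()
            for j in range(n):
                if j not in comp and oracle_identity(seqs[k], seqs[j]) >= threshold:
                    comp.add(j)
                    frontier.append(j)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def random_group(rng, max_seqs=12):
    """Records sharing (locus, V, J, length) with borderline identities."""
    length = int(rng.integers(3, 16)) * 3  # 9..45 nt
    n = int(rng.integers(2, max_seqs + 1))
    base = "".join(BASES[i] for i in rng.integers(0, 4, length))
    seqs = []
    for _ in range(n):
        seq = list(base)
        for pos in rng.choice(length, size=int(rng.integers(0, length // 3 + 1)), replace=False):
            seq[pos] = BASES[int(rng.integers(0, 4))]
        seqs.append("".join(seq))
    records = [
        make_record(
            cdr3_nt=s, cdr3_aa="", sequence_id=f"r{i}",
            v_call="TRBV7-2*01", j_call="TRBJ2-1*01", locus="TRB",
            read_count=int(rng.integers(1, 10)),
        )
        for i, s in enumerate(seqs)
    ]
    return seqs, records


class TestCdr3Identity:
    def test_identical(self):
        assert cdr3_identity("ATGCATGC", "ATGCATGC") == 1.0

    def test_seven_of_eight(self):
        assert cdr3_identity("ATGCATGC", "ATGCATGG") == pytest.approx(0.875)

    def test_eighteen_of_twenty(self):
        a = "ATGCATGCATGCATGCATGC"
        b = "ATGCATGCATGCATGCATTT"
        # oracle: position-wise count
        assert oracle_identity(a, b) == pytest.approx(0.90)
        assert cdr3_identity(a, b) == pytest.approx(0.90)

    def test_symmetric(self, rng):
        for _ in range(20):
            length = int(rng.integers(1, 30))
            a = "".join(BASES[i] for i in rng.integers(0, 4, length))
            b = "".join(BASES[i] for i in rng.integers(0, 4, length))
            assert cdr3_identity(a, b) == cdr3_identity(b, a)

    def test_n_never_matches(self):
        assert cdr3_identity("NNNN", "NNNN") == 0.0
        assert cdr3_identity("ANGC", "ANGC") == pytest.approx(0.75)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            cdr3_identity("ATG", "ATGC")


class TestPartitionGroup:
    def test_chain_linkage_merges_transitively(self):
        # id(A,B)=0.95, id(B,C)=0.95, id(A,C)=0.90 at threshold 0.95 -> one clone
        a = "A" * 20
        b = "A" * 19 + "T"  # differs from a at position 19
        c = "A" * 18 + "TT"  # differs from b at position 18, from a at 18 and 19
        assert oracle_identity(a, b) == pytest.approx(0.95)
        assert oracle_identity(b, c) == pytest.approx(0.95)
        assert oracle_identity(a, c) == pytest.approx(0.90)
        records = [
            make_record(cdr3_nt=s, cdr3_aa="", sequence_id=f"r{i}")
            for i, s in enumerate([a, b, c])
        ]
        clones = partition_group(records, 0.95)
        assert len(clones) == 1
        assert len(clones[0].members) == 3

    def test_identical_sequences_single_clone(self):
        records = [
            make_record(sequence_id="x", read_count=5),
            make_record(sequence_id="y", read_count=3),
        ]
        clones = partition_group(records, 1.0)
        assert len(clones) == 1
        assert clones[0].total_reads == 8

    def test_below_threshold_splits(self):
        a = "ATGCATGCATGCATGCATGC"
        b = list(a)
        for pos in (0, 5, 10):
            b[pos] = "T" if a[pos] != "T" else "G"
        b = "".join(b)
        assert oracle_identity(a, b) == pytest.approx(0.85)
        records = [
            make_record(cdr3_nt=s, cdr3_aa="", sequence_id=f"r{i}") for i, s in enumerate([a, b])
        ]
        assert len(partition_group(records, 0.90)) == 2

    def test_mixed_key_rejected(self):
        records = [
            make_record(sequence_id="a"),
            make_record(sequence_id="b", v_call="TRBV19*01"),
        ]
        with pytest.raises(ValueError, match="b"):
            partition_group(records, 0.9)

    def test_representative_is_lexicographic_min(self):
        records = [
            make_record(cdr3_nt="TTTGCCAGCAGCTTATTTTTT", cdr3_aa="", sequence_id="a"),
            make_record(cdr3_nt="TGTGCCAGCAGCTTATTTTTT", cdr3_aa="", sequence_id="b"),
        ]
        clones = partition_group(records, 0.90)
        assert len(clones) == 1
        assert clones[0].representative_cdr3 == "TGTGCCAGCAGCTTATTTTTT"

    @pytest.mark.parametrize("threshold", [0.90, 0.95])
    def test_oracle_equivalence_random_groups(self, rng, threshold):
        for _ in range(100):
            seqs, records = random_group(rng)
            clones = partition_group(records, threshold)
            got = {
                frozenset(int(m.sequence_id[1:]) for m in c.members) for c in clones
            }
            assert got == oracle_components(seqs, threshold)

    def test_permutation_invariance(self, rng):
        seqs, records = random_group(rng)
        reference = partition_group(records, 0.90)
        for _ in range(5):
            shuffled = list(records)
            rng.shuffle(shuffled)
            again = partition_group(shuffled, 0.90)
            assert [c.clone_id for c in again] == [c.clone_id for c in reference]
            assert [
                [m.sequence_id for m in c.members] for c in again
            ] == [[m.sequence_id for m in c.members] for c in reference]

    def test_threshold_monotonicity(self, rng):
        for _ in range(30):
            seqs, records = random_group(rng)
            sizes = [
                len(partition_group(records, t)) for t in (0.80, 0.90, 0.95, 1.0)
            ]
            assert sizes == sorted(sizes)


class TestAssignClones:
    def test_single_record(self):
        rep = make_repertoire([make_record(read_count=7)])
        cs = assign_clones(rep)
        assert cs.n_unique == 1
        assert cs.n_reads == 7

    def test_gene_vs_allele_level(self):
        records = [
            make_record(v_call="TRBV7-2*01", sequence_id="a"),
            make_record(v_call="TRBV7-2*02", sequence_id="b"),
        ]
        rep = make_repertoire(records)
        assert assign_clones(rep, ClonotypingConfig(gene_match_level="gene")).n_unique == 1
        assert assign_clones(rep, ClonotypingConfig(gene_match_level="allele")).n_unique == 2

    def test_empty_repertoire(self):
        cs = assign_clones(make_repertoire([]))
        assert cs.n_unique == 0
        assert cs.n_reads == 0

    def test_read_conservation(self, trb_repertoire):
        cs = assign_clones(trb_repertoire)
        assert cs.n_reads == sum(r.read_count for r in trb_repertoire)

    def test_missing_vj_goes_unassigned(self):
        records = [
            make_record(sequence_id="ok"),
            make_record(v_call="", sequence_id="nov"),
        ]
        cs = assign_clones(make_repertoire(records))
        assert cs.n_unique == 1
        assert cs.n_unassigned == 1

    def test_clone_ids_deterministic(self, trb_repertoire):
        ids1 = [c.clone_id for c in assign_clones(trb_repertoire).clones]
        ids2 = [c.clone_id for c in assign_clones(trb_repertoire).clones]
        assert ids1 == ids2


class TestConfig:
    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            ClonotypingConfig(bcr_identity_threshold=0.0)
        with pytest.raises(ValueError):
            ClonotypingConfig(tcr_identity_threshold=1.5)

    def test_gene_name_strips_allele(self):
        assert gene_name("TRBV7-2*01") == "TRBV7-2"
        assert gene_name("TRBV7-2*01", level="allele") == "TRBV7-2*01"

    def test_threshold_for_locus_class(self):
        cfg = ClonotypingConfig()
        assert cfg.threshold_for("IGH") == 0.90
        assert cfg.threshold_for("TRB") == 0.95
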