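"""Clonotype assignment, checked against brute-force transitive closure."""

import numpy as np
import pytest

from repdeplete.clonotyping import (
    assign_bcr_clonotypes,
    assign_tcr_clonotypes,
    cluster_junctions,
    junction_distance,
    partition_vj_groups,
)
from repdeplete.errors import LocusError, ValidationError

from conftest import make_rec, make_sample


def _partition(clones):
    """Clone assignments as an order-free partition of sequence_ids."""
    return {frozenset(c.member_ids) for c in clones}


def brute_force_bcr_partition(records, threshold):
    """All-pairs Hamming + transitive closure within V/J/length groups."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    def key(r):
        return (r.v_call.split("*")[0], r.j_call.split("*")[0], len(r.junction))

    for i in range(n):
        for j in range(i + 1, n):
            if key(records[i]) != key(records[j]):
                continue
            if junction_distance(records[i].junction, records[j].junction) <= threshold:
                parent[find(j)] = find(i)
    groups = {}
    for i, r in enumerate(records):
        groups.setdefault(find(i), set()).add(r.sequence_id)
    return {frozenset(g) for g in groups.values()}


# --- TCR -------------------------------------------------------------------


def test_tcr_identical_sequences_share_a_clone(trb_sample):
    clones = assign_tcr_clonotypes(trb_sample)
    assert len(clones) == 2
    assert sorted(c.size_sequences for c in clones) == [1, 2]


def test_tcr_duplicate_counts_sum_into_molecules():
    sample = make_sample(
        [
            make_rec("a", sequence="AAAACCCCGGGG", duplicate_count=5),
            make_rec("b", sequence="AAAACCCCGGGG", duplicate_count=2),
        ]
    )
    (clone,) = assign_tcr_clonotypes(sample)
    assert clone.size_molecules == 7
    assert clone.size_sequences == 2


def test_tcr_all_distinct_gives_one_clone_per_record():
    sample = make_sample(
        [make_rec(f"r{i}", sequence=f"{'ACGT' * 2}{'ACGT'[i] * 4}") for i in range(4)]
    )
    assert len(assign_tcr_clonotypes(sample)) == 4


def test_tcr_rejects_igh():
    sample = make_sample([make_rec("a", locus="IGH")], locus="IGH")
    with pytest.raises(LocusError):
        assign_tcr_clonotypes(sample)


# --- V/J partition ----------------------------------------------------------


def test_partition_truncates_alleles_to_genes():
    sample = make_sample(
        [
            make_rec("a", locus="IGH", v_call="IGHV3-23*01", j_call="IGHJ4*01"),
            make_rec("b", locus="IGH", v_call="IGHV3-23*04", j_call="IGHJ4*02"),
        ],
        locus="IGH",
    )
    groups = partition_vj_groups(sample)
    assert len(groups) == 1
    assert ("IGHV3-23", "IGHJ4", 12) in groups


def test_partition_separates_junction_lengths():
    sample = make_sample(
        [
            make_rec("a", locus="IGH", junction="A" * 12),
            make_rec("b", locus="IGH", junction="A" * 15),
        ],
        locus="IGH",
    )
    assert len(partition_vj_groups(sample)) == 2


def test_partition_rejects_empty_v_call():
    sample = make_sample([make_rec("a", v_call="")])
    with pytest.raises(ValidationError):
        partition_vj_groups(sample)


# --- junction clustering ----------------------------------------------------


def test_one_mismatch_within_threshold_merges_four_split():
    base = "ATGCATGCATGC"  # L = 12
    near = "TTGCATGCATGC"  # d = 1/12 = 0.083
    far = "TTTTATGCATGC"   # d = 4/12 = 0.333
    group = [make_rec("a", junction=base), make_rec("b", junction=near),
             make_rec("c", junction=far)]
    clusters = cluster_junctions(group, threshold=0.15)
    partition = {frozenset(r.sequence_id for r in cl) for cl in clusters}
    assert partition == {frozenset({"a", "b"}), frozenset({"c"})}


def test_single_linkage_chains_merge():
    # pairwise: A-B 0.1, B-C 0.1, A-C 0.2; threshold 0.15 chains all three
    a = "AAAAAAAAAA"
    b = "AAAAAAAAAC"
    c = "AAAAAAAACC"
    assert junction_distance(a, c) == pytest.approx(0.2)
    clusters = cluster_junctions(
        [make_rec("A", junction=a), make_rec("B", junction=b), make_rec("C", junction=c)],
        threshold=0.15,
    )
    assert len(clusters) == 1


def test_n_positions_do_not_count_as_mismatch():
    assert junction_distance("ATNC", "ATGC") == 0.0


def test_unequal_lengths_are_a_contract_violation():
    with pytest.raises(ValidationError):
        cluster_junctions(
            [make_rec("a", junction="AAA"), make_rec("b", junction="AAAA")], 0.1
        )


# --- BCR assignment ---------------------------------------------------------


def test_different_j_genes_never_merge():
    sample = make_sample(
        [
            make_rec("a", locus="IGH", j_call="IGHJ1*01", junction="A" * 12),
            make_rec("b", locus="IGH", j_call="IGHJ2*01", junction="A" * 12),
        ],
        locus="IGH",
    )
    assert len(assign_bcr_clonotypes(sample)) == 2


def test_empty_sample_yields_empty_assignment():
    assert assign_bcr_clonotypes(make_sample([], locus="IGH")) == []


def _random_igh_sample(rng, n=30):
    """Records with planted lineage structure for oracle comparison."""
    bases = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(6)]
    records = []
    for i in range(n):
        base = bases[rng.integers(0, len(bases))]
        junction = list(base)
        for _ in range(rng.integers(0, 3)):
            junction[rng.integers(0, 12)] = "ACGT"[rng.integers(0, 4)]
        records.append(
            make_rec(
                f"r{i}",
                locus="IGH",
                v_call=f"IGHV{rng.integers(1, 3)}-1*0{rng.integers(1, 3)}",
                j_call=f"IGHJ{rng.integers(1, 3)}*01",
                junction="".join(junction),
                duplicate_count=int(rng.integers(1, 5)),
            )
        )
    return make_sample(records, locus="IGH")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_bcr_assignment_matches_all_pairs_oracle(seed):
    rng = np.random.default_rng(seed)
    sample = _random_igh_sample(rng)
    clones = assign_bcr_clonotypes(sample, threshold=0.15)
    assert _partition(clones) == brute_force_bcr_partition(sample.records, 0.15)


def test_partition_property_sizes_sum_to_record_count():
    rng = np.random.default_rng(5)
    sample = _random_igh_sample(rng, n=40)
    clones = assign_bcr_clonotypes(sample)
    assert sum(c.size_sequences for c in clones) == len(sample)
    assert sum(c.size_molecules for c in clones) == sample.total_molecules


def test_threshold_monotonicity_and_zero_threshold():
    rng = np.random.default_rng(7)
    sample = _random_igh_sample(rng, n=40)
    counts = [
        len(assign_bcr_clonotypes(sample, threshold=t))
        for t in (0.0, 0.05, 0.1, 0.2, 0.4)
    ]
    assert counts == sorted(counts, reverse=True)
    # threshold 0 reduces to exact-junction grouping within V/J/length groups
    exact = {
        (r.v_call.split("*")[0], r.j_call.split("*")[0], r.junction)
        for r in sample.records
    }
    assert counts[0] == len(exact)


def test_clone_membership_invariant_to_record_order():
    rng = np.random.default_rng(11)
    sample = _random_igh_sample(rng, n=30)
    clones = assign_bcr_clonotypes(sample)
    shuffled = make_sample(
        [sample.records[i] for i in rng.permutation(len(sample.records))],
        locus="IGH",
    )
    clones_shuffled = assign_bcr_clonotypes(shuffled)
    assert _partition(clones) == _partition(clones_shuffled)
    # deterministic labelling survives reordering too
    assert {c.clone_id: c.member_ids for c in clones} == {
        c.clone_id: c.member_ids for c in clones_shuffled
    }
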