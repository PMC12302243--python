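"""Clonotype assignment.

A T-cell clonotype is defined by identical full nucleotide sequence (TRB/TRD).
A B-cell clonotype (IGH) is an inferred clonal lineage: records are first
partitioned by (V gene, J gene, junction length) and then single-linkage
clustered on normalized junction Hamming distance, so two sequences belong to
one lineage iff they are connected by a chain of pairs within the threshold.
Ambiguous (N) junction positions are treated as matches, which merges rather
than splits lineages on sequencing ambiguity.

Clone identifiers are deterministic: clones are sorted by descending molecule
count, then by their lexicographically smallest member sequence, so labels do
not depend on input record order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .airr_io import Rearrangement, RepertoireSample
from .errors import LocusError, ValidationError

DEFAULT_BCR_THRESHOLD = 0.15

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class CloneAssignment:
    """One clone: its identifier, members, and size in two units."""

    clone_id: str
    member_ids: frozenset
    size_molecules: int
    size_sequences: int

    def __post_init__(self) -> None:
        if not (self.size_molecules >= self.size_sequences >= 1):
            raise ValidationError(
                f"{self.clone_id}: sizes violate molecules >= sequences >= 1"
            )


def gene_of(call: str) -> str:
    """Gene-level name of an allele call (truncate at '*')."""
    return call.split("*")[0]


def junction_distance(a: str, b: str) -> float:
    """Normalized Hamming distance between equal-length junctions.

    Positions where either character is not an unambiguous nucleotide (e.g. N)
    do not count as mismatches; the denominator is the junction length.
    """
    if len(a) != len(b):
        raise ValidationError("junction lengths differ")
    if len(a) == 0:
        raise ValidationError("empty junction")
    mismatches = sum(
        1 for x, y in zip(a, b) if x != y and x in _ACGT and y in _ACGT
    )
    return mismatches / len(a)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _label_clones(
    groups: Sequence[Sequence[Rearrangement]], locus: str
) -> list[CloneAssignment]:
    """Sort clone member groups deterministically and assign identifiers."""

    def sort_key(members: Sequence[Rearrangement]):
        molecules = sum(r.duplicate_count for r in members)
        min_seq = min(r.sequence or r.junction for r in members)
        return (-molecules, min_seq, gene_of(members[0].v_call), gene_of(members[0].j_call))

    ordered = sorted(groups, key=sort_key)
    clones = []
    for i, members in enumerate(ordered):
        clones.append(
            CloneAssignment(
                clone_id=f"{locus}_C{i + 1:06d}",
                member_ids=frozenset(r.sequence_id for r in members),
                size_molecules=sum(r.duplicate_count for r in members),
                size_sequences=len(members),
            )
        )
    return clones


def assign_tcr_clonotypes(sample: RepertoireSample) -> list[CloneAssignment]:
    """Group a TRB/TRD sample into identical-nucleotide-sequence clonotypes."""
    if sample.locus not in ("TRB", "TRD"):
        raise LocusError(f"TCR clonotyping requires TRB/TRD, got {sample.locus}")
    by_seq: dict[str, list[Rearrangement]] = {}
    for r in sample.records:
        if r.sequence is None:
            raise ValidationError(f"{r.sequence_id}: missing nucleotide sequence")
        by_seq.setdefault(r.sequence, []).append(r)
    return _label_clones(list(by_seq.values()), sample.locus)


def partition_vj_groups(
    sample: RepertoireSample,
) -> dict[tuple[str, str, int], list[Rearrangement]]:
    """Partition records by (V gene, J gene, junction length).

    Alleles of one gene (split at '*') land in the same group; this is the
    standard preamble to distance-based lineage clustering.
    """
    groups: dict[tuple[str, str, int], list[Rearrangement]] = {}
    for r in sample.records:
        if not r.v_call:
            raise ValidationError(f"{r.sequence_id}: empty v_call")
        if not r.j_call:
            raise ValidationError(f"{r.sequence_id}: empty j_call")
        key = (gene_of(r.v_call), gene_of(r.j_call), len(r.junction))
        groups.setdefault(key, []).append(r)
    return groups


def cluster_junctions(
    group: Sequence[Rearrangement], threshold: float
) -> list[list[Rearrangement]]:
    """Single-linkage clusters of a V/J/length group at a junction threshold.

    Two records share a cluster iff connected by a chain of pairs with
    normalized Hamming distance <= threshold (transitive closure).
    """
    records = list(group)
    if not records:
        return []
    lengths = {len(r.junction) for r in records}
    if len(lengths) != 1:
        raise ValidationError("cluster_junctions requires equal junction lengths")
    if lengths == {0}:
        raise ValidationError("cluster_junctions requires junction length > 0")

    # collapse identical junctions first: they are always one linkage node
    by_junction: dict[str, list[Rearrangement]] = {}
    for r in records:
        by_junction.setdefault(r.junction, []).append(r)
    junctions = sorted(by_junction)
    uf = _UnionFind(len(junctions))
    for i in range(len(junctions)):
        for j in range(i + 1, len(junctions)):
            if junction_distance(junctions[i], junctions[j]) <= threshold:
                uf.union(i, j)
    clusters: dict[int, list[Rearrangement]] = {}
    for i, junction in enumerate(junctions):
        clusters.setdefault(uf.find(i), []).extend(by_junction[junction])
    return list(clusters.values())


def assign_bcr_clonotypes(
    sample: RepertoireSample, threshold: float = DEFAULT_BCR_THRESHOLD
) -> list[CloneAssignment]:
    """Cluster an IGH sample into clonal lineages.

    Composition of :func:`partition_vj_groups` and :func:`cluster_junctions`
    per group, with deterministic clone identifiers.
    """
    if sample.locus != "IGH":
        raise LocusError(f"BCR clonotyping requires IGH, got {sample.locus}")
    member_groups: list[list[Rearrangement]] = []
    groups = partition_vj_groups(sample)
    for key in sorted(groups):
        member_groups.extend(cluster_junctions(groups[key], threshold))
    return _label_clones(member_groups, sample.locus)


def assign_clonotypes(
    sample: RepertoireSample, threshold: float = DEFAULT_BCR_THRESHOLD
) -> list[CloneAssignment]:
    """Dispatch to the locus-appropriate clonotype definition."""
    if sample.locus == "IGH":
        return assign_bcr_clonotypes(sample, threshold)
    return assign_tcr_clonotypes(sample)


def annotate_clones(
    sample: RepertoireSample, clones: Iterable[CloneAssignment]
) -> RepertoireSample:
    """Return a copy of the sample with clone_id filled in on each record."""
    by_member: dict[str, str] = {}
    for clone in clones:
        for sid in clone.member_ids:
            by_member[sid] = clone.clone_id
    records = []
    for r in sample.records:
        rec = Rearrangement(**{**r.__dict__, "clone_id": by_member.get(r.sequence_id)})
        records.append(rec)
    return sample.with_records(records)
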