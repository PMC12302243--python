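"""Repertoire architecture and longitudinal tracking statistics.

Clonality is 1 minus Pielou evenness (normalized Shannon entropy) of clone
molecule frequencies: 0 for a perfectly even repertoire, 1 for a monoclonal
one (single-clone repertoires are 1 by convention).

Sample overlap follows the sequence-tracking design: the proportion of
follow-up molecules whose nucleotide sequence was already detected in a
(capped, seeded subsample of the) baseline sample.  Top-N overlap compares
the N most expanded clonotypes of two timepoints by nucleotide sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .airr_io import RepertoireSample
from .clonotyping import CloneAssignment
from .errors import LocusError, ValidationError
from .resampling import subsample


@dataclass
class AbundanceVector:
    """Clone molecule counts plus, optionally, a clone -> sequence key."""

    counts: dict[str, int]
    key: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValidationError("abundance counts must be >= 1")

    @property
    def total_molecules(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)


@dataclass
class OverlapResult:
    """Fraction of a follow-up sample traceable to baseline."""

    overlap_fraction: float
    n_followup_evaluated: int
    n_baseline_reference: int


def abundance_from_clones(
    clones: Sequence[CloneAssignment],
    sample: Optional[RepertoireSample] = None,
) -> AbundanceVector:
    """Build an abundance vector from clone assignments.

    When ``sample`` is given, each clone is keyed by its lexicographically
    smallest member nucleotide sequence (used for cross-timepoint tracking).
    """
    counts = {c.clone_id: c.size_molecules for c in clones}
    key = None
    if sample is not None:
        by_id = {r.sequence_id: r for r in sample.records}
        key = {
            c.clone_id: min(
                by_id[sid].sequence or by_id[sid].junction for sid in c.member_ids
            )
            for c in clones
        }
    return AbundanceVector(counts=counts, key=key)


def clonality(abundance: AbundanceVector) -> float:
    """1 - H/ln(R): normalized deviation from an even clone-size distribution."""
    counts = list(abundance.counts.values())
    if not counts:
        raise ValidationError("clonality: empty abundance vector")
    if len(counts) == 1:
        return 1.0
    total = sum(counts)
    entropy = -sum((c / total) * math.log(c / total) for c in counts)
    return 1.0 - entropy / math.log(len(counts))


def _ranked_clones(abundance: AbundanceVector) -> list[str]:
    """Clone ids by descending molecule count; ties by sequence key then id."""
    if abundance.key is not None:
        return sorted(
            abundance.counts,
            key=lambda cid: (-abundance.counts[cid], abundance.key[cid], cid),
        )
    return sorted(abundance.counts, key=lambda cid: (-abundance.counts[cid], cid))


def top_n_proportion(abundance: AbundanceVector, n: int) -> float:
    """Share of molecules held by the n most expanded clonotypes."""
    if n < 1:
        raise ValidationError("top_n_proportion: n must be >= 1")
    ranked = _ranked_clones(abundance)[:n]
    return sum(abundance.counts[cid] for cid in ranked) / abundance.total_molecules


def sample_overlap(
    followup: RepertoireSample,
    baseline: RepertoireSample,
    baseline_cap: int = 10000,
    seed: int = 0,
) -> OverlapResult:
    """Proportion of follow-up molecules with a sequence already seen at baseline.

    The baseline is reduced to at most ``baseline_cap`` molecules by seeded
    subsampling before the reference sequence set is formed, so donors with
    deep baselines are compared against a fixed amount of baseline evidence.
    The numerator and denominator are molecule (duplicate_count) weighted.
    """
    if followup.locus != baseline.locus:
        raise LocusError(
            f"locus mismatch: {followup.locus} vs {baseline.locus}"
        )
    if len(baseline) == 0:
        raise ValidationError("sample_overlap: empty baseline")
    reference = baseline
    if baseline.total_molecules > baseline_cap:
        reference = subsample(baseline, baseline_cap, seed)
    baseline_sequences = {r.sequence or r.junction for r in reference.records}
    total = followup.total_molecules
    if total == 0:
        raise ValidationError("sample_overlap: empty follow-up")
    hit = sum(
        r.duplicate_count
        for r in followup.records
        if (r.sequence or r.junction) in baseline_sequences
    )
    return OverlapResult(
        overlap_fraction=hit / total,
        n_followup_evaluated=total,
        n_baseline_reference=reference.total_molecules,
    )


def top_n_overlap(
    baseline: AbundanceVector,
    followup: AbundanceVector,
    n: int,
    key: Optional[Mapping[str, str]] = None,
) -> float:
    """Fraction of follow-up top-n clonotypes already in the baseline top n.

    Membership is compared by nucleotide sequence (clone keys), so clone
    labels assigned independently at the two timepoints still match.  The
    denominator is min(n, follow-up richness).
    """
    if n < 1:
        raise ValidationError("top_n_overlap: n must be >= 1")
    if not baseline.counts or not followup.counts:
        raise ValidationError("top_n_overlap: empty abundance vector")

    def seq_of(ab: AbundanceVector, cid: str) -> str:
        if ab.key is not None:
            return ab.key[cid]
        if key is not None:
            return key[cid]
        raise ValidationError("top_n_overlap: no clone -> sequence key available")

    top_base = {seq_of(baseline, cid) for cid in _ranked_clones(baseline)[:n]}
    top_follow = {seq_of(followup, cid) for cid in _ranked_clones(followup)[:n]}
    return len(top_base & top_follow) / min(n, followup.richness)


def split_vd2(
    sample: RepertoireSample,
) -> tuple[RepertoireSample, RepertoireSample]:
    """Partition a TRD sample into Vd2+ (V gene TRDV2) and Vd2- subsets."""
    if sample.locus != "TRD":
        raise LocusError(f"split_vd2 requires TRD, got {sample.locus}")
    plus = [r for r in sample.records if r.v_call.split("*")[0] == "TRDV2"]
    minus = [r for r in sample.records if r.v_call.split("*")[0] != "TRDV2"]
    return sample.with_records(plus), sample.with_records(minus)
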