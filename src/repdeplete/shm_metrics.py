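"""Somatic hypermutation (SHM) quantification.

Mutations are counted over the full V-region alignment (observed
``sequence_alignment`` against inferred ``germline_alignment``), not just the
junction: a position counts iff both characters are unambiguous nucleotides
and differ; gap and N positions are excluded.

The sample summary is a two-level mean: per-sequence mutation counts are
averaged within each clonotype, and clone means are averaged unweighted
across clonotypes ("mean SHM per clonotype").  An abundance-weighted variant
(clone means weighted by clone sequence count) is available behind a flag;
the unweighted form is the default because it preserves the bimodal signature
when a repertoire holds few large germline-near clones next to small highly
mutated ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .airr_io import RepertoireSample
from .clonotyping import CloneAssignment
from .errors import ValidationError

_ACGT = frozenset("ACGT")


def count_shm(observed: str, germline: str) -> int:
    """Number of mutated positions between two equal-length gapped alignments."""
    if len(observed) != len(germline):
        raise ValidationError("alignment lengths differ")
    return sum(
        1 for o, g in zip(observed, germline) if o != g and o in _ACGT and g in _ACGT
    )


def per_sequence_shm(sample: RepertoireSample) -> dict[str, int]:
    """Per-record mutation counts keyed by sequence_id."""
    out: dict[str, int] = {}
    for r in sample.records:
        if r.sequence_alignment is None or r.germline_alignment is None:
            raise ValidationError(f"{r.sequence_id}: missing germline alignment")
        out[r.sequence_id] = count_shm(r.sequence_alignment, r.germline_alignment)
    return out


def mean_shm_per_clonotype(
    sample: RepertoireSample,
    clones: Sequence[CloneAssignment],
    weight_by_size: bool = False,
) -> float:
    """Mean over clonotypes of the mean per-sequence SHM within each clonotype.

    Duplicate counts do not enter: the within-clone mean is over unique member
    sequences.  With ``weight_by_size`` the clone means are weighted by clone
    sequence count (equivalent to a flat per-sequence mean).
    """
    if not clones:
        raise ValidationError("mean_shm_per_clonotype: no clonotypes")
    shm = per_sequence_shm(sample)
    clone_means = []
    weights = []
    for clone in clones:
        values = [shm[sid] for sid in clone.member_ids]
        clone_means.append(sum(values) / len(values))
        weights.append(len(values))
    if weight_by_size:
        return sum(m * w for m, w in zip(clone_means, weights)) / sum(weights)
    return sum(clone_means) / len(clone_means)


def mean_clonotype_size(
    clones: Sequence[CloneAssignment], unit: str = "sequences"
) -> float:
    """Mean clonotype size, in member sequences (default) or molecules."""
    if not clones:
        raise ValidationError("mean_clonotype_size: no clonotypes")
    if unit == "sequences":
        return sum(c.size_sequences for c in clones) / len(clones)
    if unit == "molecules":
        return sum(c.size_molecules for c in clones) / len(clones)
    raise ValueError(f"unknown unit {unit!r}")


@dataclass
class ShmSummary:
    """Per-sample SHM report."""

    per_sequence_shm: dict[str, int]
    mean_shm_per_clonotype: float
    mean_shm_weighted: float
    mean_clonotype_size: float
    clone_count: int


def summarize_shm(
    sample: RepertoireSample, clones: Sequence[CloneAssignment]
) -> ShmSummary:
    """SHM and clone-size summary for one sample."""
    return ShmSummary(
        per_sequence_shm=per_sequence_shm(sample),
        mean_shm_per_clonotype=mean_shm_per_clonotype(sample, clones),
        mean_shm_weighted=mean_shm_per_clonotype(sample, clones, weight_by_size=True),
        mean_clonotype_size=mean_clonotype_size(clones),
        clone_count=len(clones),
    )
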