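"""Seeded downsampling designs.

Subsampling operates at the molecule (UMI) level: each record contributes
``duplicate_count`` indistinguishable molecules, a fixed number of molecules
is drawn uniformly without replacement (multivariate hypergeometric over
records), and the draw collapses back to records with adjusted counts.

Two planning rules mirror the study design: a fixed per-sample cap, and a
matched plan where each baseline is reduced to its own follow-up depth with a
global maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .airr_io import Rearrangement, RepertoireSample
from .errors import ValidationError

DEFAULT_IGH_CAP = 10000
DEFAULT_TRB_CAP = 100000


@dataclass
class SubsamplePlan:
    """Target molecule counts per sample key, under a common cap."""

    targets: dict
    cap: int
    seed: int = 0


def subsample(sample: RepertoireSample, n: int, seed: int) -> RepertoireSample:
    """Draw exactly ``n`` molecules without replacement, deterministically.

    Raises ValidationError if ``n`` exceeds the available molecules (never
    silently truncates).  Record order is preserved; records losing all their
    molecules are dropped.
    """
    if n < 0:
        raise ValidationError("subsample: n must be >= 0")
    counts = np.array([r.duplicate_count for r in sample.records], dtype=np.int64)
    available = int(counts.sum())
    if n > available:
        raise ValidationError(
            f"subsample: requested {n} molecules but only {available} available"
        )
    if n == available:
        return sample.with_records(list(sample.records))
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(counts, n, method="marginals")
    records = []
    for r, k in zip(sample.records, drawn):
        if k > 0:
            records.append(Rearrangement(**{**r.__dict__, "duplicate_count": int(k)}))
    return sample.with_records(records)


def plan_matched(
    baseline_n: int, followup_n: int, cap: int = DEFAULT_IGH_CAP
) -> tuple[int, int]:
    """Matched baseline-to-follow-up targets with a global cap.

    The follow-up target is min(followup_n, cap); the baseline is reduced to
    the follow-up target (or to everything it has, if shallower).
    """
    if baseline_n < 0 or followup_n < 0:
        raise ValidationError("plan_matched: counts must be >= 0")
    target_followup = min(followup_n, cap)
    target_baseline = min(baseline_n, target_followup)
    return target_baseline, target_followup


def plan_fixed(samples: Mapping, cap: int, seed: int = 0) -> SubsamplePlan:
    """Fixed-cap plan: each target is min(available, cap)."""
    targets = {key: min(int(n), cap) for key, n in samples.items()}
    return SubsamplePlan(targets=targets, cap=cap, seed=seed)
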