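"""Post-depletion B-cell repertoire classification and count calibration.

Six months after the first anti-CD20 infusion, patients separate bimodally:
either few circulating B cells carrying heavily mutated receptors traceable
to baseline (residual, non-depleted differentiated cells), or comparatively
many near-germline B cells absent at baseline (reconstitution from the bone
marrow).  The working classifier thresholds the number of sequenced B cells
at follow-up; 1,000 sequenced cells corresponds to roughly 1 B cell per uL
of fresh blood via an OLS calibration against flow cytometry counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

RESIDUAL = "residual"
RECONSTITUTED = "reconstituted"

#: sequenced B cells at follow-up at/above which a repertoire counts as reconstituted
DEFAULT_THRESHOLD_CELLS = 1000

#: alternative flow-cytometry cutoff used by large trials, in B cells per uL
FLOW_CUTOFF_CELLS_PER_UL = 10.0


def classify_reconstitution(
    n_sequenced: int, threshold: int = DEFAULT_THRESHOLD_CELLS
) -> str:
    """'reconstituted' iff the sequenced B-cell count reaches the threshold.

    The comparison is inclusive (>= threshold).
    """
    if n_sequenced < 0:
        raise ValidationError("classify_reconstitution: negative count")
    return RECONSTITUTED if n_sequenced >= threshold else RESIDUAL


@dataclass
class CountCalibration:
    """OLS line mapping flow B-cell concentration to sequenced B cells."""

    slope: float
    intercept: float
    r: float
    n: int

    def predict(self, cells_per_ul: float) -> float:
        """Expected sequenced B cells at a given blood concentration."""
        return self.slope * cells_per_ul + self.intercept

    def invert(self, n_sequenced: float) -> float:
        """Blood concentration corresponding to a sequenced count."""
        return (n_sequenced - self.intercept) / self.slope


def calibrate_counts(pairs: Sequence[tuple[float, float]]) -> CountCalibration:
    """Fit sequenced-count vs flow-count by ordinary least squares.

    ``pairs`` are (cells/uL, sequenced count); requires at least three pairs
    and a nonconstant predictor.
    """
    if len(pairs) < 3:
        raise InsufficientDataError("calibrate_counts: need >= 3 paired points")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.all(x == x[0]):
        raise ValidationError("calibrate_counts: constant predictor, degenerate fit")
    fit = stats.linregress(x, y)
    return CountCalibration(
        slope=float(fit.slope), intercept=float(fit.intercept), r=float(fit.rvalue), n=len(x)
    )


@dataclass
class BimodalityReport:
    """Per-donor follow-up metrics, calls, and rank correlations."""

    per_donor: pd.DataFrame
    correlations: dict
    threshold_cells: int


def bimodality_report(
    cohort: pd.DataFrame, threshold: int = DEFAULT_THRESHOLD_CELLS
) -> BimodalityReport:
    """Classify each donor and correlate SHM/overlap with follow-up B counts.

    ``cohort`` needs one row per donor with columns ``donor_id``,
    ``n_sequenced_m06``, ``mean_shm_m06`` and optionally ``overlap_m06`` and
    ``mean_shm_m00``.  Spearman correlations are reported for mean SHM vs
    count at both timepoints' SHM, and overlap vs count, all against the
    follow-up count (the count scale spans orders of magnitude, so rank
    correlation is used).
    """
    if len(cohort) < 2:
        raise InsufficientDataError("bimodality_report: need >= 2 donors")
    out = cohort.copy()
    out["call"] = [
        classify_reconstitution(int(n), threshold) for n in out["n_sequenced_m06"]
    ]
    correlations: dict[str, float] = {}

    def rho(col: str, name: str) -> None:
        if col in out.columns and out[col].notna().all():
            result = stats.spearmanr(out[col], out["n_sequenced_m06"])
            correlations[name] = float(result.statistic)

    rho("mean_shm_m06", "shm_vs_count_m06")
    rho("mean_shm_m00", "shm_vs_count_m00")
    rho("overlap_m06", "overlap_vs_count_m06")
    return BimodalityReport(per_donor=out, correlations=correlations, threshold_cells=threshold)
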