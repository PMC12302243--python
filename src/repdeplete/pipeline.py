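"""End-to-end cohort analysis over a sample manifest.

For every donor/locus pair in the manifest the pipeline applies the study
design: productive filtering, locus-specific downsampling (matched
baseline-to-follow-up with a 10,000-molecule cap for anti-CD20 treated IGH,
a fixed 10,000 cap for control IGH, a 100,000 cap for TRB), clonotyping,
repertoire metrics, longitudinal tracking and reconstitution classification,
then summarizes each cohort's baseline/follow-up shift with paired Wilcoxon
signed-rank tests.  Every random step is seeded from one root seed through
per-sample derived streams, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import derive_seed
from .airr_io import RepertoireSample, filter_productive, read_rearrangements
from .clonotyping import assign_clonotypes
from .errors import InsufficientDataError
from .reconstitution import DEFAULT_THRESHOLD_CELLS, bimodality_report
from .repertoire_metrics import (
    abundance_from_clones,
    clonality,
    sample_overlap,
    split_vd2,
    top_n_overlap,
    top_n_proportion,
)
from .resampling import DEFAULT_IGH_CAP, DEFAULT_TRB_CAP, plan_matched, subsample
from .shm_metrics import summarize_shm

logger = logging.getLogger(__name__)

#: per-sample metrics compared M00 vs M06 within each cohort
_PAIRED_METRICS = {
    "IGH": ("mean_shm", "mean_clone_size", "clonality"),
    "TRB": ("top_n_proportion", "clonality"),
    "TRD": ("clonality",),
}


@dataclass
class PipelineConfig:
    """Analysis options (defaults follow the study design)."""

    bcr_threshold: float = 0.15
    igh_cap: int = DEFAULT_IGH_CAP
    trb_cap: int = DEFAULT_TRB_CAP
    top_n_trb: int = 100
    top_n_trd: int = 25
    reconstitution_threshold: int = DEFAULT_THRESHOLD_CELLS
    productive_only: bool = True


@dataclass
class CohortReport:
    """Tables produced by one pipeline run."""

    samples: pd.DataFrame
    donors: pd.DataFrame
    comparisons: pd.DataFrame
    reconstitution: dict
    seed: int
    log: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, float) and math.isnan(obj):
                return None
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(
            {
                "seed": self.seed,
                "samples": self.samples.to_dict(orient="records"),
                "donors": self.donors.to_dict(orient="records"),
                "comparisons": self.comparisons.to_dict(orient="records"),
                "reconstitution": self.reconstitution,
            }
        )


def paired_wilcoxon(
    values_m00: Sequence[float], values_m06: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on within-donor differences.

    Zero differences are dropped (standard convention); requires at least
    five complete pairs and at least one nonzero difference after dropping.
    """
    x = np.asarray(values_m00, dtype=float)
    y = np.asarray(values_m06, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("paired_wilcoxon: unequal pair vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise InsufficientDataError("paired_wilcoxon: fewer than 5 complete pairs")
    diffs = y - x
    diffs = diffs[diffs != 0]
    if len(diffs) < 5:
        raise InsufficientDataError(
            "paired_wilcoxon: fewer than 5 nonzero differences after zero-dropping"
        )
    method = "exact" if len(diffs) <= 25 else "approx"
    result = stats.wilcoxon(diffs, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _analyze_sample(
    sample: RepertoireSample, config: PipelineConfig
) -> tuple[dict, list, RepertoireSample]:
    """Per-sample metrics after downsampling; returns (metrics, clones, sample)."""
    clones = assign_clonotypes(sample, config.bcr_threshold)
    abundance = abundance_from_clones(clones, sample)
    metrics = {
        "n_molecules_analyzed": sample.total_molecules,
        "n_records_analyzed": len(sample),
        "clone_count": len(clones),
        "clonality": clonality(abundance),
    }
    if sample.locus == "IGH":
        shm = summarize_shm(sample, clones)
        metrics["mean_shm"] = shm.mean_shm_per_clonotype
        metrics["mean_shm_weighted"] = shm.mean_shm_weighted
        metrics["mean_clone_size"] = shm.mean_clonotype_size
    if sample.locus == "TRB":
        metrics["top_n_proportion"] = top_n_proportion(abundance, config.top_n_trb)
    return metrics, clones, sample


def run_pipeline(
    manifest,
    seed: int = 0,
    config: Optional[PipelineConfig] = None,
    out_dir=None,
    base_dir=None,
) -> CohortReport:
    """Run the full analysis over a manifest of AIRR TSV samples.

    ``manifest`` is a DataFrame or TSV path with columns donor_id, cohort,
    timepoint, locus, path.  Relative paths resolve against ``base_dir`` (or
    the manifest's directory).  If ``out_dir`` is given, report.json,
    report.tsv and log.jsonl are written there.
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if base_dir is None:
            base_dir = manifest_path.parent
        manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
    base_dir = Path(base_dir) if base_dir is not None else Path(".")

    events: list[dict] = []

    def log_event(**kw) -> None:
        events.append(kw)

    log_event(event="start", seed=seed, n_manifest_rows=len(manifest))

    sample_rows: list[dict] = []
    donor_rows: list[dict] = []

    for (donor_id, cohort, locus), grp in manifest.groupby(
        ["donor_id", "cohort", "locus"], sort=True
    ):
        by_tp: dict[str, RepertoireSample] = {}
        for row in grp.itertuples(index=False):
            path = base_dir / row.path
            try:
                sample = read_rearrangements(
                    path,
                    locus_filter=locus,
                    donor_id=donor_id,
                    timepoint=row.timepoint,
                    cohort=cohort,
                )
            except Exception as exc:  # empty follow-up samples are legitimate
                log_event(
                    event="read_failed", donor=donor_id, locus=locus,
                    timepoint=row.timepoint, reason=str(exc),
                )
                sample = RepertoireSample(
                    records=[], locus=locus, donor_id=donor_id,
                    timepoint=row.timepoint, cohort=cohort,
                )
            if config.productive_only and len(sample):
                n_before = len(sample)
                sample = filter_productive(sample)
                if len(sample) != n_before:
                    log_event(
                        event="nonproductive_dropped", donor=donor_id, locus=locus,
                        timepoint=row.timepoint, dropped=n_before - len(sample),
                    )
            by_tp[row.timepoint] = sample

        raw = dict(by_tp)
        raw_counts = {tp: s.total_molecules for tp, s in raw.items()}

        # ---- downsampling design -----------------------------------------
        analyzed: dict[str, RepertoireSample] = {}
        if locus == "IGH" and cohort == "OCR" and {"M00", "M06"} <= set(raw):
            t_base, t_follow = plan_matched(
                raw_counts["M00"], raw_counts["M06"], config.igh_cap
            )
            targets = {"M00": t_base, "M06": t_follow}
        elif locus == "IGH":
            targets = {tp: min(n, config.igh_cap) for tp, n in raw_counts.items()}
        elif locus == "TRB":
            targets = {tp: min(n, config.trb_cap) for tp, n in raw_counts.items()}
        else:
            targets = dict(raw_counts)
        for tp, sample in raw.items():
            target = targets[tp]
            if target < raw_counts[tp]:
                sub_seed = derive_seed(seed, "subsample", donor_id, locus, tp)
                analyzed[tp] = subsample(sample, target, sub_seed)
                log_event(
                    event="subsampled", donor=donor_id, locus=locus, timepoint=tp,
                    from_n=raw_counts[tp], to_n=target, seed=sub_seed,
                )
            else:
                analyzed[tp] = sample

        # ---- per-sample metrics ------------------------------------------
        per_tp: dict[str, dict] = {}
        clones_by_tp: dict[str, list] = {}
        for tp in sorted(analyzed):
            sample = analyzed[tp]
            row_out = {
                "donor_id": donor_id,
                "cohort": cohort,
                "timepoint": tp,
                "locus": locus,
                "n_molecules_raw": raw_counts[tp],
            }
            if len(sample) == 0:
                log_event(
                    event="empty_sample", donor=donor_id, locus=locus, timepoint=tp
                )
                row_out.update(
                    {"n_molecules_analyzed": 0, "n_records_analyzed": 0,
                     "clone_count": 0}
                )
            else:
                metrics, clones, sample = _analyze_sample(sample, config)
                row_out.update(metrics)
                per_tp[tp] = metrics
                clones_by_tp[tp] = (clones, sample)
            sample_rows.append(row_out)

        # ---- paired donor metrics ----------------------------------------
        if {"M00", "M06"} <= set(raw):
            donor_row: dict = {"donor_id": donor_id, "cohort": cohort, "locus": locus}
            donor_row["n_m00_raw"] = raw_counts["M00"]
            donor_row["n_m06_raw"] = raw_counts["M06"]
            if locus == "IGH":
                if len(raw["M06"]) and len(raw["M00"]):
                    ov_seed = derive_seed(seed, "overlap", donor_id, locus)
                    donor_row["sample_overlap"] = sample_overlap(
                        raw["M06"], raw["M00"], config.igh_cap, ov_seed
                    ).overlap_fraction
                else:
                    donor_row["sample_overlap"] = float("nan")
            if locus == "TRB" and {"M00", "M06"} <= set(clones_by_tp):
                ab00 = abundance_from_clones(*clones_by_tp["M00"])
                ab06 = abundance_from_clones(*clones_by_tp["M06"])
                donor_row["top_n_overlap"] = top_n_overlap(
                    ab00, ab06, config.top_n_trb
                )
            if locus == "TRD" and len(analyzed["M00"]) and len(analyzed["M06"]):
                for stratum_idx, stratum in enumerate(("vd2_plus", "vd2_minus")):
                    s00 = split_vd2(analyzed["M00"])[stratum_idx]
                    s06 = split_vd2(analyzed["M06"])[stratum_idx]
                    if len(s00) and len(s06):
                        clones00 = assign_clonotypes(s00)
                        clones06 = assign_clonotypes(s06)
                        donor_row[f"top_n_overlap_{stratum}"] = top_n_overlap(
                            abundance_from_clones(clones00, s00),
                            abundance_from_clones(clones06, s06),
                            config.top_n_trd,
                        )
            donor_rows.append(donor_row)
        else:
            log_event(
                event="unpaired_donor_skipped", donor=donor_id, locus=locus,
                timepoints=sorted(raw),
            )

    samples_df = pd.DataFrame(sample_rows)
    donors_df = pd.DataFrame(donor_rows)

    # ---- reconstitution calls over OCR donors (IGH) ------------------------
    recon: dict = {}
    if len(donors_df):
        ocr_igh = donors_df[(donors_df["cohort"] == "OCR") & (donors_df["locus"] == "IGH")]
        if len(ocr_igh) >= 2:
            shm_m06 = samples_df[
                (samples_df["locus"] == "IGH") & (samples_df["timepoint"] == "M06")
            ].set_index("donor_id").get("mean_shm")
            shm_m00 = samples_df[
                (samples_df["locus"] == "IGH") & (samples_df["timepoint"] == "M00")
            ].set_index("donor_id").get("mean_shm")
            cohort_df = pd.DataFrame(
                {
                    "donor_id": ocr_igh["donor_id"].to_numpy(),
                    "n_sequenced_m06": ocr_igh["n_m06_raw"].to_numpy(),
                    "overlap_m06": ocr_igh["sample_overlap"].to_numpy(),
                }
            )
            if shm_m06 is not None:
                cohort_df["mean_shm_m06"] = shm_m06.reindex(cohort_df["donor_id"]).to_numpy()
            if shm_m00 is not None:
                cohort_df["mean_shm_m00"] = shm_m00.reindex(cohort_df["donor_id"]).to_numpy()
            cohort_df = cohort_df.dropna(subset=["n_sequenced_m06"])
            report = bimodality_report(cohort_df, config.reconstitution_threshold)
            recon = {
                "threshold_cells": report.threshold_cells,
                "calls": dict(
                    zip(report.per_donor["donor_id"], report.per_donor["call"])
                ),
                "correlations": report.correlations,
            }

    # ---- cohort-level paired comparisons -----------------------------------
    comparison_rows = []
    if len(samples_df):
        for (cohort, locus), _ in samples_df.groupby(["cohort", "locus"], sort=True):
            for metric in _PAIRED_METRICS.get(locus, ()):
                if metric not in samples_df.columns:
                    continue
                wide = samples_df[
                    (samples_df["cohort"] == cohort) & (samples_df["locus"] == locus)
                ].pivot(index="donor_id", columns="timepoint", values=metric)
                if "M00" not in wide.columns or "M06" not in wide.columns:
                    continue
                wide = wide.dropna()
                row = {
                    "cohort": cohort,
                    "locus": locus,
                    "metric": metric,
                    "n_pairs": len(wide),
                    "median_difference": float(
                        (wide["M06"] - wide["M00"]).median()
                    ) if len(wide) else float("nan"),
                }
                try:
                    stat, p = paired_wilcoxon(wide["M00"], wide["M06"])
                    row["wilcoxon_statistic"] = stat
                    row["p_value"] = p
                except InsufficientDataError as exc:
                    row["wilcoxon_statistic"] = float("nan")
                    row["p_value"] = float("nan")
                    log_event(event="comparison_skipped", cohort=cohort,
                              locus=locus, metric=metric, reason=str(exc))
                comparison_rows.append(row)
    comparisons_df = pd.DataFrame(comparison_rows)

    report = CohortReport(
        samples=samples_df,
        donors=donors_df,
        comparisons=comparisons_df,
        reconstitution=recon,
        seed=seed,
        log=events,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report_json = out_dir / "report.json"
        with open(report_json, "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        samples_df.to_csv(out_dir / "report.tsv", sep="\t", index=False)
        log_event(event="report_written", sha256=_sha256(report_json))
        with open(out_dir / "log.jsonl", "w") as fh:
            for event in events:
                fh.write(json.dumps(event, sort_keys=True) + "\n")
    return report
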