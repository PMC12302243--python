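"""Transcript-positivity gating of a marker gene in single-cell counts.

Cells are called positive for a gene iff its raw count exceeds zero — no
normalization, mirroring how CD20 (gene MS4A1) positivity is scored on
single-cell RNA data.  Per-subset positive fractions are computed per sample,
subsets are retained when at least a minimum fraction of their cells express
the marker, and RNA calls can be checked against protein (e.g. CITE-seq)
labels for concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_FRACTION = 0.01
MARKER_GENE = "MS4A1"

LABEL_COLUMNS = ("cell_id", "subset", "sample_id", "timepoint", "protein_positive")


@dataclass
class CellCounts:
    """Sparse genes x cells count matrix with per-cell labels.

    ``labels`` is indexed like ``cell_ids`` and carries at least ``subset``;
    optional columns: ``sample_id``, ``timepoint``, ``protein_positive``.
    """

    counts: sparse.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError("gene_ids length != matrix rows")
        if len(self.cell_ids) != n_cells or len(self.labels) != n_cells:
            raise ValidationError("cell label vector lengths != number of cells")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be nonnegative")

    def gene_row(self, gene: str) -> np.ndarray:
        """Dense per-cell count vector for one gene."""
        if gene not in self.gene_ids:
            raise ValidationError(f"unknown gene {gene!r}")
        return np.asarray(
            self.counts[self.gene_ids.index(gene), :].todense()
        ).ravel()

    @classmethod
    def from_mtx(cls, matrix_path, genes_path, cells_path, labels_path) -> "CellCounts":
        """Load MatrixMarket counts plus gene/cell id and label TSVs."""
        counts = sparse.csr_matrix(mmread(matrix_path))
        gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
        cell_ids = pd.read_csv(cells_path, sep="\t", header=None)[0].tolist()
        labels = pd.read_csv(labels_path, sep="\t", dtype={"cell_id": str})
        labels = labels.set_index("cell_id").loc[cell_ids].reset_index()
        return cls(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, labels=labels)

    @classmethod
    def from_dense_tsv(cls, matrix_path, labels_path) -> "CellCounts":
        """Load a small dense genes x cells TSV (gene ids in the first column)."""
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", dtype={"cell_id": str})
        labels = labels.set_index("cell_id").loc[list(df.columns)].reset_index()
        return cls(
            counts=sparse.csr_matrix(df.to_numpy()),
            gene_ids=list(df.index),
            cell_ids=list(df.columns),
            labels=labels,
        )

    def to_anndata(self):
        """Cells x genes AnnData view of the matrix (lazy import)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.labels.set_index(pd.Index(self.cell_ids, name="cell_id")),
        )
        adata.var_names = self.gene_ids
        return adata


def gate_positive(counts_row: np.ndarray) -> np.ndarray:
    """Boolean positivity per cell: count > 0, exactly."""
    counts_row = np.asarray(counts_row)
    if counts_row.size and counts_row.min() < 0:
        raise ValidationError("gate_positive: negative counts")
    return counts_row > 0


def subset_fractions(
    cells: CellCounts,
    gene: str = MARKER_GENE,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> pd.DataFrame:
    """Positive fraction of ``gene`` per (subset, sample).

    Returns one row per subset/sample with columns ``n_cells``,
    ``n_positive``, ``positive_fraction`` and ``retained`` (fraction >=
    ``min_fraction``).  Empty subsets are excluded with a warning rather than
    dividing by zero.
    """
    positive = gate_positive(cells.gene_row(gene))
    df = cells.labels.copy()
    df["positive"] = positive
    if "sample_id" not in df.columns:
        df["sample_id"] = "sample"
    rows = []
    for (subset, sample_id), grp in df.groupby(["subset", "sample_id"], sort=True):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("empty subset %s/%s excluded", subset, sample_id)
            continue
        k = int(grp["positive"].sum())
        rows.append(
            {
                "subset": subset,
                "sample_id": sample_id,
                "n_cells": n,
                "n_positive": k,
                "positive_fraction": k / n,
                "retained": k / n >= min_fraction,
            }
        )
    return pd.DataFrame(rows)


def rna_protein_concordance(
    rna_positive: np.ndarray, protein_positive: np.ndarray
) -> tuple[float, float]:
    """(false-negative rate, true-positive fraction) of the RNA gate.

    false_negative_rate = P(protein+ | RNA-): cells called negative on RNA
    that carry the protein; true_positive_fraction = P(protein+ | RNA+).
    """
    rna = np.asarray(rna_positive, dtype=bool)
    prot = np.asarray(protein_positive, dtype=bool)
    if rna.shape != prot.shape:
        raise ValidationError("rna_protein_concordance: unequal lengths")
    n_neg = int((~rna).sum())
    n_pos = int(rna.sum())
    if n_neg == 0:
        raise ValidationError("rna_protein_concordance: no RNA-negative cells")
    if n_pos == 0:
        raise ValidationError("rna_protein_concordance: no RNA-positive cells")
    fn_rate = float(prot[~rna].sum() / n_neg)
    tp_fraction = float(prot[rna].sum() / n_pos)
    return fn_rate, tp_fraction


def longitudinal_fraction_delta(
    cells: CellCounts,
    gene: str = MARKER_GENE,
    groups: Optional[Mapping[str, str]] = None,
    baseline: str = "M00",
    followup: str = "M06",
) -> dict:
    """Per-subset positive fractions over timepoints, with group ratios.

    ``groups`` maps subset -> {"infiltrating", "resident"}.  The summary gives
    each subset's follow-up/baseline fraction ratio and the mean ratio per
    group; subsets missing a timepoint are reported with a warning and no
    ratio.
    """
    if "timepoint" not in cells.labels.columns:
        raise ValidationError("longitudinal_fraction_delta: no timepoint labels")
    positive = gate_positive(cells.gene_row(gene))
    df = cells.labels.copy()
    df["positive"] = positive
    frac = (
        df.groupby(["subset", "timepoint"], sort=True)["positive"]
        .agg(n_cells="size", n_positive="sum", positive_fraction="mean")
        .reset_index()
    )
    ratios = []
    for subset, grp in frac.groupby("subset", sort=True):
        by_tp = grp.set_index("timepoint")["positive_fraction"]
        if baseline not in by_tp.index or followup not in by_tp.index:
            logger.warning("subset %s missing a timepoint; ratio omitted", subset)
            ratio = np.nan
        elif by_tp[baseline] == 0:
            ratio = np.nan
        else:
            ratio = by_tp[followup] / by_tp[baseline]
        ratios.append(
            {
                "subset": subset,
                "group": (groups or {}).get(subset),
                "fraction_ratio": ratio,
            }
        )
    ratios_df = pd.DataFrame(ratios)
    group_summary = (
        ratios_df.dropna(subset=["group", "fraction_ratio"])
        .groupby("group")["fraction_ratio"]
        .mean()
        .to_dict()
    )
    return {
        "per_subset_timepoint": frac,
        "ratios": ratios_df,
        "group_mean_ratio": group_summary,
    }
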