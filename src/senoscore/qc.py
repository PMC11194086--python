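"""Cell and gene quality filtering and the expression transforms.

The pipeline's expression unit is Ex = log2((CPM/10) + 1), computed per cell
from raw counts; per-gene z-scoring of (recovered) expression yields the
scaled matrix Es used for module scoring. Cell filters come in two named
profiles matching the two dataset types analysed: a multi-study "compendium"
profile (1000-9000 detected genes, >=500 UMI, mito ratio <0.20, complexity
>0.80) and a droplet "tenx" profile (>=200 genes, >=200 UMI, mito <0.10,
complexity >0.80), where complexity is log10(genes detected)/log10(UMI).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .syndata import MITO_PREFIX

logger = logging.getLogger(__name__)

#: thresholds per profile: (min_genes, max_genes, min_umi, max_mito, min_complexity)
FILTER_PROFILES = {
    "compendium": dict(min_genes=1000, max_genes=9000, min_umi=500, max_mito=0.20,
                       min_complexity=0.80),
    "tenx": dict(min_genes=200, max_genes=np.inf, min_umi=200, max_mito=0.10,
                 min_complexity=0.80),
}


@dataclass
class CountMatrix:
    """Sparse gene x cell integer counts with aligned metadata."""

    counts: sp.csr_matrix
    gene_names: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = np.asarray(self.gene_names)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.counts.shape != (len(self.gene_names), len(self.cell_ids)):
            raise ValueError("counts shape does not match gene/cell names")
        if (self.counts.data < 0).any():
            raise ValueError("negative counts")
        for names, what in [(self.gene_names, "gene"), (self.cell_ids, "cell")]:
            if len(np.unique(names)) != len(names):
                raise ValueError(f"duplicate {what} names")

    @classmethod
    def from_population(cls, population) -> "CountMatrix":
        return cls(
            counts=population.counts,
            gene_names=population.gene_names,
            cell_ids=population.cell_ids,
            cell_meta=population.cell_meta,
        )

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(self.counts.shape[0], bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.counts.shape[1], bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            counts=self.counts[gm][:, cm],
            gene_names=self.gene_names[gm],
            cell_ids=self.cell_ids[cm],
            cell_meta=self.cell_meta.iloc[cm],
        )


@dataclass
class ExpressionMatrix:
    """Gene x cell Ex values (dense), with provenance of the CPM scaling."""

    values: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.cell_ids)


@dataclass
class ScaledMatrix:
    """Per-gene z-scored expression Es (sample s.d., clipped)."""

    values: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.cell_ids)


def compute_cell_qc(counts: CountMatrix, mito_prefix: str = MITO_PREFIX) -> pd.DataFrame:
    """Per-cell QC metrics: genes detected, total UMI, mito ratio, complexity.

    Complexity is log10(n_genes_detected)/log10(total_umi) and is NaN where
    total_umi <= 1 (such cells cannot pass any filter profile).
    """
    if counts.counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    X = counts.counts.tocsc()
    n_genes = X.getnnz(axis=0)
    total = np.asarray(X.sum(axis=0)).ravel()
    mito_mask = np.char.startswith(counts.gene_names.astype(str), mito_prefix)
    mito = np.asarray(X[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        complexity = np.where(
            total > 1, np.log10(np.maximum(n_genes, 1)) / np.log10(np.maximum(total, 2)), np.nan
        )
        mito_ratio = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes_detected": n_genes,
            "total_umi": total,
            "mito_ratio": mito_ratio,
            "complexity": complexity,
        },
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )


def filter_cells(counts: CountMatrix, metrics: pd.DataFrame, profile: str = "compendium") -> CountMatrix:
    """Retain cells passing all four thresholds of the named profile."""
    if profile not in FILTER_PROFILES:
        raise ValueError(f"unknown filter profile {profile!r}")
    if not np.array_equal(metrics.index.to_numpy(), counts.cell_ids):
        raise ValueError("metrics do not align with the count matrix")
    t = FILTER_PROFILES[profile]
    keep = (
        (metrics["n_genes_detected"] >= t["min_genes"])
        & (metrics["n_genes_detected"] <= t["max_genes"])
        & (metrics["total_umi"] >= t["min_umi"])
        & (metrics["mito_ratio"] < t["max_mito"])
        & (metrics["complexity"] > t["min_complexity"])
    ).fillna(False).to_numpy()
    logger.info("filter_cells[%s]: kept %d / %d cells", profile, keep.sum(), keep.size)
    return counts.subset(cell_mask=keep)


def transform_ex(counts: CountMatrix) -> ExpressionMatrix:
    """Ex[g, c] = log2((CPM[g, c] / 10) + 1); requires positive cell totals."""
    total = np.asarray(counts.counts.sum(axis=0)).ravel()
    if (total <= 0).any():
        raise ValueError("zero-total cell present; run cell filtering first")
    cpm = counts.counts.multiply(1e6 / total).toarray()
    ex = np.log2(cpm / 10.0 + 1.0)
    return ExpressionMatrix(
        values=ex,
        gene_names=counts.gene_names,
        cell_ids=counts.cell_ids,
        cell_meta=counts.cell_meta,
        provenance={"transform": "log2((CPM/10)+1)"},
    )


def filter_genes(ex: ExpressionMatrix, min_ex: float = 3.5, min_frac: float = 0.02) -> ExpressionMatrix:
    """Keep genes with Ex > min_ex (strict) in at least min_frac of cells."""
    if not (0.0 <= min_frac <= 1.0):
        raise ValueError("min_frac must lie in [0, 1]")
    frac = (ex.values > min_ex).mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return ExpressionMatrix(
        values=ex.values[keep],
        gene_names=ex.gene_names[keep],
        cell_ids=ex.cell_ids,
        cell_meta=ex.cell_meta,
        provenance={**ex.provenance, "gene_filter": {"min_ex": min_ex, "min_frac": min_frac}},
    )


def scale_genes(values, gene_names=None, cell_ids=None, clip: float = 10.0) -> ScaledMatrix:
    """Per-gene z-score with sample s.d. (ddof=1), clipped at +/-clip.

    Accepts an ExpressionMatrix, a DataFrame, or a bare gene x cell array
    (then gene_names/cell_ids must be given). Constant genes map to zero.
    """
    if isinstance(values, ExpressionMatrix):
        gene_names, cell_ids, mat = values.gene_names, values.cell_ids, values.values
    elif isinstance(values, pd.DataFrame):
        gene_names, cell_ids, mat = values.index.to_numpy(), values.columns.to_numpy(), values.to_numpy()
    else:
        mat = np.asarray(values, dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("scaling needs at least two cells")
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return ScaledMatrix(
        values=np.clip(z, -clip, clip),
        gene_names=np.asarray(gene_names),
        cell_ids=np.asarray(cell_ids),
        provenance={"ddof": 1, "clip": clip},
    )


def detected_fraction(counts: CountMatrix, gene: str) -> float:
    """Fraction of cells in which a transcript is detected (raw count >= 1)."""
    row = np.flatnonzero(counts.gene_names == gene)
    if row.size == 0:
        raise KeyError(gene)
    return counts.counts[int(row[0])].getnnz() / counts.counts.shape[1]
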