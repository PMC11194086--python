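"""Marker-anchored signatures, control-matched module scores, classification.

The anchor signature is the top-N genes most correlated with the marker
(N = 100 by default; 250 and 500 are conventional alternatives). Each
signature is scored per cell as

    SC = mean(Es over signature genes G) - mean(Es over control genes C)

where the control set C is drawn from expression-matched bins (equal-
frequency bins of mean Ex; n_ctrl genes sampled per signature gene), so that
SC is centred at zero for an exchangeable gene set. Cells are classified
into high / mid / neg groups by empirical percentiles of a per-cell value
(marker expression: 70/30; staining intensity: 80/20).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import ScaledMatrix
from .recovery import GeneCorrelationRanking

logger = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    name: str
    genes: list
    source: str = "marker_topN"  # or "external"
    N: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        self.N = len(self.genes)


@dataclass
class ControlGeneSet:
    signature: str
    controls: list  # union of sampled control genes
    per_gene: dict  # signature gene -> list of matched controls
    n_bins: int
    n_ctrl: int
    seed: int


@dataclass
class ModuleScoreVector:
    signature: str
    scores: pd.Series  # per cell SC
    control_provenance: dict = field(default_factory=dict)


@dataclass
class SignatureCorrelationMatrix:
    R: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame  # BH-adjusted p over off-diagonal pairs


@dataclass
class CellClassLabels:
    labels: pd.Series  # per cell: "high" | "mid" | "neg"
    upper_threshold: float
    lower_threshold: float
    upper_pct: float
    lower_pct: float
    source: str = "marker"

    def cells(self, cls: str) -> np.ndarray:
        return self.labels.index[self.labels == cls].to_numpy()


def build_marker_signature(
    ranking: GeneCorrelationRanking, N: int = 100, name: str | None = None
) -> GeneSignature:
    """Top-N genes by adjusted correlation; the marker itself is excluded."""
    if N > len(ranking.table):
        raise ValueError(f"N={N} exceeds the {len(ranking.table)} ranked genes")
    genes = ranking.top(N)
    return GeneSignature(
        name=name or f"{ranking.marker}_top{N}", genes=genes, source="marker_topN"
    )


def match_control_genes(
    signature: GeneSignature,
    ex_means: pd.Series,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ControlGeneSet:
    """Sample expression-matched controls from equal-frequency mean-Ex bins."""
    missing = [g for g in signature.genes if g not in ex_means.index]
    if missing:
        raise KeyError(f"signature genes missing from ex_means: {missing[:5]}")
    rng = np.random.default_rng(seed)
    bins = pd.qcut(ex_means.rank(method="first"), q=n_bins, labels=False)
    sig_set = set(signature.genes)
    per_gene: dict[str, list] = {}
    union: set = set()
    for gene in signature.genes:
        b = bins.loc[gene]
        pool = bins.index[(bins == b) & ~bins.index.isin(sig_set)].to_numpy()
        pool = np.sort(pool)  # stable order independent of ex_means ordering
        if len(pool) < n_ctrl:
            warnings.warn(
                f"bin {b} holds only {len(pool)} candidate controls "
                f"(< n_ctrl={n_ctrl}); using the whole bin",
                stacklevel=2,
            )
            chosen = pool
        else:
            chosen = rng.choice(pool, size=n_ctrl, replace=False)
        per_gene[gene] = sorted(chosen.tolist())
        union.update(chosen.tolist())
    return ControlGeneSet(
        signature=signature.name,
        controls=sorted(union),
        per_gene=per_gene,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def score_modules(
    es: ScaledMatrix, signature: GeneSignature, controls: ControlGeneSet
) -> ModuleScoreVector:
    """SC = mean(Es over G) - mean(Es over C), exactly, per cell."""
    if not signature.genes or not controls.controls:
        raise ValueError("empty signature or control set")
    frame = es.to_frame()
    for group, genes in [("signature", signature.genes), ("control", controls.controls)]:
        missing = [g for g in genes if g not in frame.index]
        if missing:
            raise KeyError(f"{group} genes absent from scaled matrix: {missing[:5]}")
    sc = frame.loc[signature.genes].mean(axis=0) - frame.loc[controls.controls].mean(axis=0)
    sc.name = signature.name
    return ModuleScoreVector(
        signature=signature.name,
        scores=sc,
        control_provenance={
            "n_bins": controls.n_bins,
            "n_ctrl": controls.n_ctrl,
            "seed": controls.seed,
            "n_controls": len(controls.controls),
        },
    )


def correlate_signatures(scores: list[ModuleScoreVector]) -> SignatureCorrelationMatrix:
    """All pairwise Pearson correlations of signature scores across cells."""
    if len(scores) < 2:
        raise ValueError("need at least two signatures")
    frame = pd.concat([s.scores.rename(s.signature) for s in scores],
                      axis=1, join="inner")
    if frame.empty:
        raise ValueError("signatures share no cells")
    names = frame.columns.tolist()
    k = len(names)
    n = len(frame)
    X = frame.to_numpy()
    sd = X.std(axis=0, ddof=1)
    R = np.eye(k)
    P = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if sd[i] == 0 or sd[j] == 0:
                R[i, j] = R[j, i] = np.nan
                P[i, j] = P[j, i] = np.nan
                continue
            r, p = stats.pearsonr(X[:, i], X[:, j])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    iu = np.triu_indices(k, 1)
    q = np.full((k, k), np.nan)
    pvec = P[iu]
    finite = np.isfinite(pvec)
    if finite.any():
        adj = np.full(pvec.shape, np.nan)
        adj[finite] = multipletests(pvec[finite], method="fdr_bh")[1]
        q[iu] = adj
        q.T[iu] = adj
    np.fill_diagonal(q, 0.0)
    idx = pd.Index(names)
    return SignatureCorrelationMatrix(
        R=pd.DataFrame(R, index=idx, columns=idx),
        p=pd.DataFrame(P, index=idx, columns=idx),
        q=pd.DataFrame(q, index=idx, columns=idx),
    )


def classify_cells_by_value(
    values: pd.Series,
    upper_pct: float = 70.0,
    lower_pct: float = 30.0,
    source: str = "marker",
) -> CellClassLabels:
    """Label cells high (> upper percentile), neg (< lower), else mid.

    Thresholds are empirical quantiles with linear interpolation; both
    inequalities are strict, so values tied with a threshold fall into the
    middle class.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 10:
        raise ValueError("classification requires at least 10 cells")
    if not lower_pct < upper_pct:
        raise ValueError("lower_pct must be strictly below upper_pct")
    upper = float(np.percentile(values, upper_pct, method="linear"))
    lower = float(np.percentile(values, lower_pct, method="linear"))
    labels = pd.Series("mid", index=values.index, dtype=object)
    labels[values > upper] = "high"
    labels[values < lower] = "neg"
    if values.nunique() == 1:
        warnings.warn("all values identical; every cell labelled mid", stacklevel=2)
    return CellClassLabels(
        labels=labels,
        upper_threshold=upper,
        lower_threshold=lower,
        upper_pct=upper_pct,
        lower_pct=lower_pct,
        source=source,
    )
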