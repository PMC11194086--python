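"""Preranked gene-set enrichment (weighted-KS GSEA) and over-representation.

The preranked GSEA walks the ranked list accumulating a weighted hit CDF
(|metric|^p at member genes, p = 1 by default) against a uniform miss CDF;
the enrichment score ES is the signed maximum deviation between the two.
The null is built by drawing random gene-label sets of the same size, NES is
ES normalised by the mean |null ES| of matching sign, and FDR q-values pool
null and observed NES in the standard way. Over-representation uses the
upper-tail hypergeometric distribution with BH adjustment across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    genes: np.ndarray  # strictly ordered, metric descending
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.metric = np.asarray(self.metric, dtype=float)
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")

    @classmethod
    def from_series(cls, series: pd.Series) -> "RankedGeneList":
        """Sort descending by metric with deterministic gene-name tie-break."""
        df = pd.DataFrame({"gene": series.index, "metric": series.to_numpy(float)})
        df = df.sort_values(["metric", "gene"], ascending=[False, True], kind="mergesort")
        return cls(genes=df["gene"].to_numpy(), metric=df["metric"].to_numpy())

    @classmethod
    def from_ranking(cls, ranking) -> "RankedGeneList":
        return cls.from_series(ranking.table["r_adj"])


@dataclass
class GSEAResult:
    table: pd.DataFrame  # per set: ES, NES, p, q, size, leading edge
    n_perm: int
    seed: int
    weight_p: float
    skipped: dict = field(default_factory=dict)  # set -> reason


@dataclass
class ORAResult:
    table: pd.DataFrame  # per set: k, K, n, N, p, q


def enrichment_score(
    metric: np.ndarray, hit_mask: np.ndarray, weight_p: float = 1.0
) -> tuple[float, int]:
    """Signed maximum deviation of weighted hit CDF minus miss CDF.

    Returns (ES, peak position). The miss CDF steps uniformly at non-member
    genes; the hit CDF steps by |metric|^p (equal steps if all weights
    vanish). Requires at least one hit and one miss.
    """
    n = metric.size
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit a strict subset of the list")
    w = np.where(hit_mask, np.abs(metric) ** weight_p, 0.0)
    sw = w.sum()
    if sw == 0:
        w = hit_mask.astype(float)
        sw = float(nh)
    p_hit = np.cumsum(w) / sw
    p_miss = np.cumsum(~hit_mask) / (n - nh)
    dev = p_hit - p_miss
    i_max = int(np.argmax(dev))
    i_min = int(np.argmin(dev))
    # ES is the extremum of larger magnitude; magnitude ties (to within
    # float roundoff) resolve to the positive side
    if dev[i_max] >= -dev[i_min] - 1e-12:
        return float(dev[i_max]), i_max
    return float(dev[i_min]), i_min


def gsea_preranked(
    ranked: RankedGeneList,
    sets: dict[str, list],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 5,
) -> GSEAResult:
    """Weighted-KS preranked GSEA with a random-gene-set null."""
    rng = np.random.default_rng(seed)
    genes = ranked.genes
    metric = ranked.metric
    n = genes.size
    index = {g: i for i, g in enumerate(genes)}

    results = []
    skipped: dict[str, str] = {}
    null_by_size: dict[int, np.ndarray] = {}
    for name in sets:
        members = [g for g in dict.fromkeys(sets[name]) if g in index]
        k = len(members)
        if k < min_overlap:
            skipped[name] = f"overlap {k} below minimum {min_overlap}"
            continue
        if k == n:
            skipped[name] = "set spans the whole ranked list (degenerate ES)"
            continue
        hit = np.zeros(n, dtype=bool)
        hit[[index[g] for g in members]] = True
        es, peak = enrichment_score(metric, hit, weight_p)
        if es >= 0:
            leading = genes[: peak + 1][hit[: peak + 1]]
        else:
            leading = genes[peak:][hit[peak:]]

        if k not in null_by_size:
            null = np.empty(n_perm)
            mask = np.zeros(n, dtype=bool)
            for b in range(n_perm):
                mask[:] = False
                mask[rng.choice(n, size=k, replace=False)] = True
                null[b], _ = enrichment_score(metric, mask, weight_p)
            null_by_size[k] = null
        null = null_by_size[k]

        same_sign = null >= 0 if es >= 0 else null < 0
        denom = int(same_sign.sum())
        if denom == 0:
            p = 1.0
            nes = np.nan
        else:
            p = float((np.abs(null[same_sign]) >= abs(es)).sum()) / denom
            mean_abs = float(np.abs(null[same_sign]).mean())
            nes = es / mean_abs if mean_abs > 0 else np.nan
        results.append(
            {
                "set": name,
                "size": k,
                "ES": es,
                "NES": nes,
                "p": p,
                "leading_edge": ",".join(map(str, leading)),
                "n_leading": leading.size,
            }
        )

    table = pd.DataFrame(results).set_index("set") if results else pd.DataFrame(
        columns=["size", "ES", "NES", "p", "leading_edge", "n_leading"]
    )
    if len(table):
        table["q"] = _gsea_fdr(table, null_by_size, weight_p)
    return GSEAResult(
        table=table, n_perm=n_perm, seed=seed, weight_p=weight_p, skipped=skipped
    )


def _gsea_fdr(table: pd.DataFrame, null_by_size: dict, weight_p: float) -> np.ndarray:
    """Standard NES-pooling FDR: compare observed NES against pooled null NES."""
    null_nes = []
    for k, null in null_by_size.items():
        pos = null[null >= 0]
        neg = null[null < 0]
        if pos.size and pos.mean() > 0:
            null_nes.append(pos / pos.mean())
        if neg.size and np.abs(neg).mean() > 0:
            null_nes.append(neg / np.abs(neg).mean())
    null_nes = np.concatenate(null_nes) if null_nes else np.array([])
    obs = table["NES"].to_numpy()
    q = np.full(obs.shape, np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac = np.mean(null_nes >= nes) if null_nes.size else 1.0
            obs_frac = np.mean(obs[np.isfinite(obs)] >= nes)
        else:
            null_frac = np.mean(null_nes <= nes) if null_nes.size else 1.0
            obs_frac = np.mean(obs[np.isfinite(obs)] <= nes)
        q[i] = min(1.0, null_frac / max(obs_frac, 1e-12))
    return q


def ora_hypergeometric(
    hits: list, sets: dict[str, list], universe: list
) -> ORAResult:
    """Upper-tail hypergeometric over-representation with BH adjustment."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hit_set = set(hits)
    if not hit_set <= uni:
        raise ValueError("hits must be a subset of the universe")
    N = len(uni)
    n = len(hit_set)
    rows = []
    for name, members in sets.items():
        mem = set(members) & uni
        K = len(mem)
        k = len(mem & hit_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return ORAResult(table=table)
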