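"""Empirical-Bayes expression recovery and marker-correlation ranking.

A Gamma-Poisson (negative binomial) empirical-Bayes scheme recovers per-cell
expression from sparse counts. For each gene g and cell c with size factor
s_c, the observed count is modelled as Poisson(s_c * lambda) with a Gamma
prior on lambda whose mean mu_hat[g, c] is predicted from the principal
components of the log-normalised matrix (ridge regression per gene) and whose
variance is phi_g * mu_hat^2 with a per-gene maximum-likelihood dispersion.
The posterior mean

    lambda_hat = (y + 1/phi_g) / (s_c + 1 / (phi_g * mu_hat))

interpolates between the normalised observation y/s_c (phi -> infinity) and
the prediction mu_hat (phi -> 0). A per-gene reliability weight

    w_g = sqrt( Var_c(lambda_hat_g) / (Var_c(lambda_hat_g) + mean_c posterior_var_g) )

down-weights correlations of noisily recovered genes; the ranking of genes by
adjusted correlation to a designated marker (r_adj = r * w_g * w_marker) is
the input to signature construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from sklearn.decomposition import PCA

from .qc import CountMatrix

logger = logging.getLogger(__name__)

_MU_FLOOR = 1e-6
_PHI_FLOOR = 1e-6  # below this the prior is treated as degenerate (phi = 0)


@dataclass
class RecoveredExpression:
    lambda_hat: np.ndarray  # genes x cells posterior mean (normalised scale)
    prior_mean: np.ndarray  # genes x cells mu_hat
    prior_dispersion: np.ndarray  # phi_g per gene
    cell_size: np.ndarray  # s_c per cell
    posterior_var: np.ndarray  # genes x cells
    reliability: np.ndarray  # w_g per gene, in (0, 1]
    gene_names: np.ndarray
    cell_ids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.lambda_hat, index=self.gene_names, columns=self.cell_ids)


@dataclass
class GeneCorrelationRanking:
    marker: str
    table: pd.DataFrame  # per gene: r, r_adj, rank, defined

    def top(self, n: int) -> list[str]:
        return self.table.index[:n].tolist()


def _nb_negloglik(log_phi: float, y: np.ndarray, m: np.ndarray) -> float:
    phi = np.exp(log_phi)
    inv = 1.0 / phi
    pm = phi * m
    ll = (
        gammaln(y + inv)
        - gammaln(inv)
        - gammaln(y + 1.0)
        - inv * np.log1p(pm)
        + y * (np.log(pm) - np.log1p(pm))
    )
    return -float(ll.sum())


def _poisson_negloglik(y: np.ndarray, m: np.ndarray) -> float:
    return -float((y * np.log(m) - m - gammaln(y + 1.0)).sum())


def recover_expression(
    counts: CountMatrix,
    n_components: int = 20,
    ridge: float = 1e-2,
) -> RecoveredExpression:
    """Recover per-cell expression by PC-ridge prediction + NB posterior."""
    Y = counts.counts.toarray().astype(float)
    G, C = Y.shape
    if C < 50:
        raise ValueError("recovery requires at least 50 cells")

    total = Y.sum(axis=0)
    s = total / np.median(total)

    norm = Y / s  # normalised counts
    log_norm = np.log1p(norm)

    k = min(n_components, C - 1, G)
    if k < n_components:
        warnings.warn(
            f"reducing n_components from {n_components} to {k} for a "
            f"{G} x {C} matrix",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    Z = pca.fit_transform(log_norm.T)  # cells x k

    # per-gene ridge regression of log1p(count/s) on the PCs (shared design,
    # one linear solve for all genes; intercept unpenalised)
    A = np.hstack([np.ones((C, 1)), Z])
    penalty = np.diag(np.r_[0.0, np.full(k, ridge)])
    coef = np.linalg.solve(A.T @ A + penalty, A.T @ log_norm.T)  # (k+1) x G
    mu_hat = np.maximum(np.expm1(A @ coef).T, _MU_FLOOR)  # genes x cells

    # per-gene 1-D maximum-likelihood dispersion of NB(y | s * mu_hat, phi)
    phi = np.zeros(G)
    for g in range(G):
        y, m = Y[g], s * mu_hat[g]
        try:
            res = minimize_scalar(
                _nb_negloglik, bounds=(-12.0, 6.0), args=(y, m), method="bounded",
                options={"xatol": 1e-3},
            )
            cand = float(np.exp(res.x))
            # accept only if the NB fit is at least as good as the Poisson limit
            if _nb_negloglik(np.log(cand), y, m) <= _poisson_negloglik(y, m):
                phi[g] = cand
        except Exception:  # pragma: no cover - optimizer failure fallback
            warnings.warn(f"dispersion fit failed for gene {g}; using phi=0",
                          stacklevel=2)
            phi[g] = 0.0
    phi[phi < _PHI_FLOOR] = 0.0

    lambda_hat = np.empty_like(mu_hat)
    posterior_var = np.empty_like(mu_hat)
    degenerate = phi == 0.0
    if degenerate.any():
        lambda_hat[degenerate] = mu_hat[degenerate]
        posterior_var[degenerate] = 0.0
    ok = ~degenerate
    if ok.any():
        shape = (1.0 / phi[ok])[:, None] + Y[ok]
        rate = 1.0 / (phi[ok][:, None] * mu_hat[ok]) + s[None, :]
        lambda_hat[ok] = shape / rate
        posterior_var[ok] = shape / rate**2

    var_l = lambda_hat.var(axis=1, ddof=1)
    mean_pv = posterior_var.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.sqrt(np.where(var_l + mean_pv > 0, var_l / (var_l + mean_pv), 1.0))
    w = np.clip(w, 1e-12, 1.0)
    w[var_l + mean_pv == 0] = 1.0  # constant gene with exact posterior

    return RecoveredExpression(
        lambda_hat=lambda_hat,
        prior_mean=mu_hat,
        prior_dispersion=phi,
        cell_size=s,
        posterior_var=posterior_var,
        reliability=w,
        gene_names=counts.gene_names,
        cell_ids=counts.cell_ids,
        provenance={
            "n_components": k,
            "ridge": ridge,
            "correlation_scale": "recovered (pre-scaling)",
        },
    )


def rank_genes_by_marker(
    recovered: RecoveredExpression, marker: str
) -> GeneCorrelationRanking:
    """Rank all genes by reliability-adjusted Pearson correlation to the marker.

    r_adj = r * w_gene * w_marker; descending sort with ties broken by gene
    name; genes whose recovered profile is constant are placed last with
    r_adj = 0 and flagged as undefined. The marker itself is excluded.
    """
    names = recovered.gene_names
    idx = np.flatnonzero(names == marker)
    if idx.size == 0:
        raise KeyError(f"marker {marker!r} not present")
    if recovered.lambda_hat.shape[1] < 3:
        raise ValueError("ranking requires at least 3 cells")
    mrow = int(idx[0])

    X = recovered.lambda_hat
    xm = X[mrow]
    xm_c = xm - xm.mean()
    denom_m = np.sqrt((xm_c**2).sum())
    if denom_m == 0:
        raise ValueError("marker expression is constant; correlation undefined")
    Xc = X - X.mean(axis=1, keepdims=True)
    denom_g = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ xm_c) / (denom_g * denom_m)
    defined = denom_g > 0
    r = np.where(defined, np.clip(r, -1.0, 1.0), np.nan)

    w = recovered.reliability
    r_adj = np.where(defined, r * w * w[mrow], 0.0)

    keep = names != marker
    table = pd.DataFrame(
        {
            "gene": names[keep],
            "r": r[keep],
            "r_adj": r_adj[keep],
            "reliability": w[keep],
            "defined": defined[keep],
        }
    )
    table = table.sort_values(
        ["defined", "r_adj", "gene"], ascending=[False, False, True], kind="mergesort"
    ).set_index("gene")
    table["rank"] = np.arange(1, len(table) + 1)
    return GeneCorrelationRanking(marker=marker, table=table)
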