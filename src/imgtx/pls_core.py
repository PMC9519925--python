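"""Single-response partial least squares via NIPALS, with bootstrap gene ranking.

The first component of PLS1 has the closed form u_1 = X^T y / ||X^T y||; the
NIPALS iteration is kept (with deflation) so additional components are
available, but all reported statistics use component 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from imgtx._utils import pearson, rng_from
from imgtx.types import EffectMap, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PLSModel", "RankedGeneList", "fit_pls", "component_correlation", "bootstrap_loadings", "align_xy"]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


@dataclass
class PLSModel:
    """Fitted PLS1 model: unit-norm loading weights, scores, correlations."""

    loading_weights: np.ndarray  # genes x K
    scores: np.ndarray  # parcels x K (deflation-aware)
    component_correlations: np.ndarray  # K
    n_components: int
    x_mean: np.ndarray
    y_mean: float


@dataclass
class RankedGeneList:
    """Bootstrap-standardized gene ranking from the first PLS component."""

    table: pd.DataFrame  # gene_id, empirical_lw, bootstrap_sd, z, rank
    n_boot: int
    n_redrawn: int = 0

    def top(self, n: int) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")


def align_xy(X: ExpressionMatrix, Y: EffectMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-align an expression matrix and an effect map.

    Rows are the covered parcels that also appear in the effect map (in X's
    parcel order); columns exclude degenerate genes. Returns
    (matrix, y vector, gene_ids).
    """
    in_map = np.isin(X.parcel_ids, np.asarray(Y.parcel_ids, dtype=object))
    sel = X.covered_mask & in_map
    if not sel.any():
        raise ValueError("no covered parcels shared between X and Y")
    keep = ~X.degenerate_genes
    mat = X.values[sel][:, keep]
    y = Y.aligned_to(X.parcel_ids[sel])
    return mat, y, X.gene_ids[keep]


def _center(X: np.ndarray, y: np.ndarray):
    xm = X.mean(axis=0)
    ym = y.mean()
    return X - xm, y - ym, xm, ym


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> PLSModel:
    """NIPALS PLS1 with deflation and unit-norm weight vectors.

    X is parcels x genes (columns standardized upstream; centered again here,
    which is idempotent), y the effect-map vector (centered here, not
    variance-scaled). Component 1 is sign-aligned so its correlation with y
    is non-negative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y must be row-aligned")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 aligned parcels")
    if np.var(y) == 0:
        raise ValueError("zero-variance response")
    Xc, yc, xm, ym = _center(X, y)

    P, G = Xc.shape
    K = min(n_components, min(P - 1, G))
    Xd, yd = Xc.copy(), yc.copy()
    W = np.zeros((G, K))
    T = np.zeros((P, K))
    for m in range(K):
        w = Xd.T @ yd
        nrm = np.linalg.norm(w)
        if nrm == 0:
            K = m
            break
        w /= nrm
        # PLS1 converges in one step; iterate defensively anyway
        for _ in range(_NIPALS_MAX_ITER):
            t = Xd @ w
            w_new = Xd.T @ yd
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xd @ w
        tt = t @ t
        if tt == 0:
            K = m
            break
        p_load = Xd.T @ t / tt
        c = yd @ t / tt
        Xd = Xd - np.outer(t, p_load)
        yd = yd - t * c
        W[:, m] = w
        T[:, m] = t
    W, T = W[:, :K], T[:, :K]

    rho = np.array([pearson(Xc @ W[:, m], yc) for m in range(K)])
    if K > 0 and rho[0] < 0:
        W[:, 0] *= -1
        T[:, 0] *= -1
        rho[0] *= -1
    return PLSModel(
        loading_weights=W,
        scores=T,
        component_correlations=rho,
        n_components=K,
        x_mean=xm,
        y_mean=ym,
    )


def component_correlation(model: PLSModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of the gene-expression scores X u_m with y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return np.array(
        [pearson(Xc @ model.loading_weights[:, m], yc) for m in range(model.n_components)]
    )


def first_component_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form first-component weights: normalized X^T y after centering."""
    Xc, yc, *_ = _center(np.asarray(X, float), np.asarray(y, float).ravel())
    w = Xc.T @ yc
    return w / np.linalg.norm(w)


def bootstrap_loadings(
    X: np.ndarray,
    y: np.ndarray,
    gene_ids,
    n_boot: int = 10_000,
    seed: int = 0,
) -> RankedGeneList:
    """Rank genes by empirical first-component weight over its bootstrap SD.

    Rows of X and y are resampled jointly with replacement; the first
    component is refit per replicate and sign-aligned to the empirical weight
    vector before SDs are accumulated. Replicates with zero-variance y are
    redrawn (counted). Genes with zero bootstrap SD are excluded from the
    ranking with a non-finite z.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    P = X.shape[0]
    rng = rng_from(seed)
    w_emp = first_component_weights(X, y)
    # empirical component sign-aligned as in fit_pls
    Xc, yc, *_ = _center(X, y)
    if pearson(Xc @ w_emp, yc) < 0:
        w_emp = -w_emp

    boot = np.empty((n_boot, X.shape[1]))
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, P, size=P)
            yb = y[idx]
            if np.var(yb) > 0:
                break
            n_redrawn += 1
        wb = first_component_weights(X[idx], yb)
        if wb @ w_emp < 0:
            wb = -wb
        boot[b] = wb
    sd = boot.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, w_emp / sd, np.inf * np.sign(w_emp))
    finite = np.isfinite(z)
    if not finite.all():
        logger.warning("%d genes with zero bootstrap SD excluded from ranking", int((~finite).sum()))
    table = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids, dtype=object),
            "empirical_lw": w_emp,
            "bootstrap_sd": sd,
            "z": z,
        }
    )
    ranked = table[finite].sort_values("z", ascending=False, kind="stable")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    table = table.merge(ranked[["gene_id", "rank"]], on="gene_id", how="left")
    if n_redrawn:
        logger.info("%d bootstrap replicates redrawn for zero-variance y", n_redrawn)
    return RankedGeneList(table=table, n_boot=n_boot, n_redrawn=n_redrawn)
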