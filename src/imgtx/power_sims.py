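"""Sample-composition and classifier simulations.

Quantifies how the sex composition of a case-control sample shapes
group-contrast statistics (bootstrap subsampling over a composition grid)
and whether sex-stratified diagnostic classifiers outperform pooled ones at
matched n (elastic-net logistic models evaluated along a regularization
path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from imgtx._utils import rng_from
from imgtx.connectivity_stats import two_sample_t
from imgtx.types import ConnectivityDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionSimResult",
    "ClassifierResult",
    "DEFAULT_COMPOSITIONS",
    "sex_composition_bootstrap",
    "train_diagnostic_classifiers",
    "aggregate_feature_weights",
]

DEFAULT_COMPOSITIONS = (0.0, 0.20, 1.0 / 3.0, 0.50, 2.0 / 3.0, 0.80, 1.0)


@dataclass
class CompositionSimResult:
    compositions: tuple
    mean_t: np.ndarray  # compositions x iterations
    rejection_freq: np.ndarray  # compositions x features
    n_iter: int
    alpha: float


@dataclass
class ClassifierResult:
    stratum: str
    lambda_grid: np.ndarray
    auc: np.ndarray  # iterations x lambdas
    mean_coefficients: np.ndarray  # lambdas x features (averaged over iterations)
    nonzero_counts: np.ndarray  # iterations x lambdas
    n_iter: int
    extra: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> np.ndarray:
        return self.auc.mean(axis=0)


def _draw_composition(rng, pool_f: np.ndarray, pool_m: np.ndarray, n: int, frac_female: float):
    n_f = int(round(frac_female * n))
    n_m = n - n_f
    if n_f > len(pool_f) or n_m > len(pool_m):
        raise ValueError(
            f"composition {frac_female:.2f} needs {n_f} female / {n_m} male subjects; "
            f"pools hold {len(pool_f)} / {len(pool_m)}"
        )
    idx = []
    if n_f:
        idx.append(rng.choice(pool_f, size=n_f, replace=False))
    if n_m:
        idx.append(rng.choice(pool_m, size=n_m, replace=False))
    return np.concatenate(idx) if idx else np.array([], dtype=int)


def sex_composition_bootstrap(
    dataset: ConnectivityDataset,
    n_mdd: int = 140,
    n_hc: int = 70,
    compositions: tuple = DEFAULT_COMPOSITIONS,
    n_iter: int = 1000,
    seed: int = 0,
    feature_columns: np.ndarray | None = None,
    alpha: float = 0.05,
) -> CompositionSimResult:
    """Subsample the case-control contrast across a female-fraction grid.

    Per iteration and composition, draws ``n_mdd`` cases and ``n_hc``
    controls without replacement with the same female fraction in both
    groups, computes the per-feature two-sample t (cases - controls) over
    ``feature_columns`` (default: all features), and records the mean t and
    per-feature rejections at unadjusted p < ``alpha``.
    """
    meta = dataset.metadata
    x = dataset.features if feature_columns is None else dataset.features[:, feature_columns]
    female = (meta["sex"] == "F").to_numpy()
    mdd = (meta["diagnosis"] == "MDD").to_numpy()
    pools = {
        ("MDD", True): np.flatnonzero(mdd & female),
        ("MDD", False): np.flatnonzero(mdd & ~female),
        ("HC", True): np.flatnonzero(~mdd & female),
        ("HC", False): np.flatnonzero(~mdd & ~female),
    }
    rng = rng_from(seed)
    mean_t = np.empty((len(compositions), n_iter))
    rej = np.zeros((len(compositions), x.shape[1]))
    for ci, frac in enumerate(compositions):
        for it in range(n_iter):
            cases = _draw_composition(rng, pools[("MDD", True)], pools[("MDD", False)], n_mdd, frac)
            controls = _draw_composition(rng, pools[("HC", True)], pools[("HC", False)], n_hc, frac)
            idx = np.concatenate([cases, controls])
            labels = np.concatenate([np.ones(len(cases), bool), np.zeros(len(controls), bool)])
            t, p = two_sample_t(x[idx], labels)
            mean_t[ci, it] = t.mean()
            rej[ci] += p < alpha
    rej /= n_iter
    return CompositionSimResult(
        compositions=tuple(compositions), mean_t=mean_t, rejection_freq=rej, n_iter=n_iter, alpha=alpha
    )


def _lambda_grid(X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int) -> np.ndarray:
    """glmnet-style grid: log-spaced from the all-zero lambda down 4 decades."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - 4, n_lambda)


def train_diagnostic_classifiers(
    dataset: ConnectivityDataset,
    stratum: str,
    n_train: int = 145,
    n_test: int = 72,
    alpha: float = 0.5,
    n_lambda: int = 80,
    n_iter: int = 100,
    seed: int = 0,
    max_redraw: int = 50,
) -> ClassifierResult:
    """Elastic-net logistic diagnosis classifiers over a regularization path.

    ``stratum`` is 'male-only', 'female-only', or 'pooled'. Per iteration a
    disjoint train/test draw is taken from the stratum pool (redrawn if a
    class is absent from either split), features are standardized on the
    training split, and the penalized model is fit at each lambda with warm
    starts; held-out AUC and coefficients are recorded per lambda.
    """
    meta = dataset.metadata
    if stratum == "pooled":
        pool = np.arange(dataset.n_subjects)
    elif stratum in ("male-only", "female-only"):
        pool = np.flatnonzero((meta["sex"] == ("M" if stratum == "male-only" else "F")).to_numpy())
    else:
        raise ValueError("stratum must be 'male-only', 'female-only', or 'pooled'")
    if len(pool) < n_train + n_test:
        raise ValueError(f"stratum pool {len(pool)} < n_train + n_test = {n_train + n_test}")
    y_all = (meta["diagnosis"] == "MDD").to_numpy(int)
    rng = rng_from(seed)

    F = dataset.n_features
    auc = np.empty((n_iter, n_lambda))
    nonzero = np.empty((n_iter, n_lambda), dtype=int)
    coef_sum = np.zeros((n_lambda, F))
    lam_grid = None

    for it in range(n_iter):
        for _ in range(max_redraw):
            draw = rng.choice(pool, size=n_train + n_test, replace=False)
            tr, te = draw[:n_train], draw[n_train:]
            if len(np.unique(y_all[tr])) == 2 and len(np.unique(y_all[te])) == 2:
                break
            logger.info("iteration %d: single-class draw, redrawing", it)
        else:
            raise ValueError("could not draw a two-class train/test split")
        Xtr, ytr = dataset.features[tr], y_all[tr]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr = (Xtr - mu) / sd
        Xte = (dataset.features[te] - mu) / sd
        yte = y_all[te]
        if lam_grid is None:
            lam_grid = _lambda_grid(Xtr, ytr.astype(float), alpha, n_lambda)
        model = LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            warm_start=True,
            max_iter=2000,
            tol=1e-4,
        )
        for li, lam in enumerate(lam_grid):
            model.C = 1.0 / (lam * n_train)
            model.fit(Xtr, ytr)
            beta = model.coef_.ravel()
            coef_sum[li] += beta
            nonzero[it, li] = int(np.count_nonzero(beta))
            scores = Xte @ beta + model.intercept_[0]
            auc[it, li] = roc_auc_score(yte, scores) if np.ptp(scores) > 0 else 0.5
    return ClassifierResult(
        stratum=stratum,
        lambda_grid=lam_grid,
        auc=auc,
        mean_coefficients=coef_sum / n_iter,
        nonzero_counts=nonzero,
        n_iter=n_iter,
        extra={"n_train": n_train, "n_test": n_test, "alpha": alpha},
    )


def aggregate_feature_weights(
    result: ClassifierResult, feature_index: list, lambda_index: int | None = None
) -> dict:
    """Per-ROI sum of |iteration-averaged beta| over features touching the ROI.

    Coefficients are averaged across iterations first, then the absolute
    value is taken and summed into both endpoint parcels of each feature.
    ``lambda_index`` defaults to the lambda with the best mean AUC.
    """
    if lambda_index is None:
        lambda_index = int(np.argmax(result.mean_auc))
    beta = np.abs(result.mean_coefficients[lambda_index])
    roi_weight: dict = {}
    for (a, b), w in zip(feature_index, beta):
        roi_weight[a] = roi_weight.get(a, 0.0) + float(w)
        roi_weight[b] = roi_weight.get(b, 0.0) + float(w)
    return roi_weight
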