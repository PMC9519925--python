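"""Significance and reproducibility testing of PLS associations.

Two permutation nulls for the component correlation — a spatially
constrained "spin" null built from random rotations of the spherical parcel
projection, and a spatially naive uniform permutation null — plus
ten-times ten-fold cross-validation with a corrected resampled t-test and a
Bonferroni omnibus decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from imgtx._utils import pearson, rng_from
from imgtx.connectivity_stats import bh_fdr, seed_effect_map
from imgtx.pls_core import first_component_weights
from imgtx.types import ConnectivityDataset, EffectMap, ExpressionMatrix, ParcelGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "CVResult",
    "random_rotation",
    "spin_permutation",
    "spin_test",
    "random_test",
    "fdr_across_models",
    "cross_validate",
    "corrected_resampled_ttest",
    "omnibus_cv_test",
]


@dataclass
class NullDistribution:
    rho_null: np.ndarray
    observed_rho: float
    p_value: float
    method: str  # 'spin' or 'random'
    n_perm: int
    seed: int


@dataclass
class CVResult:
    rho_real: np.ndarray  # repeats x folds
    rho_null: np.ndarray  # repeats x folds
    t_per_repeat: np.ndarray
    p_per_repeat: np.ndarray
    p_bonferroni: np.ndarray
    reject: bool
    n_repeats: int
    n_folds: int
    extra: dict = field(default_factory=dict)


def random_rotation(seed) -> np.ndarray:
    """Rotation matrix uniform over SO(3).

    QR of a Gaussian matrix with the sign of R's diagonal absorbed into Q,
    then a determinant fix to land in SO(3) rather than O(3).
    """
    rng = rng_from(seed)
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def _greedy_bijective_assignment(dist: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbor matching without replacement.

    ``dist[i, j]`` is the distance from target slot i to source j. Pairs are
    taken in globally ascending distance order; returns perm with
    perm[i] = assigned source for slot i (a true permutation).
    """
    n = dist.shape[0]
    order = np.argsort(dist, axis=None, kind="stable")
    rows, cols = np.unravel_index(order, dist.shape)
    perm = np.full(n, -1, dtype=int)
    used_src = np.zeros(n, dtype=bool)
    remaining = n
    for i, j in zip(rows, cols):
        if perm[i] == -1 and not used_src[j]:
            perm[i] = j
            used_src[j] = True
            remaining -= 1
            if remaining == 0:
                break
    return perm


_MIRROR_X = np.diag([-1.0, 1.0, 1.0])


def spin_permutation(geometry: ParcelGeometry, n_perm: int, seed: int) -> np.ndarray:
    """Spatial permutations from random rotations of the spherical projection.

    Per permutation, left-hemisphere centroids are rotated by a uniform
    random rotation and right-hemisphere centroids by its x-mirrored twin;
    parcels are then reassigned to rotated centroids within hemisphere by
    greedy bijective nearest-neighbor. Returns an (n_perm, P) integer array
    of index permutations: permuted_map = map[perm_row].
    """
    rng = rng_from(seed)
    left = geometry.hemisphere_indices("L")
    right = geometry.hemisphere_indices("R")
    xyz = geometry.sphere_xyz
    perms = np.empty((n_perm, geometry.n_parcels), dtype=int)
    for k in range(n_perm):
        R = random_rotation(rng)
        R_mirror = _MIRROR_X @ R @ _MIRROR_X
        perm = np.empty(geometry.n_parcels, dtype=int)
        for hemi_idx, rot in ((left, R), (right, R_mirror)):
            rotated = xyz[hemi_idx] @ rot.T
            d = np.linalg.norm(xyz[hemi_idx][:, None, :] - rotated[None, :, :], axis=2)
            local = _greedy_bijective_assignment(d)
            perm[hemi_idx] = hemi_idx[local]
        perms[k] = perm
    return perms


def _null_rho(X: np.ndarray, y: np.ndarray, u_fixed: np.ndarray | None) -> float:
    """Component correlation for one permuted response, refitting unless
    a fixed weight vector is supplied."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if u_fixed is None:
        w = Xc.T @ yc
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 0.0
        w = w / nrm
    else:
        w = u_fixed
    return abs(pearson(Xc @ w, yc)) if u_fixed is None else pearson(Xc @ w, yc)


def _observed_rho(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    u = first_component_weights(X, y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    rho = pearson(Xc @ u, yc)
    if rho < 0:
        u, rho = -u, -rho
    return rho, u


def spin_test(
    X: ExpressionMatrix,
    Y: EffectMap,
    geometry: ParcelGeometry,
    n_perm: int = 10_000,
    seed: int = 0,
    permutations: np.ndarray | None = None,
    refit: bool = True,
) -> NullDistribution:
    """Spin-permutation significance of the first-component correlation.

    The rotation and reassignment run on the full parcel set; entries landing
    on (or originating from) uncovered parcels are dropped after permutation.
    The null statistic refits the first component per permutation (``refit``
    False keeps the empirical weights fixed instead). One-sided p with the
    +1 correction.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is very small for a permutation test", n_perm)
    from imgtx.pls_core import align_xy

    if not np.array_equal(X.parcel_ids, geometry.parcel_ids):
        raise ValueError("X parcel order must match the geometry")
    Xa, y_cov, _genes = align_xy(X, Y)
    sel = X.covered_mask & np.isin(X.parcel_ids, np.asarray(Y.parcel_ids, dtype=object))
    covered_idx = np.flatnonzero(sel)
    y_full = np.full(geometry.n_parcels, np.nan)
    y_full[covered_idx] = y_cov
    if permutations is None:
        permutations = spin_permutation(geometry, n_perm, seed)
    n_perm = permutations.shape[0]

    rho_obs, u_emp = _observed_rho(Xa, y_cov)
    Xc_all = Xa - Xa.mean(axis=0)  # X rows never move under the spin; reuse
    rho_null = np.empty(n_perm)
    for k in range(n_perm):
        y_p = y_full[permutations[k]][covered_idx]
        ok = np.isfinite(y_p)
        if ok.all():
            yc = y_p - y_p.mean()
            if refit:
                w = Xc_all.T @ yc
                nrm = np.linalg.norm(w)
                w = w / nrm if nrm > 0 else w
            else:
                w = u_emp
            rho_null[k] = pearson(Xc_all @ w, yc)
        else:
            rho_null[k] = _null_rho(Xa[ok], y_p[ok], None if refit else u_emp)
    p = (1 + np.sum(rho_null >= rho_obs)) / (1 + n_perm)
    return NullDistribution(rho_null, float(rho_obs), float(p), "spin", n_perm, seed)


def random_test(
    X: ExpressionMatrix,
    Y: EffectMap,
    n_perm: int = 10_000,
    seed: int = 0,
    refit: bool = True,
) -> NullDistribution:
    """Spatially naive null: uniform permutations of the covered response."""
    from imgtx.pls_core import align_xy

    Xa, y_cov, _genes = align_xy(X, Y)
    rng = rng_from(seed)
    rho_obs, u_emp = _observed_rho(Xa, y_cov)
    rho_null = np.empty(n_perm)
    for k in range(n_perm):
        y_p = y_cov[rng.permutation(y_cov.size)]
        rho_null[k] = _null_rho(Xa, y_p, None if refit else u_emp)
    p = (1 + np.sum(rho_null >= rho_obs)) / (1 + n_perm)
    return NullDistribution(rho_null, float(rho_obs), float(p), "random", n_perm, seed)


def fdr_across_models(p_values: np.ndarray, q_level: float = 0.05):
    """BH adjustment across the family of fitted models (e.g. 5 seeds x 2 sexes)."""
    return bh_fdr(np.asarray(p_values, dtype=float), q_level)


def _stratified_folds(labels: np.ndarray, n_folds: int, rng) -> list[np.ndarray]:
    """Diagnosis-stratified fold assignment; returns per-fold index arrays."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        idx = idx[rng.permutation(len(idx))]
        offset = int(rng.integers(n_folds))  # rotate so fold 0 isn't always largest
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[(k + offset) % n_folds].extend(chunk.tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate(
    X: ExpressionMatrix,
    dataset: ConnectivityDataset,
    seed_parcels: list,
    sex: str,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    max_repartition: int = 20,
) -> CVResult:
    """Ten-times ten-fold reproducibility test of the gene-map association.

    Per fold, seed effect maps are recomputed from the training and test
    subject subsets; first-component weights fit on the training map are
    scored against the held-out map (rho_ho). A matched null arm permutes
    diagnosis labels within the sex stratum once per fold evaluation. Per
    repeat, per-fold (real - null) differences feed the corrected resampled
    t-test; the 10 p-values are Bonferroni-adjusted and an omnibus decision
    rejects if any survives.
    """
    meta = dataset.metadata
    stratum_mask = (meta["sex"] == sex).to_numpy()
    sub = dataset.subset(stratum_mask)
    diag = (sub.metadata["diagnosis"] == "MDD").to_numpy()
    n = len(diag)
    n_mdd, n_hc = int(diag.sum()), int((~diag).sum())
    if min(n_mdd, n_hc) < 2 * n_folds:
        raise ValueError("too few subjects per diagnosis group for the fold count")

    # restrict to covered parcels that are targets of the seed's features
    target_set = {t for s, t in sub.feature_index if s in set(seed_parcels)}
    map_parcels = [p for p in X.covered_parcel_ids if p in target_set]
    if len(map_parcels) < 3:
        raise ValueError("too few covered target parcels for CV")
    keep_rows = np.isin(X.covered_parcel_ids, np.array(map_parcels, dtype=object))
    Xa = X.analysis_matrix()[0][keep_rows]

    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(c) for c in ss.spawn(n_repeats)]

    def fold_ok(test_idx: np.ndarray) -> bool:
        d = diag[test_idx]
        return d.sum() >= 2 and (~d).sum() >= 2

    def effect_y(subset_idx: np.ndarray, labels: np.ndarray) -> np.ndarray | None:
        ds = ConnectivityDataset(
            features=sub.features[subset_idx],
            feature_index=sub.feature_index,
            metadata=sub.metadata.iloc[subset_idx]
            .assign(diagnosis=np.where(labels[subset_idx], "MDD", "HC"))
            .reset_index(drop=True),
        )
        em = seed_effect_map(ds, seed_parcels, sex, covered_parcel_ids=map_parcels)
        return em.aligned_to(map_parcels)

    rho_real = np.empty((n_repeats, n_folds))
    rho_null = np.empty((n_repeats, n_folds))
    t_rep = np.empty(n_repeats)
    p_rep = np.empty(n_repeats)
    n_test_avg = n / n_folds
    n_train_avg = n - n_test_avg

    for r, rng in enumerate(streams):
        folds = None
        for _attempt in range(max_repartition):
            cand = _stratified_folds(diag, n_folds, rng)
            if all(fold_ok(f) for f in cand):
                folds = cand
                break
            logger.info("repeat %d: degenerate fold, repartitioning", r)
        if folds is None:
            raise ValueError("could not build diagnosis-stratified folds")
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            y_train = effect_y(train_idx, diag)
            y_test = effect_y(test_idx, diag)
            u = first_component_weights(Xa, y_train)
            if pearson(Xa @ u, y_train) < 0:
                u = -u
            rho_real[r, f] = pearson(Xa @ u, y_test)

            # null arm: one diagnosis-label permutation per fold evaluation
            while True:
                perm_diag = rng.permutation(diag)
                if fold_ok(test_idx) and perm_diag[test_idx].sum() >= 2 and (~perm_diag[test_idx]).sum() >= 2 and perm_diag[train_idx].sum() >= 2 and (~perm_diag[train_idx]).sum() >= 2:
                    break
            yn_train = effect_y(train_idx, perm_diag)
            yn_test = effect_y(test_idx, perm_diag)
            un = first_component_weights(Xa, yn_train)
            if pearson(Xa @ un, yn_train) < 0:
                un = -un
            rho_null[r, f] = pearson(Xa @ un, yn_test)
        d = rho_real[r] - rho_null[r]
        t_rep[r], p_rep[r] = corrected_resampled_ttest(d, n_train_avg, n_test_avg, k=n_folds)

    p_bonf = np.minimum(p_rep * n_repeats, 1.0)
    decision = omnibus_cv_test(p_rep, n_repeats=n_repeats)
    return CVResult(
        rho_real=rho_real,
        rho_null=rho_null,
        t_per_repeat=t_rep,
        p_per_repeat=p_rep,
        p_bonferroni=p_bonf,
        reject=decision["reject"],
        n_repeats=n_repeats,
        n_folds=n_folds,
        extra={"n_train_avg": n_train_avg, "n_test_avg": n_test_avg},
    )


def corrected_resampled_ttest(
    d: np.ndarray, n_train: float, n_test: float, k: int = 10
) -> tuple[float, float]:
    """Corrected resampled t-test for k overlapping-train-set folds.

    t = mean(d) / sqrt((1/k + n_test/n_train) * var(d)), two-sided p on
    k - 1 degrees of freedom; the variance multiplier compensates for
    dependence between folds sharing training subjects.
    """
    d = np.asarray(d, dtype=float)
    if k < 2 or d.size != k:
        raise ValueError("need k >= 2 fold differences")
    mean = d.mean()
    var = d.var(ddof=1)
    if var == 0:
        if mean == 0:
            return 0.0, 1.0
        logger.warning("zero variance with nonzero mean; returning +/- inf sentinel")
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / np.sqrt((1.0 / k + n_test / n_train) * var)
    p = 2 * stats.t.sf(abs(t), k - 1)
    return float(t), float(p)


def omnibus_cv_test(p_values: np.ndarray, n_repeats: int | None = None, alpha: float = 0.05) -> dict:
    """Bonferroni-correct the per-repeat p-values; reject iff any survives."""
    p = np.asarray(p_values, dtype=float)
    m = n_repeats if n_repeats is not None else p.size
    p_adj = np.minimum(p * m, 1.0)
    return {
        "p_adjusted": p_adj,
        "min_p_adjusted": float(p_adj.min()),
        "reject": bool(p_adj.min() < alpha),
    }
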