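"""Group-level connectivity statistics.

Fisher-z rsFC computation, empirical-Bayes site harmonization, two-way
factorial ANOVA, sex-stratified post-hoc contrasts, BH-FDR, shared/specific
classification with a sex-label permutation test, and seed effect maps (the
PLS response vector). Positive t denotes increased connectivity in cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from imgtx._utils import rng_from
from imgtx.types import ConnectivityDataset, EffectMap

logger = logging.getLogger(__name__)

__all__ = [
    "compute_rsfc",
    "combat_harmonize",
    "factorial_anova",
    "posthoc_contrasts",
    "bh_fdr",
    "classify_shared_specific",
    "sex_specificity_permutation",
    "seed_effect_map",
    "two_sample_t",
]


def compute_rsfc(
    time_series: dict,
    seed_set: list,
    target_set: list,
    metadata: pd.DataFrame,
) -> ConnectivityDataset:
    """Pearson r per (seed, target) region pair, Fisher z-transformed.

    ``time_series`` maps subject_id -> regions x time frame (pd.DataFrame
    indexed by region label). |r| = 1 is clipped before atanh; constant
    series yield NaN features with a warning.
    """
    feature_index = [(s, t) for s in seed_set for t in target_set if s != t]
    subjects = metadata["subject_id"].tolist()
    features = np.empty((len(subjects), len(feature_index)))
    for i, sid in enumerate(subjects):
        ts = time_series[sid]
        if ts.shape[1] < 3:
            raise ValueError(f"{sid}: need >= 3 time points")
        arr = ts.to_numpy(float)
        sd = arr.std(axis=1)
        constant = sd == 0
        if constant.any():
            logger.warning("%s: %d constant series; features set missing", sid, int(constant.sum()))
        z = (arr - arr.mean(axis=1, keepdims=True)) / np.where(constant, 1.0, sd)[:, None]
        r = (z @ z.T) / arr.shape[1]
        r = np.clip(r, -(1 - 1e-12), 1 - 1e-12)
        fz = np.arctanh(r)
        ridx = {lab: k for k, lab in enumerate(ts.index)}
        for j, (s, t) in enumerate(feature_index):
            a, b = ridx[s], ridx[t]
            features[i, j] = np.nan if (constant[a] or constant[b]) else fz[a, b]
    return ConnectivityDataset(features=features, feature_index=feature_index, metadata=metadata)


def _combat_design(meta: pd.DataFrame, batches: np.ndarray, covariates: tuple) -> np.ndarray:
    cols = []
    for b in batches:
        cols.append((meta["site"] == b).to_numpy(float))
    for cov in covariates:
        if cov == "sex":
            cols.append((meta["sex"] == "M").to_numpy(float))
        elif cov == "diagnosis":
            cols.append((meta["diagnosis"] == "MDD").to_numpy(float))
        elif cov == "age":
            age = meta["age"].to_numpy(float)
            cols.append((age - age.mean()) / (age.std() or 1.0))
        else:
            raise ValueError(f"unknown covariate {cov}")
    return np.column_stack(cols)


def combat_harmonize(
    dataset: ConnectivityDataset,
    covariates: tuple = ("sex", "diagnosis", "age"),
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ConnectivityDataset:
    """Parametric empirical-Bayes location/scale batch harmonization.

    Site is the batch variable; modeled covariates are retained in the
    standardization design so their signal survives harmonization. Features
    are adjusted by subtracting the shrunken additive site parameter and
    dividing by the shrunken multiplicative parameter. Single-site input is
    returned unchanged.
    """
    meta = dataset.metadata
    batches = np.array(sorted(meta["site"].unique()), dtype=object)
    if len(batches) == 1:
        logger.info("single batch; harmonization is the identity")
        return ConnectivityDataset(
            features=dataset.features.copy(),
            feature_index=dataset.feature_index,
            metadata=meta.copy(),
        )
    batch_sizes = np.array([(meta["site"] == b).sum() for b in batches])
    if (batch_sizes < 2).any():
        raise ValueError("every batch needs >= 2 subjects")

    Y = dataset.features  # subjects x features
    n, F = Y.shape
    design = _combat_design(meta, batches, covariates)
    n_batch = len(batches)
    beta = np.linalg.lstsq(design, Y, rcond=None)[0]  # (n_batch + n_cov) x F

    grand_mean = (batch_sizes / n) @ beta[:n_batch]
    cov_effect = design[:, n_batch:] @ beta[n_batch:]
    stand_mean = grand_mean[None, :] + cov_effect
    resid = Y - design @ beta
    var_pooled = (resid**2).sum(axis=0) / n
    var_pooled = np.where(var_pooled == 0, 1e-12, var_pooled)
    s_data = (Y - stand_mean) / np.sqrt(var_pooled)[None, :]

    adjusted = np.empty_like(s_data)
    for bi, b in enumerate(batches):
        mask = (meta["site"] == b).to_numpy()
        nb = mask.sum()
        sb = s_data[mask]
        gamma_hat = sb.mean(axis=0)
        delta_hat = sb.var(axis=0, ddof=1)

        # parametric priors across features
        g_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        lam = (d_mean**2 + 2 * d_var) / d_var if d_var > 0 else 2.0 + 1e6
        theta = (d_mean**3 + d_mean * d_var) / d_var if d_var > 0 else d_mean

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (t2 * nb * gamma_hat + delta_star * g_bar) / (t2 * nb + delta_star)
            ss = ((sb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (theta + 0.5 * ss) / (nb / 2.0 + lam - 1.0)
            change = max(
                np.abs(g_new - gamma_star).max() / (np.abs(gamma_star).max() + 1e-12),
                np.abs(d_new - delta_star).max() / (np.abs(delta_star).max() + 1e-12),
            )
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        adjusted[mask] = (sb - gamma_star[None, :]) / np.sqrt(delta_star)[None, :]

    out = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    return ConnectivityDataset(
        features=out, feature_index=dataset.feature_index, metadata=meta.copy()
    )


@dataclass
class ContrastTable:
    """Per-feature two-way factorial statistics plus post-hoc maps."""

    table: pd.DataFrame  # F_*, p_*, q_* per term; t/p/q per sex; classification

    def __getitem__(self, col):
        return self.table[col]


def _ols_term_f(Y: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient partial F (= t^2) and p for each column of D beyond the
    intercept, vectorized over response columns of Y."""
    n, k = D.shape
    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ D.T @ Y
    resid = Y - D @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(DtD_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    F = t**2
    p = stats.f.sf(F, 1, df)
    return F, p


def factorial_anova(dataset: ConnectivityDataset, q_level: float = 0.05) -> ContrastTable:
    """2x2 factorial ANOVA (sex, diagnosis, interaction) per feature.

    Effect-coded design so the single-df partial F-tests match the classic
    cell-means ANOVA in the balanced case; BH-FDR across features per term.
    """
    meta = dataset.metadata
    male = np.where(meta["sex"] == "M", 1.0, -1.0)
    mdd = np.where(meta["diagnosis"] == "MDD", 1.0, -1.0)
    cells = pd.crosstab(meta["sex"], meta["diagnosis"])
    if cells.shape != (2, 2) or (cells.to_numpy() == 0).any():
        raise ValueError("all four sex x diagnosis cells must be nonempty")
    D = np.column_stack([np.ones(len(meta)), male, mdd, male * mdd])
    F, p = _ols_term_f(dataset.features, D)
    out = pd.DataFrame(index=pd.RangeIndex(dataset.n_features))
    for i, term in enumerate(("sex", "mdd", "interaction"), start=1):
        out[f"F_{term}"] = F[i]
        out[f"p_{term}"] = p[i]
        q, _ = bh_fdr(p[i], q_level)
        out[f"q_{term}"] = q

    t_male, p_male = posthoc_contrasts(dataset, "M")
    t_female, p_female = posthoc_contrasts(dataset, "F")
    out["t_male"], out["p_male"] = t_male, p_male
    out["t_female"], out["p_female"] = t_female, p_female
    out["q_male"], _ = bh_fdr(p_male, q_level)
    out["q_female"], _ = bh_fdr(p_female, q_level)
    labels, _ = classify_shared_specific(t_male, p_male, t_female, p_female)
    out["classification"] = labels
    return ContrastTable(out)


def two_sample_t(
    x: np.ndarray, group: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t over feature columns; positive t = group True > False."""
    a = x[group]
    b = x[~group]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 subjects")
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(se, n1 + n2 - 2)
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se**4 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    t = np.where(se == 0, 0.0, t)
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def posthoc_contrasts(
    dataset: ConnectivityDataset, sex: str, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t (MDD - HC) per feature within one sex stratum."""
    meta = dataset.metadata
    stratum = (meta["sex"] == sex).to_numpy()
    if stratum.sum() == 0:
        raise ValueError(f"no subjects in sex stratum {sex}")
    x = dataset.features[stratum]
    mdd = (meta.loc[stratum, "diagnosis"] == "MDD").to_numpy()
    return two_sample_t(x, mdd, equal_var=equal_var)


def bh_fdr(p_values: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values (monotone) and rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= q_level


def classify_shared_specific(
    t_male: np.ndarray,
    p_male: np.ndarray,
    t_female: np.ndarray,
    p_female: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, dict]:
    """Label each feature male-specific / female-specific / shared / none at
    unadjusted p < alpha; returns (labels, Venn counts)."""
    sig_m = np.asarray(p_male) < alpha
    sig_f = np.asarray(p_female) < alpha
    labels = np.full(sig_m.shape, "none", dtype=object)
    labels[sig_m & ~sig_f] = "male-specific"
    labels[~sig_m & sig_f] = "female-specific"
    labels[sig_m & sig_f] = "shared"
    counts = {
        "male-specific": int((sig_m & ~sig_f).sum()),
        "female-specific": int((~sig_m & sig_f).sum()),
        "shared": int((sig_m & sig_f).sum()),
    }
    return labels, counts


def sex_specificity_permutation(
    dataset: ConnectivityDataset,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Are sex-specific effect counts larger than chance under shuffled sex labels?

    Permutes sex labels across the full sample, recomputes the stratified
    MDD-HC contrasts and specific-effect counts per permutation; one-sided
    p = (1 + #{null >= observed}) / (1 + n_perm) per count.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng_from(seed)
    meta = dataset.metadata
    male = (meta["sex"] == "M").to_numpy()
    mdd = (meta["diagnosis"] == "MDD").to_numpy()
    x = dataset.features

    def counts_for(male_mask):
        tm, pm = two_sample_t(x[male_mask], mdd[male_mask])
        tf, pf = two_sample_t(x[~male_mask], mdd[~male_mask])
        _, c = classify_shared_specific(tm, pm, tf, pf, alpha)
        return c["male-specific"], c["female-specific"]

    obs_m, obs_f = counts_for(male)
    null_m = np.empty(n_perm)
    null_f = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(male)
        null_m[k], null_f[k] = counts_for(perm)
    p_m = (1 + np.sum(null_m >= obs_m)) / (1 + n_perm)
    p_f = (1 + np.sum(null_f >= obs_f)) / (1 + n_perm)
    return {
        "observed": {"male-specific": obs_m, "female-specific": obs_f},
        "p_male_specific": float(p_m),
        "p_female_specific": float(p_f),
        "null_male_specific": null_m,
        "null_female_specific": null_f,
        "n_perm": n_perm,
    }


def seed_effect_map(
    dataset: ConnectivityDataset,
    seed_parcels: list,
    sex: str,
    covered_parcel_ids=None,
    seed_label: str | None = None,
    equal_var: bool = True,
) -> EffectMap:
    """Per-target-parcel case-control t after averaging Fisher-z over the seed.

    Features seeded in ``seed_parcels`` are averaged at the Fisher-z level per
    target parcel, then a two-sample t (MDD - HC) is computed within the sex
    stratum. The map is restricted to ``covered_parcel_ids`` when given;
    covered parcels absent from the dataset are dropped with a warning.
    """
    if not seed_parcels:
        raise ValueError("seed_parcels must be nonempty")
    cols = dataset.feature_columns(seed_parcels)
    if covered_parcel_ids is None:
        targets = sorted(cols)
    else:
        targets = [p for p in covered_parcel_ids if p in cols]
        dropped = [p for p in covered_parcel_ids if p not in cols]
        if dropped:
            logger.warning("%d covered parcels missing from dataset; dropped", len(dropped))
    if not targets:
        raise ValueError("no target parcels available for the effect map")

    meta = dataset.metadata
    stratum = (meta["sex"] == sex).to_numpy()
    x = dataset.features[stratum]
    mdd = (meta.loc[stratum, "diagnosis"] == "MDD").to_numpy()
    seed_avg = np.column_stack([x[:, cols[t]].mean(axis=1) for t in targets])
    t, p = two_sample_t(seed_avg, mdd, equal_var=equal_var)
    return EffectMap(
        seed_label=seed_label or "+".join(map(str, seed_parcels)),
        sex=sex,
        parcel_ids=np.array(targets, dtype=object),
        t_values=t,
        p_values=p,
    )
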