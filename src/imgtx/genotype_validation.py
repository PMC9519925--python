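"""Genotype-based validation of the PLS gene ranking.

Convergent-gene selection (extreme PLS decile + expression-study direction +
eQTL direction), SNP quality control (missingness, MAF, Hardy-Weinberg),
additive risk-allele scoring, and the sex-stratified score -> connectivity
association model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from imgtx.types import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "hwe_chisq",
    "qc_filter_snps",
    "select_convergent_genes",
    "risk_allele_score",
    "score_fc_association",
]


def hwe_chisq(n_ref: int, n_het: int, n_alt: int) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions from genotype counts.

    Expected counts come from the observed allele frequencies; monomorphic
    SNPs return (0, 1) by convention.
    """
    n = n_ref + n_het + n_alt
    if n < 1:
        raise ValueError("need at least one genotyped subject")
    p_alt = (2 * n_alt + n_het) / (2 * n)
    if p_alt in (0.0, 1.0):
        logger.info("monomorphic SNP; HWE p = 1 by convention")
        return 0.0, 1.0
    expected = np.array(
        [n * (1 - p_alt) ** 2, n * 2 * p_alt * (1 - p_alt), n * p_alt**2]
    )
    observed = np.array([n_ref, n_het, n_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class QCReport:
    retained: GenotypeTable
    exclusions: dict = field(default_factory=dict)  # snp_id -> reason


def qc_filter_snps(
    table: GenotypeTable,
    missing_thresh: float = 0.10,
    maf_thresh: float = 0.05,
    hwe_alpha: float = 0.05,
    exclude_common: bool = False,
) -> QCReport:
    """Exclude SNPs failing missingness, MAF, or Hardy-Weinberg criteria.

    Default: exclude missingness > ``missing_thresh``, minor allele frequency
    < ``maf_thresh``, or HWE p < ``hwe_alpha``. ``exclude_common`` flips the
    MAF rule to exclude MAF > threshold instead (literal reading of some QC
    descriptions; non-standard).
    """
    keep, exclusions = [], {}
    for j, snp in enumerate(table.snp_ids):
        col = table.counts[:, j]
        called = col[~np.isnan(col)]
        if len(called) < 30:
            raise ValueError(f"{snp}: need >= 30 genotyped subjects")
        miss = 1.0 - len(called) / len(col)
        freq_alt = called.sum() / (2 * len(called))
        maf = min(freq_alt, 1 - freq_alt)
        counts = [int((called == g).sum()) for g in (0, 1, 2)]
        _chi2, hwe_p = hwe_chisq(*counts)
        if miss > missing_thresh:
            exclusions[snp] = "missingness"
        elif (maf > maf_thresh) if exclude_common else (maf < maf_thresh):
            exclusions[snp] = "maf"
        elif hwe_p < hwe_alpha:
            exclusions[snp] = "hwe"
        else:
            keep.append(snp)
    if not keep:
        raise ValueError("all SNPs excluded by QC")
    return QCReport(retained=table.select_snps(keep), exclusions=exclusions)


def select_convergent_genes(
    ranked: pd.DataFrame,
    dex_table: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    decile_thresh: float = 0.10,
) -> pd.DataFrame:
    """Genes satisfying all three convergence criteria, with supporting SNPs.

    A gene qualifies when (1) its PLS rank lies in the top or bottom
    ``decile_thresh`` tail of the ranking, (2) it appears in ``dex_table``
    (columns gene_id, direction in {up, down}), and (3) some SNP in
    ``eqtl_table`` (columns snp_id, gene_id, direction) targets it — with all
    three directions consistent: tail sign matches the expression-study
    direction matches the eQTL direction.
    """
    df = ranked.dropna(subset=["rank"]).sort_values("rank")
    G = len(df)
    n_tail = int(np.floor(decile_thresh * G))
    top = set(df["gene_id"].iloc[:n_tail])
    bottom = set(df["gene_id"].iloc[G - n_tail :])
    dex = {r.gene_id: r.direction for r in dex_table.itertuples()}
    if not set(dex.values()) <= {"up", "down"}:
        raise ValueError("dex directions must be 'up' or 'down'")
    rows = []
    for r in eqtl_table.itertuples():
        gene = r.gene_id
        tail = "up" if gene in top else ("down" if gene in bottom else None)
        if tail is None or gene not in dex:
            continue
        if dex[gene] == tail == r.direction:
            rows.append({"gene_id": gene, "tail": tail, "snp_id": r.snp_id, "direction": r.direction})
    out = pd.DataFrame(rows, columns=["gene_id", "tail", "snp_id", "direction"])
    return out.drop_duplicates().reset_index(drop=True)


def risk_allele_score(table: GenotypeTable, snp_ids: list) -> pd.Series:
    """Integer sum of risk-allele counts across the given SNPs per subject.

    Subjects missing any scored SNP are excluded (complete-case) and logged.
    """
    sub = table.select_snps(list(snp_ids))
    complete = ~np.isnan(sub.counts).any(axis=1)
    if (~complete).sum():
        logger.info("%d subjects excluded for missing scored genotypes", int((~complete).sum()))
    score = sub.counts[complete].sum(axis=1).astype(int)
    return pd.Series(score, index=pd.Index(sub.subject_ids[complete], name="subject_id"), name="risk_score")


def score_fc_association(
    scores: pd.Series,
    feature_values: pd.Series,
    age: pd.Series,
    min_n: int = 10,
) -> dict:
    """OLS of a connectivity feature on the allele score with age as covariate.

    All three series are aligned on subject_id; returns beta, t, and the
    two-sided p for the score coefficient plus the n used.
    """
    df = pd.concat(
        {"score": scores, "y": feature_values, "age": age}, axis=1, join="inner"
    ).dropna()
    n = len(df)
    if n < min_n:
        raise ValueError(f"need >= {min_n} subjects in the stratum, got {n}")
    if df["score"].nunique() < 2:
        raise ValueError("allele score has zero variance")
    D = np.column_stack([np.ones(n), df["score"], df["age"]])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("collinear design")
    y = df["y"].to_numpy(float)
    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ D.T @ y
    resid = y - D @ beta
    dof = n - D.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * DtD_inv[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return {"beta": float(beta[1]), "t": float(t), "p": float(p), "n": n}
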