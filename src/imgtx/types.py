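"""Core domain types shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParcelGeometry",
    "ExpressionMatrix",
    "ConnectivityDataset",
    "EffectMap",
    "GeneSetCollection",
    "GenotypeTable",
]


@dataclass
class ParcelGeometry:
    """Cortical parcellation with spherical and volumetric coordinates.

    Parameters
    ----------
    parcel_ids : array of str, length P
        Unique parcel labels.
    hemisphere : array of {'L', 'R'}, length P
    sphere_xyz : (P, 3) float array
        Unit-sphere centroid of each parcel (spherical surface projection).
    volume_xyz : (P, 3) float array
        Representative volumetric locus in millimetres (MNI-like frame).
    homolog_id : array of str, length P
        parcel_id of the mirror-hemisphere counterpart.
    """

    parcel_ids: np.ndarray
    hemisphere: np.ndarray
    sphere_xyz: np.ndarray
    volume_xyz: np.ndarray
    homolog_id: np.ndarray

    def __post_init__(self) -> None:
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=object)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.sphere_xyz = np.asarray(self.sphere_xyz, dtype=float)
        self.volume_xyz = np.asarray(self.volume_xyz, dtype=float)
        self.homolog_id = np.asarray(self.homolog_id, dtype=object)
        if len(set(self.parcel_ids)) != self.n_parcels:
            raise ValueError("parcel_ids must be unique")
        norms = np.linalg.norm(self.sphere_xyz, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sphere_xyz rows must be unit vectors")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def index_of(self, parcel_id: str) -> int:
        return self._index()[parcel_id]

    def _index(self) -> dict:
        if not hasattr(self, "_idx_cache"):
            self._idx_cache = {p: i for i, p in enumerate(self.parcel_ids)}
        return self._idx_cache

    @property
    def homolog_index(self) -> np.ndarray:
        """Integer index of each parcel's mirror-hemisphere homolog."""
        idx = self._index()
        return np.array([idx[h] for h in self.homolog_id], dtype=int)

    def hemisphere_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "hemisphere": self.hemisphere,
                "sx": self.sphere_xyz[:, 0],
                "sy": self.sphere_xyz[:, 1],
                "sz": self.sphere_xyz[:, 2],
                "vx": self.volume_xyz[:, 0],
                "vy": self.volume_xyz[:, 1],
                "vz": self.volume_xyz[:, 2],
                "homolog_id": self.homolog_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParcelGeometry":
        return cls(
            parcel_ids=df["parcel_id"].to_numpy(),
            hemisphere=df["hemisphere"].to_numpy(),
            sphere_xyz=df[["sx", "sy", "sz"]].to_numpy(float),
            volume_xyz=df[["vx", "vy", "vz"]].to_numpy(float),
            homolog_id=df["homolog_id"].to_numpy(),
        )


@dataclass
class ExpressionMatrix:
    """Parcels x genes Z-scored expression matrix.

    ``values`` has one row per parcel in ``parcel_ids``; rows where
    ``covered_mask`` is False hold NaN (uncovered parcels are excluded from
    analysis, never imputed). ``degenerate_genes`` flags zero-SD columns.
    """

    parcel_ids: np.ndarray
    gene_ids: np.ndarray
    values: np.ndarray
    covered_mask: np.ndarray
    degenerate_genes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.covered_mask = np.asarray(self.covered_mask, dtype=bool)
        if self.degenerate_genes is None:
            self.degenerate_genes = np.zeros(len(self.gene_ids), dtype=bool)
        else:
            self.degenerate_genes = np.asarray(self.degenerate_genes, dtype=bool)
        if self.values.shape != (len(self.parcel_ids), len(self.gene_ids)):
            raise ValueError("values shape must be (n_parcels, n_genes)")

    @property
    def n_covered(self) -> int:
        return int(self.covered_mask.sum())

    @property
    def covered_values(self) -> np.ndarray:
        return self.values[self.covered_mask]

    @property
    def covered_parcel_ids(self) -> np.ndarray:
        return self.parcel_ids[self.covered_mask]

    def analysis_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Covered rows restricted to non-degenerate genes.

        Returns (matrix, gene_ids) as used by PLS.
        """
        keep = ~self.degenerate_genes
        return self.covered_values[:, keep], self.gene_ids[keep]


@dataclass
class ConnectivityDataset:
    """Subject-level Fisher-z connectivity features plus metadata.

    ``features`` is subjects x F; ``feature_index`` is a list of
    (seed_parcel_id, target_parcel_id) tuples; ``metadata`` holds one row per
    subject with columns subject_id, sex ('M'/'F'), diagnosis ('HC'/'MDD'),
    site, age.
    """

    features: np.ndarray
    feature_index: list
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.feature_index = [tuple(f) for f in self.feature_index]
        if self.features.shape != (len(self.metadata), len(self.feature_index)):
            raise ValueError("features shape must be (n_subjects, n_features)")
        if any(s == t for s, t in self.feature_index):
            raise ValueError("feature index contains self-pairs")
        required = {"subject_id", "sex", "diagnosis", "site", "age"}
        missing = required - set(self.metadata.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, mask: np.ndarray) -> "ConnectivityDataset":
        mask = np.asarray(mask)
        return ConnectivityDataset(
            features=self.features[mask],
            feature_index=self.feature_index,
            metadata=self.metadata.iloc[mask].reset_index(drop=True)
            if mask.dtype == bool or mask.dtype.kind in "iu"
            else self.metadata.loc[mask].reset_index(drop=True),
        )

    def feature_columns(self, seed_parcels) -> dict:
        """Map target parcel -> column indices of features seeded in seed_parcels."""
        seeds = set(seed_parcels)
        cols: dict = {}
        for j, (s, t) in enumerate(self.feature_index):
            if s in seeds:
                cols.setdefault(t, []).append(j)
        return cols


@dataclass
class EffectMap:
    """Per-parcel case-control effect sizes for one seed region and stratum."""

    seed_label: str
    sex: str
    parcel_ids: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray

    def __post_init__(self) -> None:
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=object)
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)

    def aligned_to(self, parcel_ids) -> np.ndarray:
        """t-values reindexed to the given parcel order (KeyError if absent)."""
        idx = {p: i for i, p in enumerate(self.parcel_ids)}
        return self.t_values[[idx[p] for p in parcel_ids]]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional direction tags."""

    sets: dict
    directions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {str(k): list(v) for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def filtered(self, universe, min_size: int = 15, max_size: int = 500):
        """Restrict members to the universe and drop out-of-size sets.

        Returns (GeneSetCollection, excluded set names).
        """
        uni = set(universe)
        kept, excluded = {}, []
        for name, members in self.sets.items():
            inter = [g for g in members if g in uni]
            if min_size <= len(inter) <= max_size:
                kept[name] = inter
            else:
                excluded.append(name)
        return GeneSetCollection(kept, dict(self.directions)), excluded


@dataclass
class GenotypeTable:
    """Subjects x SNPs allele counts with per-SNP annotations.

    ``counts`` holds {0, 1, 2} with NaN for missing calls. ``annotations``
    maps snp_id -> dict with keys such as risk_allele, target_gene,
    direction.
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    counts: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError("counts shape must be (n_subjects, n_snps)")
        observed = self.counts[~np.isnan(self.counts)]
        if observed.size and not np.isin(observed, [0.0, 1.0, 2.0]).all():
            raise ValueError("allele counts must be 0, 1, 2 or missing")

    def column(self, snp_id: str) -> np.ndarray:
        j = int(np.flatnonzero(self.snp_ids == snp_id)[0])
        return self.counts[:, j]

    def select_snps(self, snp_ids) -> "GenotypeTable":
        keep = [int(np.flatnonzero(self.snp_ids == s)[0]) for s in snp_ids]
        return GenotypeTable(
            subject_ids=self.subject_ids,
            snp_ids=self.snp_ids[keep],
            counts=self.counts[:, keep],
            annotations={s: self.annotations[s] for s in snp_ids if s in self.annotations},
        )
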