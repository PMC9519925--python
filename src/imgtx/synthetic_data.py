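"""Synthetic fixture generators for every input the pipeline consumes.

Generators are bit-reproducible given (parameters, seed) and record the
ground truth they used (planted gene weights, effect sizes, enriched sets,
causal variants) so downstream tests can do parameter recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from imgtx._utils import great_circle_distance, rng_from
from imgtx.types import ConnectivityDataset, EffectMap, GeneSetCollection, GenotypeTable, ParcelGeometry

__all__ = [
    "EffectSpec",
    "SyntheticTruth",
    "DonorSampleSet",
    "make_parcellation",
    "simulate_expression_atlas",
    "simulate_subject_rsfc",
    "plant_gene_association",
    "simulate_gene_sets",
    "simulate_genotypes",
    "simulate_time_series",
    "all_pair_feature_index",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_SPHERE_RADIUS_MM = 70.0


@dataclass
class EffectSpec:
    """Additive per-feature effects for the two-way factorial rsFC design.

    Each field broadcasts to the feature vector: scalars apply to all
    features, arrays must have length F. ``site_shifts`` maps site label to
    a per-feature additive shift. Sex is coded 0 = F, 1 = M; diagnosis
    0 = HC, 1 = MDD; the interaction is their product.
    """

    baseline: float | np.ndarray = 0.0
    beta_sex: float | np.ndarray = 0.0
    beta_mdd: float | np.ndarray = 0.0
    beta_int: float | np.ndarray = 0.0
    site_shifts: dict = field(default_factory=dict)

    def as_arrays(self, n_features: int) -> dict:
        def bc(v):
            arr = np.broadcast_to(np.asarray(v, dtype=float), (n_features,)).copy()
            return arr

        return {
            "baseline": bc(self.baseline),
            "beta_sex": bc(self.beta_sex),
            "beta_mdd": bc(self.beta_mdd),
            "beta_int": bc(self.beta_int),
            "site_shifts": {s: bc(v) for s, v in self.site_shifts.items()},
        }


@dataclass
class SyntheticTruth:
    """Ground-truth record serialized alongside every fixture."""

    gene_weights: dict = field(default_factory=dict)
    snr: float | None = None
    effect_spec: EffectSpec | None = None
    enriched_sets: dict = field(default_factory=dict)
    causal_snps: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        out = {
            "gene_weights": {k: float(v) for k, v in self.gene_weights.items()},
            "snr": self.snr,
            "enriched_sets": self.enriched_sets,
            "causal_snps": self.causal_snps,
            "extras": {},
        }
        if self.effect_spec is not None:
            out["effect_spec"] = {
                "baseline": np.asarray(self.effect_spec.baseline).tolist(),
                "beta_sex": np.asarray(self.effect_spec.beta_sex).tolist(),
                "beta_mdd": np.asarray(self.effect_spec.beta_mdd).tolist(),
                "beta_int": np.asarray(self.effect_spec.beta_int).tolist(),
                "site_shifts": {
                    s: np.asarray(v).tolist() for s, v in self.effect_spec.site_shifts.items()
                },
            }
        for k, v in self.extras.items():
            out["extras"][k] = np.asarray(v).tolist() if isinstance(v, np.ndarray) else v
        return out


@dataclass
class DonorSampleSet:
    """One donor's microarray samples: coordinates plus probe expression."""

    donor_id: str
    samples: pd.DataFrame  # sample_id, x, y, z, hemisphere
    probe_expression: pd.DataFrame  # probes x samples
    probe_to_gene: dict

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValueError("donor must carry at least one sample")
        unmapped = set(self.probe_expression.index) - set(self.probe_to_gene)
        if unmapped:
            raise ValueError(f"probes without gene mapping: {sorted(unmapped)[:3]}")
        coords = self.samples[["x", "y", "z"]].to_numpy(float)
        if not np.isfinite(coords).all():
            raise ValueError("sample coordinates must be finite")


_HEMI_VOLUME_OFFSET_MM = 90.0


def make_parcellation(n_per_hemisphere: int, seed: int, jitter: float = 0.3) -> ParcelGeometry:
    """Quasi-uniform spherical parcellation with exact homolog mirroring.

    Each hemisphere's surface is projected to its own full unit sphere (as in
    surface-based spin permutation, where one hemisphere inflates to one
    sphere): left-hemisphere centroids come from a deterministic Fibonacci
    lattice jittered tangentially by ``seed``, and each right parcel is the
    exact x-mirror of its left homolog. Volumetric loci put the hemispheres
    on opposite sides of x = 0, also exact mirrors.
    """
    if n_per_hemisphere < 4:
        raise ValueError("n_per_hemisphere must be >= 4")
    rng = rng_from(seed)
    n = n_per_hemisphere
    i = np.arange(n)
    # Fibonacci lattice over the full sphere
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * _GOLDEN_ANGLE
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # tangential jitter scaled to typical lattice spacing
    scale = jitter * np.sqrt(4.0 * np.pi / n)
    noise = rng.normal(scale=scale, size=(n, 3))
    pts = pts + noise - (np.sum(noise * pts, axis=1, keepdims=True)) * pts
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)

    mirrored = pts.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    sphere = np.vstack([pts, mirrored])

    offset = np.array([_HEMI_VOLUME_OFFSET_MM, 0.0, 0.0])
    volume = np.vstack(
        [pts * _SPHERE_RADIUS_MM - offset, mirrored * _SPHERE_RADIUS_MM + offset]
    )

    width = len(str(n))
    left_ids = [f"L{k + 1:0{width}d}" for k in range(n)]
    right_ids = [f"R{k + 1:0{width}d}" for k in range(n)]
    return ParcelGeometry(
        parcel_ids=np.array(left_ids + right_ids, dtype=object),
        hemisphere=np.array(["L"] * n + ["R"] * n, dtype=object),
        sphere_xyz=sphere,
        volume_xyz=volume,
        homolog_id=np.array(right_ids + left_ids, dtype=object),
    )


def effective_positions(geometry: ParcelGeometry) -> np.ndarray:
    """Sphere coordinates with the right hemisphere mirrored onto the left
    sphere, so homologs coincide.

    Each hemisphere is its own full sphere; in this shared frame the paired
    hemispheric spin rotations (R and its x-mirror) act as one coherent
    rotation, so spatial structure defined here is exactly what the spin
    null preserves.
    """
    eff = geometry.sphere_xyz.copy()
    right = geometry.hemisphere == "R"
    eff[right, 0] = -eff[right, 0]
    return eff


def _gene_fields(geometry: ParcelGeometry, n_genes: int, smoothness: float, rng) -> np.ndarray:
    """Zero-mean Gaussian fields with covariance exp(-d/smoothness) over
    great-circle distance between effective positions, drawn by Cholesky at
    parcel resolution. Homolog pairs coincide in the effective frame, so the
    fields are mirror-symmetric up to the numerical jitter."""
    d = great_circle_distance(effective_positions(geometry))
    cov = np.exp(-d / smoothness)
    L = np.linalg.cholesky(cov + 1e-8 * np.eye(geometry.n_parcels))
    return L @ rng.standard_normal((geometry.n_parcels, n_genes))


def simulate_expression_atlas(
    geometry: ParcelGeometry,
    n_genes: int,
    n_donors: int,
    smoothness: float,
    probes_per_gene: int = 2,
    right_hemi_donor_fraction: float = 2.0 / 6.0,
    seed: int = 0,
    sample_noise_sd: float = 0.2,
    coord_jitter_mm: float = 0.5,
    parcel_coverage: float = 0.9,
    gene_ids: list | None = None,
) -> tuple[list[DonorSampleSet], SyntheticTruth]:
    """Simulate donor microarray sample sets over smooth latent gene fields.

    Each gene has one latent spatial field shared by all donors; each donor
    observes noisy probe replicates at sample sites jittered around a random
    subset of parcel loci. Only ``round(fraction * n_donors)`` donors carry
    right-hemisphere samples. Returns the donors and a truth record whose
    ``extras['gene_fields']`` holds the latent parcels x genes fields.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    rng = rng_from(seed)
    if gene_ids is None:
        gene_ids = [f"GENE{g + 1:05d}" for g in range(n_genes)]
    fields = _gene_fields(geometry, n_genes, smoothness, rng)

    n_right = int(round(right_hemi_donor_fraction * n_donors))
    right_donors = set(rng.choice(n_donors, size=n_right, replace=False).tolist())

    probe_ids = [
        f"{g}_p{j + 1}" for g in gene_ids for j in range(probes_per_gene)
    ]
    probe_to_gene = {p: p.rsplit("_p", 1)[0] for p in probe_ids}
    gene_of_probe = np.repeat(np.arange(n_genes), probes_per_gene)

    donors = []
    for di in range(n_donors):
        allowed = np.ones(geometry.n_parcels, dtype=bool)
        if di not in right_donors:
            allowed &= geometry.hemisphere == "L"
        covered = allowed & (rng.random(geometry.n_parcels) < parcel_coverage)
        if not covered.any():  # guarantee the >=1 sample invariant
            covered[np.flatnonzero(allowed)[0]] = True
        pidx = np.flatnonzero(covered)
        coords = geometry.volume_xyz[pidx] + rng.normal(
            scale=coord_jitter_mm, size=(len(pidx), 3)
        )
        sample_ids = [f"D{di + 1}_S{k + 1:03d}" for k in range(len(pidx))]
        samples = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
                "hemisphere": geometry.hemisphere[pidx],
            }
        )
        # probes x samples: gene field value at the sample's parcel + probe noise
        base = fields[np.ix_(pidx, gene_of_probe)].T
        expr = base + rng.normal(scale=sample_noise_sd, size=base.shape)
        donors.append(
            DonorSampleSet(
                donor_id=f"D{di + 1}",
                samples=samples,
                probe_expression=pd.DataFrame(expr, index=probe_ids, columns=sample_ids),
                probe_to_gene=probe_to_gene,
            )
        )
    truth = SyntheticTruth(
        extras={
            "gene_fields": fields,
            "gene_ids": list(gene_ids),
            "smoothness": smoothness,
            "right_hemisphere_donors": sorted(f"D{d + 1}" for d in right_donors),
        }
    )
    return donors, truth


def gp_expression_matrix(
    geometry: ParcelGeometry,
    n_genes: int,
    smoothness: float,
    seed: int,
    noise_fraction: float = 0.0,
):
    """Column-standardized smooth expression matrix drawn directly at parcel
    resolution (bypasses the donor/probe pipeline; full coverage).

    ``noise_fraction`` of each column's variance is spatially white, mimicking
    measurement noise on top of the smooth latent fields. Convenience for
    null-calibration studies where probe-level structure is irrelevant.
    """
    from imgtx.types import ExpressionMatrix

    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if not 0 <= noise_fraction < 1:
        raise ValueError("noise_fraction must be in [0, 1)")
    rng = rng_from(seed)
    fields = _gene_fields(geometry, n_genes, smoothness, rng)
    fields = (fields - fields.mean(axis=0)) / fields.std(axis=0)
    if noise_fraction > 0:
        white = rng.standard_normal(fields.shape)
        fields = np.sqrt(1 - noise_fraction) * fields + np.sqrt(noise_fraction) * white
    vals = (fields - fields.mean(axis=0)) / fields.std(axis=0)
    gene_ids = np.array([f"GENE{g + 1:05d}" for g in range(n_genes)], dtype=object)
    return ExpressionMatrix(
        parcel_ids=geometry.parcel_ids,
        gene_ids=gene_ids,
        values=vals,
        covered_mask=np.ones(geometry.n_parcels, dtype=bool),
    )


def factor_expression_matrix(
    geometry: ParcelGeometry,
    n_genes: int,
    n_factors: int,
    smoothness: float,
    seed: int,
    gene_noise_fraction: float = 0.3,
):
    """Expression matrix with gene co-expression structure.

    Genes are random mixtures of ``n_factors`` smooth latent spatial fields
    plus per-gene white noise, mimicking transcriptomic co-expression modules
    (thousands of genes, far fewer independent spatial patterns). The column
    space is then a proper low-dimensional subspace rather than all smooth
    maps, which is what gives gene-map association tests leverage over
    spatial nulls.
    """
    from imgtx.types import ExpressionMatrix

    rng = rng_from(seed)
    F = _gene_fields(geometry, n_factors, smoothness, rng)
    F = (F - F.mean(axis=0)) / F.std(axis=0)
    A = rng.standard_normal((n_factors, n_genes)) / np.sqrt(n_factors)
    vals = F @ A
    vals = (vals - vals.mean(axis=0)) / vals.std(axis=0)
    if gene_noise_fraction > 0:
        white = rng.standard_normal(vals.shape)
        vals = np.sqrt(1 - gene_noise_fraction) * vals + np.sqrt(gene_noise_fraction) * white
    vals = (vals - vals.mean(axis=0)) / vals.std(axis=0)
    gene_ids = np.array([f"GENE{g + 1:05d}" for g in range(n_genes)], dtype=object)
    return ExpressionMatrix(
        parcel_ids=geometry.parcel_ids,
        gene_ids=gene_ids,
        values=vals,
        covered_mask=np.ones(geometry.n_parcels, dtype=bool),
    )


def gp_effect_map(
    geometry: ParcelGeometry,
    smoothness: float,
    seed: int,
    noise_fraction: float = 0.0,
    seed_label: str = "synthetic",
    sex: str = "M",
) -> EffectMap:
    """One smooth-plus-noise map packaged as an EffectMap (t-map analogue)."""
    X = gp_expression_matrix(geometry, 1, smoothness, seed, noise_fraction)
    return EffectMap(
        seed_label=seed_label,
        sex=sex,
        parcel_ids=geometry.parcel_ids,
        t_values=X.values[:, 0],
        p_values=np.full(geometry.n_parcels, np.nan),
    )


def all_pair_feature_index(seed_parcels, target_parcels) -> list:
    """Cross product of seeds and targets, excluding self-pairs."""
    return [(s, t) for s, t in itertools.product(seed_parcels, target_parcels) if s != t]


def simulate_subject_rsfc(
    geometry: ParcelGeometry,
    n_per_cell: dict,
    effect_spec: EffectSpec,
    noise_sd: float,
    seed: int,
    feature_index: list | None = None,
) -> tuple[ConnectivityDataset, SyntheticTruth]:
    """Draw subject-level Fisher-z connectivity from the factorial design.

    ``n_per_cell`` maps (sex, diagnosis, site) -> subject count. Feature f of
    subject s is baseline + site shift + beta_sex*male + beta_mdd*mdd +
    beta_int*male*mdd + Normal(0, noise_sd) noise, generated directly at
    Fisher-z scale.
    """
    if feature_index is None:
        seeds = [geometry.parcel_ids[0]]
        feature_index = all_pair_feature_index(seeds, list(geometry.parcel_ids))
    n_features = len(feature_index)
    spec = effect_spec.as_arrays(n_features)

    cells = {k: int(v) for k, v in n_per_cell.items() if int(v) > 0}
    if any(v < 2 for v in cells.values()):
        raise ValueError("each nonempty design cell needs >= 2 subjects")
    present_sexdx = {(s, d) for (s, d, _site) in cells}
    if np.any(spec["beta_int"] != 0) and len(present_sexdx) < 4:
        raise ValueError("interaction effect requires all four sex x diagnosis cells")
    if np.any(spec["beta_mdd"] != 0) and not any(d == "MDD" for _, d in present_sexdx):
        raise ValueError("diagnosis effect references an empty MDD cell")
    missing_sites = set(spec["site_shifts"]) - {site for *_, site in cells}
    if missing_sites:
        raise ValueError(f"site shift references empty site(s): {sorted(missing_sites)}")

    rng = rng_from(seed)
    rows, meta = [], []
    sid = 0
    for (sex, dx, site), n in sorted(cells.items()):
        male = 1.0 if sex == "M" else 0.0
        mdd = 1.0 if dx == "MDD" else 0.0
        mean = (
            spec["baseline"]
            + spec["site_shifts"].get(site, 0.0)
            + spec["beta_sex"] * male
            + spec["beta_mdd"] * mdd
            + spec["beta_int"] * male * mdd
        )
        block = mean + rng.normal(scale=noise_sd, size=(n, n_features))
        rows.append(block)
        for _ in range(n):
            sid += 1
            meta.append(
                {
                    "subject_id": f"sub{sid:05d}",
                    "sex": sex,
                    "diagnosis": dx,
                    "site": site,
                    "age": float(np.round(rng.uniform(18, 65), 1)),
                }
            )
    dataset = ConnectivityDataset(
        features=np.vstack(rows),
        feature_index=feature_index,
        metadata=pd.DataFrame(meta),
    )
    truth = SyntheticTruth(effect_spec=effect_spec, extras={"noise_sd": noise_sd})
    return dataset, truth


def plant_gene_association(
    X: np.ndarray,
    gene_ids,
    parcel_ids,
    sparsity: float,
    snr: float,
    seed: int,
    seed_label: str = "planted",
    sex: str = "M",
) -> tuple[EffectMap, SyntheticTruth]:
    """Plant Y = X w + noise with a sparse weight vector at the given SNR.

    X must be column-standardized over its rows. The returned EffectMap's
    t_values hold Y; the truth records the dense weight vector.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    X = np.asarray(X, dtype=float)
    P, G = X.shape
    k = int(np.ceil(sparsity * G))
    if not 1 <= k <= G:
        raise ValueError("sparsity must yield between 1 and G nonzero weights")
    rng = rng_from(seed)
    support = rng.choice(G, size=k, replace=False)
    w = np.zeros(G)
    w[support] = rng.standard_normal(k)
    signal = X @ w
    signal = signal - signal.mean()
    noise = rng.standard_normal(P)
    noise = noise - noise.mean()
    sig_var = signal.var()
    noise_var = noise.var()
    if noise_var > 0 and np.isfinite(snr):
        noise = noise * np.sqrt(sig_var / (snr * noise_var))
    else:
        noise = np.zeros(P)
    y = signal + noise
    effect = EffectMap(
        seed_label=seed_label,
        sex=sex,
        parcel_ids=np.asarray(parcel_ids, dtype=object),
        t_values=y,
        p_values=np.full(P, np.nan),
    )
    truth = SyntheticTruth(
        gene_weights={g: float(v) for g, v in zip(gene_ids, w)},
        snr=float(snr),
        extras={"support": np.sort(support), "signal_variance": sig_var},
    )
    return effect, truth


def simulate_gene_sets(
    gene_ids,
    planted: list,
    n_random_sets: int,
    seed: int,
    in_decile_fraction: float = 0.9,
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Build planted and random gene sets against a ranked gene universe.

    ``gene_ids`` must already be in rank order (best first); deciles are by
    rank position. ``planted`` is a list of (set_size, target_decile,
    direction) triples; planted sets draw ``in_decile_fraction`` of members
    from the target decile and the rest uniformly from outside it.
    """
    genes = np.asarray(gene_ids, dtype=object)
    G = len(genes)
    rng = rng_from(seed)
    decile_of = np.minimum(np.arange(G) * 10 // G + 1, 10)

    sets, directions, truth_sets = {}, {}, {}
    for si, (set_size, target_decile, direction) in enumerate(planted):
        if not 1 <= target_decile <= 10:
            raise ValueError("target_decile must be in 1..10")
        if set_size >= G:
            raise ValueError("set_size must be smaller than the gene universe")
        inside = np.flatnonzero(decile_of == target_decile)
        outside = np.flatnonzero(decile_of != target_decile)
        n_in = min(int(round(in_decile_fraction * set_size)), len(inside))
        n_out = set_size - n_in
        members = np.concatenate(
            [
                rng.choice(inside, size=n_in, replace=False),
                rng.choice(outside, size=n_out, replace=False),
            ]
        )
        name = f"planted_d{target_decile}_{si + 1}"
        sets[name] = genes[np.sort(members)].tolist()
        directions[name] = direction
        truth_sets[name] = {"decile": target_decile, "direction": direction, "size": set_size}
    for ri in range(n_random_sets):
        size = int(rng.integers(15, max(16, min(200, G // 2))))
        members = rng.choice(G, size=size, replace=False)
        sets[f"random_{ri + 1}"] = genes[np.sort(members)].tolist()
    collection = GeneSetCollection(sets, directions)
    return collection, SyntheticTruth(enriched_sets=truth_sets)


def simulate_genotypes(
    snp_spec: dict,
    seed: int,
    n_subjects: int | None = None,
    causal_spec: dict | None = None,
    dataset: ConnectivityDataset | None = None,
) -> tuple[GenotypeTable, ConnectivityDataset | None, SyntheticTruth]:
    """Draw genotypes from Hardy-Weinberg proportions and plant causal effects.

    ``snp_spec`` maps snp_id -> {maf, missing_rate, hwe_violation, and
    optional annotation keys (risk_allele, target_gene, direction)}. For each
    entry of ``causal_spec`` (snp_id -> {feature: (seed, target), effect,
    sex}) the named rsFC feature of subjects in the affected sex is shifted
    by allele_count * effect; requires ``dataset``.
    """
    if dataset is not None:
        n_subjects = dataset.n_subjects
    if n_subjects is None:
        raise ValueError("n_subjects or dataset required")
    rng = rng_from(seed)
    snp_ids = list(snp_spec)
    counts = np.empty((n_subjects, len(snp_ids)))
    annotations = {}
    for j, snp in enumerate(snp_ids):
        spec = snp_spec[snp]
        maf = float(spec["maf"])
        if not 0 < maf < 0.5:
            raise ValueError(f"{snp}: maf must be in (0, 0.5)")
        if spec.get("hwe_violation", False):
            # excess homozygosity via inbreeding coefficient
            f = 0.5
            probs = [
                (1 - maf) ** 2 + f * maf * (1 - maf),
                2 * maf * (1 - maf) * (1 - f),
                maf**2 + f * maf * (1 - maf),
            ]
        else:
            probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
        counts[:, j] = rng.choice([0.0, 1.0, 2.0], size=n_subjects, p=probs)
        miss = float(spec.get("missing_rate", 0.0))
        if miss > 0:
            counts[rng.random(n_subjects) < miss, j] = np.nan
        annotations[snp] = {
            k: spec[k] for k in ("risk_allele", "target_gene", "direction") if k in spec
        }

    out_dataset = dataset
    causal_truth = {}
    if causal_spec:
        if dataset is None:
            raise ValueError("causal_spec requires a ConnectivityDataset")
        features = dataset.features.copy()
        findex = {f: i for i, f in enumerate(dataset.feature_index)}
        male = (dataset.metadata["sex"] == "M").to_numpy()
        for snp, cspec in causal_spec.items():
            feat = tuple(cspec["feature"])
            if feat not in findex:
                raise ValueError(f"causal feature {feat} absent from dataset")
            col = counts[:, snp_ids.index(snp)]
            in_sex = male if cspec["sex"] == "M" else ~male
            shift = np.nan_to_num(col) * float(cspec["effect"]) * in_sex
            features[:, findex[feat]] += shift
            causal_truth[snp] = {
                "feature": list(feat),
                "effect": float(cspec["effect"]),
                "sex": cspec["sex"],
            }
        out_dataset = ConnectivityDataset(
            features=features,
            feature_index=dataset.feature_index,
            metadata=dataset.metadata.copy(),
        )
    table = GenotypeTable(
        subject_ids=np.array(
            dataset.metadata["subject_id"].tolist()
            if dataset is not None
            else [f"sub{i + 1:05d}" for i in range(n_subjects)],
            dtype=object,
        ),
        snp_ids=np.array(snp_ids, dtype=object),
        counts=counts,
        annotations=annotations,
    )
    return table, out_dataset, SyntheticTruth(causal_snps=causal_truth)


def simulate_time_series(
    n_regions: int,
    n_timepoints: int,
    seed: int,
    shared_weight: float = 0.5,
    ar_coef: float = 0.3,
) -> np.ndarray:
    """AR(1) region time series sharing a common latent component.

    Provided only to exercise the Pearson/Fisher-z connectivity computation;
    not a model of BOLD physiology.
    """
    rng = rng_from(seed)
    common = rng.standard_normal(n_timepoints)
    out = np.empty((n_regions, n_timepoints))
    for r in range(n_regions):
        eps = rng.standard_normal(n_timepoints)
        x = np.empty(n_timepoints)
        x[0] = eps[0]
        for t in range(1, n_timepoints):
            x[t] = ar_coef * x[t - 1] + eps[t]
        out[r] = shared_weight * common + (1 - shared_weight) * x
    return out
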