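"""Donor microarray samples -> final parcels x genes Z-scored matrix.

Pipeline order: collapse probes to genes -> assign samples to parcels within
a 2 mm radius -> per-donor parcel means with per-gene Z over covered parcels
-> hemisphere mirroring -> cross-donor mean with a final per-gene Z.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from imgtx.synthetic_data import DonorSampleSet
from imgtx.types import ExpressionMatrix, ParcelGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "collapse_probes",
    "assign_samples_to_parcels",
    "build_donor_matrix",
    "mirror_hemispheres",
    "aggregate_donors",
    "build_expression_matrix",
]


def collapse_probes(probe_expression: pd.DataFrame, probe_to_gene: dict) -> pd.DataFrame:
    """Average probe rows belonging to the same gene.

    Returns a genes x samples frame with genes in lexicographic order.
    Probes lacking a gene mapping raise; genes with zero probes simply do
    not appear.
    """
    unmapped = [p for p in probe_expression.index if p not in probe_to_gene]
    if unmapped:
        raise ValueError(f"unmapped probes: {unmapped[:3]}")
    genes = pd.Index([probe_to_gene[p] for p in probe_expression.index], name="gene")
    collapsed = probe_expression.groupby(genes).mean()
    return collapsed.sort_index()


def assign_samples_to_parcels(
    samples: pd.DataFrame, geometry: ParcelGeometry, radius_mm: float = 2.0
) -> dict:
    """Map each sample to the nearest parcel locus within ``radius_mm``.

    Euclidean distance in the volumetric frame; ties go to the
    lexicographically smaller parcel_id. Samples with no locus in range are
    dropped (counted in the log). Returns {sample_id: parcel_id}.
    """
    coords = samples[["x", "y", "z"]].to_numpy(float)
    # sort parcels by id so argmin resolves exact ties lexicographically
    order = np.argsort(geometry.parcel_ids.astype(str))
    loci = geometry.volume_xyz[order]
    ids = geometry.parcel_ids[order]
    d = np.linalg.norm(coords[:, None, :] - loci[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    within = d[np.arange(len(coords)), nearest] <= radius_mm
    assignment = {
        sid: ids[j]
        for sid, j, ok in zip(samples["sample_id"], nearest, within)
        if ok
    }
    n_dropped = len(samples) - len(assignment)
    if n_dropped:
        logger.warning("%d/%d samples outside %.1f mm of any parcel locus", n_dropped, len(samples), radius_mm)
    if not assignment:
        logger.warning("no samples assigned to any parcel")
    return assignment


def build_donor_matrix(
    donor: DonorSampleSet, assignment: dict, geometry: ParcelGeometry
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-parcel gene means for one donor, Z-scored per gene over covered parcels.

    Returns (parcels x genes frame over the full parcel set, NaN where
    uncovered) and a boolean flag array marking zero-SD gene columns (set to
    all-zero over covered parcels).
    """
    if not assignment:
        raise ValueError("assignment is empty")
    gene_by_sample = collapse_probes(donor.probe_expression, donor.probe_to_gene)
    sample_ids = [s for s in gene_by_sample.columns if s in assignment]
    parcel_of = pd.Index([assignment[s] for s in sample_ids], name="parcel_id")
    by_parcel = gene_by_sample[sample_ids].T.groupby(parcel_of).mean()  # parcels x genes

    out = pd.DataFrame(
        np.nan, index=pd.Index(geometry.parcel_ids, name="parcel_id"), columns=gene_by_sample.index
    )
    out.loc[by_parcel.index] = by_parcel.to_numpy()

    covered = out.notna().all(axis=1).to_numpy()
    vals = out.to_numpy()
    sub = vals[covered]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    vals[covered] = (sub - mean) / sd_safe
    if degenerate.any():
        vals[np.ix_(covered, degenerate)] = 0.0
        logger.warning("%d gene columns constant across parcels; zeroed", int(degenerate.sum()))
    out.iloc[:, :] = vals
    return out, degenerate


def mirror_hemispheres(donor_matrix: pd.DataFrame, geometry: ParcelGeometry) -> pd.DataFrame:
    """Share coverage across hemispheres through homolog pairs.

    A parcel covered in one hemisphere only donates its values to its
    homolog; parcels covered in both get the mean of the pair written to
    both sides. Idempotent.
    """
    out = donor_matrix.copy()
    vals = out.to_numpy()
    hidx = geometry.homolog_index
    covered = ~np.isnan(vals).any(axis=1)
    mate_covered = covered[hidx]
    mirrored = vals.copy()
    both = covered & mate_covered
    mirrored[both] = (vals[both] + vals[hidx[both]]) / 2.0
    only_mate = ~covered & mate_covered
    mirrored[only_mate] = vals[hidx[only_mate]]
    out.iloc[:, :] = mirrored
    return out


def aggregate_donors(donor_matrices: list[pd.DataFrame]) -> ExpressionMatrix:
    """Mean over covering donors per parcel, then a final per-gene Z-score."""
    if not donor_matrices:
        raise ValueError("need at least one donor matrix")
    ref = donor_matrices[0]
    for m in donor_matrices[1:]:
        if not (m.index.equals(ref.index) and m.columns.equals(ref.columns)):
            raise ValueError("donor matrices must share parcel and gene indices")
    stack = np.stack([m.to_numpy() for m in donor_matrices])  # donors x parcels x genes
    donor_covered = ~np.isnan(stack).any(axis=2)  # donors x parcels
    covered = donor_covered.any(axis=0)
    if not covered.any():
        raise ValueError("no parcel covered by any donor")
    mean = np.full(stack.shape[1:], np.nan)
    mean[covered] = np.nanmean(stack[:, covered, :], axis=0)

    sub = mean[covered]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    mean[covered] = (sub - mu) / sd_safe
    if degenerate.any():
        mean[np.ix_(covered, degenerate)] = 0.0
        logger.warning("%d aggregated gene columns have zero SD; zeroed and flagged", int(degenerate.sum()))
    return ExpressionMatrix(
        parcel_ids=ref.index.to_numpy(),
        gene_ids=ref.columns.to_numpy(),
        values=mean,
        covered_mask=covered,
        degenerate_genes=degenerate,
    )


def build_expression_matrix(
    donors: list[DonorSampleSet],
    geometry: ParcelGeometry,
    radius_mm: float = 2.0,
    mirror: bool = True,
) -> ExpressionMatrix:
    """Full mapping pipeline: collapse -> assign -> build -> mirror -> aggregate."""
    matrices = []
    for donor in donors:
        assignment = assign_samples_to_parcels(donor.samples, geometry, radius_mm)
        if not assignment:
            logger.warning("donor %s contributed no assigned samples; skipped", donor.donor_id)
            continue
        m, _flags = build_donor_matrix(donor, assignment, geometry)
        if mirror:
            m = mirror_hemispheres(m, geometry)
        matrices.append(m)
    if not matrices:
        raise ValueError("no donor produced an assignable sample set")
    return aggregate_donors(matrices)
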