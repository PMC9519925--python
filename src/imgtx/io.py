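"""Plain-text readers and writers for every pipeline artifact.

All formats are uncompressed text: TSV matrices, AHBA-dialect CSV triplets,
GMT gene sets, JSON sidecars for masks/truth/results.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from imgtx.synthetic_data import DonorSampleSet, SyntheticTruth
from imgtx.types import ConnectivityDataset, EffectMap, ExpressionMatrix, GeneSetCollection, GenotypeTable, ParcelGeometry

__all__ = [
    "write_geometry", "read_geometry",
    "write_expression_matrix", "read_expression_matrix",
    "write_rsfc", "read_rsfc",
    "write_effect_map", "read_effect_map",
    "write_donor_ahba", "read_donor_ahba",
    "write_gmt", "read_gmt",
    "write_genotypes", "read_genotypes",
    "write_truth", "read_truth",
    "write_ranked_genes", "read_ranked_genes",
]


def write_geometry(geometry: ParcelGeometry, path) -> None:
    geometry.to_frame().to_csv(path, sep="\t", index=False)


def read_geometry(path) -> ParcelGeometry:
    return ParcelGeometry.from_frame(pd.read_csv(path, sep="\t"))


def write_expression_matrix(X: ExpressionMatrix, path) -> None:
    """Values as TSV (first column parcel_id); masks in a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(X.values, index=pd.Index(X.parcel_ids, name="parcel_id"), columns=X.gene_ids)
    df.to_csv(path, sep="\t")
    sidecar = {
        "covered_mask": X.covered_mask.astype(int).tolist(),
        "degenerate_genes": X.degenerate_genes.astype(int).tolist(),
    }
    path.with_suffix(path.suffix + ".mask.json").write_text(json.dumps(sidecar))


def read_expression_matrix(path) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = json.loads(path.with_suffix(path.suffix + ".mask.json").read_text())
    return ExpressionMatrix(
        parcel_ids=df.index.to_numpy(object),
        gene_ids=df.columns.to_numpy(object),
        values=df.to_numpy(float),
        covered_mask=np.array(sidecar["covered_mask"], dtype=bool),
        degenerate_genes=np.array(sidecar["degenerate_genes"], dtype=bool),
    )


def _feature_label(pair) -> str:
    return f"{pair[0]}|{pair[1]}"


def write_rsfc(dataset: ConnectivityDataset, features_path, metadata_path) -> None:
    cols = [_feature_label(p) for p in dataset.feature_index]
    df = pd.DataFrame(dataset.features, columns=cols)
    df.insert(0, "subject_id", dataset.metadata["subject_id"].to_numpy())
    df.to_csv(features_path, sep="\t", index=False)
    dataset.metadata.to_csv(metadata_path, sep="\t", index=False)


def read_rsfc(features_path, metadata_path) -> ConnectivityDataset:
    df = pd.read_csv(features_path, sep="\t")
    meta = pd.read_csv(metadata_path, sep="\t")
    feat_cols = [c for c in df.columns if c != "subject_id"]
    index = [tuple(c.split("|", 1)) for c in feat_cols]
    order = df["subject_id"].to_numpy()
    meta = meta.set_index("subject_id").loc[order].reset_index()
    return ConnectivityDataset(features=df[feat_cols].to_numpy(float), feature_index=index, metadata=meta)


def write_effect_map(effect: EffectMap, path) -> None:
    pd.DataFrame(
        {
            "parcel_id": effect.parcel_ids,
            "t": effect.t_values,
            "p": effect.p_values,
            "seed_label": effect.seed_label,
            "sex": effect.sex,
        }
    ).to_csv(path, sep="\t", index=False)


def read_effect_map(path) -> EffectMap:
    df = pd.read_csv(path, sep="\t")
    return EffectMap(
        seed_label=str(df["seed_label"].iloc[0]),
        sex=str(df["sex"].iloc[0]),
        parcel_ids=df["parcel_id"].to_numpy(object),
        t_values=df["t"].to_numpy(float),
        p_values=df["p"].to_numpy(float),
    )


def write_donor_ahba(donor: DonorSampleSet, out_dir) -> None:
    """AHBA-dialect CSV triplet: SampleAnnot, MicroarrayExpression, Probes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annot = donor.samples.rename(columns={"x": "mni_x", "y": "mni_y", "z": "mni_z"})
    annot.to_csv(out_dir / "SampleAnnot.csv", index=False)
    donor.probe_expression.to_csv(out_dir / "MicroarrayExpression.csv", index_label="probe_id")
    pd.DataFrame(
        {"probe_id": list(donor.probe_to_gene), "gene_id": list(donor.probe_to_gene.values())}
    ).to_csv(out_dir / "Probes.csv", index=False)


def read_donor_ahba(donor_dir, donor_id: str | None = None) -> DonorSampleSet:
    donor_dir = Path(donor_dir)
    annot = pd.read_csv(donor_dir / "SampleAnnot.csv").rename(
        columns={"mni_x": "x", "mni_y": "y", "mni_z": "z"}
    )
    expr = pd.read_csv(donor_dir / "MicroarrayExpression.csv", index_col="probe_id")
    probes = pd.read_csv(donor_dir / "Probes.csv")
    return DonorSampleSet(
        donor_id=donor_id or donor_dir.name,
        samples=annot,
        probe_expression=expr,
        probe_to_gene=dict(zip(probes["probe_id"], probes["gene_id"])),
    )


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.directions.get(name, "na")
            fh.write("\t".join([name, str(desc), *members]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    sets, directions = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, *members = parts
            sets[name] = members
            if desc in ("up", "down", "+", "-"):
                directions[name] = desc
    return GeneSetCollection(sets, directions)


def write_genotypes(table: GenotypeTable, path) -> None:
    path = Path(path)
    df = pd.DataFrame(table.counts, index=pd.Index(table.subject_ids, name="subject_id"), columns=table.snp_ids)
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")
    path.with_suffix(path.suffix + ".annot.json").write_text(json.dumps(table.annotations))


def read_genotypes(path) -> GenotypeTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    annot_path = path.with_suffix(path.suffix + ".annot.json")
    annotations = json.loads(annot_path.read_text()) if annot_path.exists() else {}
    return GenotypeTable(
        subject_ids=df.index.to_numpy(object),
        snp_ids=df.columns.to_numpy(object),
        counts=df.to_numpy(float),
        annotations=annotations,
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_ranked_genes(ranked, path) -> None:
    ranked.table.to_csv(path, sep="\t", index=False)


def read_ranked_genes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
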