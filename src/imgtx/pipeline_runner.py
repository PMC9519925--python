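"""Configuration and end-to-end orchestration of the synthetic workflow.

One master seed spawns a named substream per stage; every run directory
receives the verbatim config, a structured log of stage timings, and a
manifest with a checksum per artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from imgtx import io as iio
from imgtx import synthetic_data as sd
from imgtx.connectivity_stats import combat_harmonize, factorial_anova, seed_effect_map
from imgtx.enrichment import decile_counts, decile_null_ci, gsea_preranked
from imgtx.expression_atlas import build_expression_matrix
from imgtx.genotype_validation import qc_filter_snps, risk_allele_score, score_fc_association
from imgtx.null_models_cv import cross_validate, random_test, spin_test
from imgtx.pls_core import align_xy, bootstrap_loadings, fit_pls
from imgtx.power_sims import sex_composition_bootstrap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_workflow", "DEFAULTS"]

DEFAULTS: dict = {
    "config_version": 1,
    "seed": 0,
    # geometry / atlas
    "n_per_hemisphere": 100,
    "n_genes": 1000,
    "n_donors": 6,
    "smoothness": 0.5,
    "probes_per_gene": 2,
    "right_hemi_donor_fraction": 2.0 / 6.0,
    "radius_mm": 2.0,
    # planted association
    "sparsity": 0.02,
    "snr": 2.0,
    # rsFC sample
    "n_per_cell": 60,
    "sites": ["siteA", "siteB"],
    "site_shift": 0.1,
    "noise_sd": 0.5,
    "effect_scale": 0.3,
    "harmonize": True,
    # PLS / nulls / CV
    "n_components": 2,
    "n_boot": 500,
    "n_perm": 500,
    "cv_repeats": 5,
    "cv_folds": 5,
    # enrichment
    "n_gene_set_perm": 500,
    "planted_set_size": 50,
    "n_random_sets": 5,
    # genetics
    "n_snps": 8,
    "snp_maf": 0.3,
    "causal_effect": 0.15,
    # power sims
    "run_power": False,
    "power_n_iter": 50,
    "power_n_mdd": 60,
    "power_n_hc": 30,
}


@dataclass
class RunConfig:
    """Flat, versioned stage-parameter tree. Unknown keys are rejected."""

    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.params)
        self.params = merged

    def __getitem__(self, key):
        return self.params[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.params, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.params, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_workflow(config: RunConfig, out_dir, seed: int | None = None) -> dict:
    """Execute the synthetic end-to-end workflow into ``out_dir``.

    Stages: simulate geometry and donor atlas -> build the expression matrix
    -> plant a sparse gene-map association -> simulate the factorial rsFC
    sample carrying it as a male-specific effect -> harmonize -> contrasts
    and effect maps -> PLS + bootstrap ranking -> spin/random nulls -> CV ->
    enrichment -> genotype validation (-> power sims if enabled). Returns a
    summary dict; writes artifacts, config, timings, and a checksum manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config["seed"])
    stage_names = [
        "geometry", "atlas", "plant", "rsfc", "contrast", "pls",
        "nulls", "cv", "enrichment", "genetics", "power",
    ]
    ss = np.random.SeedSequence(seed)
    sub = {n: s for n, s in zip(stage_names, ss.spawn(len(stage_names)))}
    seeds = {n: int(s.generate_state(1)[0]) for n, s in sub.items()}
    timings: dict = {}
    summary: dict = {"seed": seed, "config_digest": config.digest()}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_

            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                logger.info("stage %s finished in %.2fs", name, timings[name])

        return _T()

    with stage("geometry"):
        geometry = sd.make_parcellation(config["n_per_hemisphere"], seeds["geometry"])
        iio.write_geometry(geometry, out / "geometry.tsv")

    with stage("atlas"):
        donors, atlas_truth = sd.simulate_expression_atlas(
            geometry,
            n_genes=config["n_genes"],
            n_donors=config["n_donors"],
            smoothness=config["smoothness"],
            probes_per_gene=config["probes_per_gene"],
            right_hemi_donor_fraction=config["right_hemi_donor_fraction"],
            seed=seeds["atlas"],
        )
        X = build_expression_matrix(donors, geometry, radius_mm=config["radius_mm"])
        iio.write_expression_matrix(X, out / "expression.tsv")
        iio.write_truth(atlas_truth, out / "atlas_truth.json")
        summary["n_covered_parcels"] = X.n_covered

    with stage("plant"):
        Xa, gene_ids = X.analysis_matrix()
        planted, plant_truth = sd.plant_gene_association(
            Xa, gene_ids, X.covered_parcel_ids,
            sparsity=config["sparsity"], snr=config["snr"], seed=seeds["plant"],
        )
        iio.write_truth(plant_truth, out / "plant_truth.json")

    with stage("rsfc"):
        seed_parcel = str(geometry.parcel_ids[0])
        targets = [p for p in geometry.parcel_ids if p != seed_parcel]
        findex = sd.all_pair_feature_index([seed_parcel], targets)
        y_by_parcel = dict(zip(planted.parcel_ids, planted.t_values))
        beta_int = np.array([config["effect_scale"] * y_by_parcel.get(t, 0.0) for _s, t in findex])
        spec = sd.EffectSpec(
            beta_int=beta_int,
            site_shifts={s: config["site_shift"] * i for i, s in enumerate(config["sites"])},
        )
        n_per_cell = {
            (sex, dx, site): config["n_per_cell"]
            for sex in ("M", "F")
            for dx in ("HC", "MDD")
            for site in config["sites"]
        }
        dataset, rsfc_truth = sd.simulate_subject_rsfc(
            geometry, n_per_cell, spec, noise_sd=config["noise_sd"],
            seed=seeds["rsfc"], feature_index=findex,
        )
        if config["harmonize"] and len(config["sites"]) > 1:
            dataset = combat_harmonize(dataset)
        iio.write_rsfc(dataset, out / "rsfc.tsv", out / "rsfc_meta.tsv")
        iio.write_truth(rsfc_truth, out / "rsfc_truth.json")

    with stage("contrast"):
        contrasts = factorial_anova(dataset)
        contrasts.table.to_csv(out / "contrasts.tsv", sep="\t", index=False)
        effect_map = seed_effect_map(
            dataset, [seed_parcel], "M", covered_parcel_ids=X.covered_parcel_ids,
        )
        iio.write_effect_map(effect_map, out / "effect_map_male.tsv")

    with stage("pls"):
        Xa, y, gene_ids = align_xy(X, effect_map)
        model = fit_pls(Xa, y, n_components=config["n_components"])
        ranked = bootstrap_loadings(Xa, y, gene_ids, n_boot=config["n_boot"], seed=seeds["pls"])
        iio.write_ranked_genes(ranked, out / "ranked_genes.tsv")
        summary["rho_first_component"] = float(model.component_correlations[0])

    with stage("nulls"):
        spin = spin_test(X, effect_map, geometry, n_perm=config["n_perm"], seed=seeds["nulls"])
        rand = random_test(X, effect_map, n_perm=config["n_perm"], seed=seeds["nulls"])
        (out / "null_tests.json").write_text(json.dumps({
            "spin": {"observed_rho": spin.observed_rho, "p": spin.p_value, "n_perm": spin.n_perm},
            "random": {"observed_rho": rand.observed_rho, "p": rand.p_value, "n_perm": rand.n_perm},
        }, indent=1))
        summary["p_spin"] = spin.p_value
        summary["p_random"] = rand.p_value

    with stage("cv"):
        cv = cross_validate(
            X, dataset, [seed_parcel], "M",
            n_repeats=config["cv_repeats"], n_folds=config["cv_folds"], seed=seeds["cv"],
        )
        (out / "cv_result.json").write_text(json.dumps({
            "rho_real": cv.rho_real.tolist(),
            "rho_null": cv.rho_null.tolist(),
            "p_per_repeat": cv.p_per_repeat.tolist(),
            "p_bonferroni": cv.p_bonferroni.tolist(),
            "reject": cv.reject,
        }, indent=1))
        summary["cv_reject"] = cv.reject

    with stage("enrichment"):
        table = iio.read_ranked_genes(out / "ranked_genes.tsv")
        ranked_order = table.dropna(subset=["rank"]).sort_values("rank")["gene_id"].tolist()
        sets, set_truth = sd.simulate_gene_sets(
            ranked_order,
            planted=[(config["planted_set_size"], 1, "up")],
            n_random_sets=config["n_random_sets"],
            seed=seeds["enrichment"],
        )
        iio.write_gmt(sets, out / "gene_sets.gmt")
        iio.write_truth(set_truth, out / "gene_set_truth.json")
        ranking = table.dropna(subset=["rank"])[["gene_id", "z"]]
        results = gsea_preranked(ranking, sets, n_perm=config["n_gene_set_perm"], seed=seeds["enrichment"])
        rows = [{
            "set_name": r.set_name, "ES": r.es, "NES": r.nes, "p": r.p_value,
            "q": r.q_value, "sign": r.sign, "size": r.size,
        } for r in results]
        (out / "enrichment.json").write_text(json.dumps(rows, indent=1))
        planted_name = next(iter(set_truth.enriched_sets))
        counts = decile_counts(ranking, sets.sets[planted_name])
        lo, hi = decile_null_ci(len(ranking), len(sets.sets[planted_name]),
                                n_sim=config["n_gene_set_perm"], seed=seeds["enrichment"])
        (out / "decile_analysis.json").write_text(json.dumps({
            "counts": counts.tolist(), "ci_lower": lo.tolist(), "ci_upper": hi.tolist(),
        }, indent=1))
        summary["planted_set_q"] = next(r.q_value for r in results if r.set_name == planted_name)

    with stage("genetics"):
        causal_feature = findex[0]
        snp_spec = {
            f"rs{1000 + i}": {"maf": config["snp_maf"], "missing_rate": 0.02}
            for i in range(config["n_snps"])
        }
        causal = {"rs1000": {"feature": causal_feature, "effect": config["causal_effect"], "sex": "M"}}
        table, dataset_g, geno_truth = sd.simulate_genotypes(
            snp_spec, seed=seeds["genetics"], causal_spec=causal, dataset=dataset,
        )
        iio.write_genotypes(table, out / "genotypes.tsv")
        iio.write_truth(geno_truth, out / "genotype_truth.json")
        qc = qc_filter_snps(table)
        scores = risk_allele_score(qc.retained, list(qc.retained.snp_ids))
        meta = dataset_g.metadata.set_index("subject_id")
        fcol = dataset_g.feature_index.index(causal_feature)
        feat = pd.Series(
            dataset_g.features[:, fcol],
            index=pd.Index(dataset_g.metadata["subject_id"], name="subject_id"),
        )
        results_by_sex = {}
        for sex in ("M", "F"):
            sub_ids = meta.index[meta["sex"] == sex]
            results_by_sex[sex] = score_fc_association(
                scores.loc[scores.index.intersection(sub_ids)],
                feat.loc[feat.index.intersection(sub_ids)],
                meta.loc[sub_ids, "age"],
            )
        (out / "genotype_association.json").write_text(
            json.dumps({"by_sex": results_by_sex, "excluded": qc.exclusions}, indent=1)
        )
        summary["qc_excluded"] = qc.exclusions
        summary["genotype_p_male"] = results_by_sex["M"]["p"]

    with stage("power"):
        if config["run_power"]:
            comp = sex_composition_bootstrap(
                dataset, n_mdd=config["power_n_mdd"], n_hc=config["power_n_hc"],
                n_iter=config["power_n_iter"], seed=seeds["power"],
            )
            (out / "composition_sim.json").write_text(json.dumps({
                "compositions": list(comp.compositions),
                "mean_t_by_composition": comp.mean_t.mean(axis=1).tolist(),
            }, indent=1))

    config.to_yaml(out / "config.yaml")
    (out / "timings.json").write_text(json.dumps(timings, indent=1))
    manifest = {
        "seed": seed,
        "config_digest": config.digest(),
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            # timings are wall-clock and inherently non-deterministic
            if p.is_file() and p.name not in ("manifest.json", "timings.json")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    summary["timings"] = timings
    return summary
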