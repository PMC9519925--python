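import numpy as np
import pytest
from scipy import stats

from imgtx import synthetic_data as sd
from imgtx._utils import great_circle_distance, morans_i


def neighbor_weights(geometry, k=5):
    """Inverse-distance weights to the k nearest parcels in the effective
    (homolog-aligned) frame, excluding the coincident homolog itself."""
    d = great_circle_distance(sd.effective_positions(geometry))
    n = geometry.n_parcels
    w = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(d[i])
        picked = 0
        for j in order:
            if j == i or d[i, j] < 1e-6:
                continue  # self or coincident homolog
            w[i, j] = 1.0 / d[i, j]
            picked += 1
            if picked == k:
                break
    return w


class TestMakeParcellation:
    def test_parcel_count(self):
        assert sd.make_parcellation(180, seed=0).n_parcels == 360

    def test_minimum_size_and_unit_norm(self):
        g = sd.make_parcellation(4, seed=123)
        assert g.n_parcels == 8
        assert np.allclose(np.linalg.norm(g.sphere_xyz, axis=1), 1.0, atol=1e-9)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            sd.make_parcellation(3, seed=0)

    def test_homologs_are_exact_x_mirrors(self):
        g = sd.make_parcellation(50, seed=7)
        for i in range(g.n_parcels):
            j = g.homolog_index[i]
            expected = g.sphere_xyz[i] * np.array([-1.0, 1.0, 1.0])
            assert np.allclose(g.sphere_xyz[j], expected, atol=1e-12)

    def test_homolog_bijection_between_hemispheres(self):
        g = sd.make_parcellation(30, seed=3)
        hidx = g.homolog_index
        assert np.array_equal(np.sort(hidx), np.arange(g.n_parcels))
        assert all(g.hemisphere[hidx[i]] != g.hemisphere[i] for i in range(g.n_parcels))

    def test_seed_determinism(self):
        a = sd.make_parcellation(20, seed=5)
        b = sd.make_parcellation(20, seed=5)
        assert np.array_equal(a.sphere_xyz, b.sphere_xyz)
        c = sd.make_parcellation(20, seed=6)
        assert not np.array_equal(a.sphere_xyz, c.sphere_xyz)


class TestExpressionAtlasSim:
    def test_right_hemisphere_donor_count(self, small_geometry):
        donors, _ = sd.simulate_expression_atlas(
            small_geometry, n_genes=10, n_donors=6, smoothness=0.5,
            right_hemi_donor_fraction=2.0 / 6.0, seed=1,
        )
        with_right = sum((d.samples["hemisphere"] == "R").any() for d in donors)
        assert with_right == 2

    def test_invalid_smoothness(self, small_geometry):
        with pytest.raises(ValueError):
            sd.simulate_expression_atlas(small_geometry, 10, 2, smoothness=0.0, seed=1)

    def test_probe_gene_mapping_complete(self, small_atlas):
        donors, _ = small_atlas
        for d in donors:
            assert set(d.probe_expression.index) <= set(d.probe_to_gene)

    def test_white_noise_limit_has_no_spatial_autocorrelation(self, small_geometry):
        _, truth = sd.simulate_expression_atlas(
            small_geometry, n_genes=50, n_donors=1, smoothness=0.01, seed=4,
        )
        fields = truth.extras["gene_fields"]
        w = neighbor_weights(small_geometry)
        mi = np.mean([morans_i(fields[:, g], w) for g in range(fields.shape[1])])
        assert abs(mi) < 0.15

    @pytest.mark.parametrize("smooth_pair", [(0.05, 1.0)])
    def test_morans_i_increases_with_smoothness(self, small_geometry, smooth_pair):
        lo, hi = smooth_pair
        w = neighbor_weights(small_geometry)

        def mean_mi(s):
            _, truth = sd.simulate_expression_atlas(
                small_geometry, n_genes=50, n_donors=1, smoothness=s, seed=9,
            )
            f = truth.extras["gene_fields"]
            return np.mean([morans_i(f[:, g], w) for g in range(f.shape[1])])

        assert mean_mi(hi) > mean_mi(lo)

    def test_monotone_autocorrelation_three_values(self, small_geometry):
        w = neighbor_weights(small_geometry)
        mis = []
        for s in (0.05, 0.3, 1.5):
            _, truth = sd.simulate_expression_atlas(
                small_geometry, n_genes=40, n_donors=1, smoothness=s, seed=21,
            )
            f = truth.extras["gene_fields"]
            mis.append(np.mean([morans_i(f[:, g], w) for g in range(f.shape[1])]))
        assert mis[0] < mis[1] < mis[2]

    def test_bit_reproducible(self, small_geometry):
        a, _ = sd.simulate_expression_atlas(small_geometry, 10, 2, smoothness=0.5, seed=8)
        b, _ = sd.simulate_expression_atlas(small_geometry, 10, 2, smoothness=0.5, seed=8)
        assert a[0].probe_expression.equals(b[0].probe_expression)


class TestSimulateSubjectRsfc:
    def _cells(self, n, sites=("A",)):
        return {(s, d, site): n for s in "MF" for d in ("HC", "MDD") for site in sites}

    def test_global_null_anova_rejects_at_alpha(self, small_geometry):
        from imgtx.connectivity_stats import factorial_anova

        ds, _ = sd.simulate_subject_rsfc(
            small_geometry, self._cells(30), sd.EffectSpec(), noise_sd=1.0, seed=2,
        )
        ct = factorial_anova(ds)
        for term in ("sex", "mdd", "interaction"):
            rate = (ct[f"p_{term}"] < 0.05).mean()
            assert 0.0 <= rate < 0.12

    def test_male_contrast_recovers_interaction_sign(self, small_geometry):
        from imgtx.connectivity_stats import posthoc_contrasts

        fidx = sd.all_pair_feature_index([str(small_geometry.parcel_ids[0])],
                                         list(small_geometry.parcel_ids))
        beta_int = np.zeros(len(fidx))
        beta_int[3] = 0.6
        ds, _ = sd.simulate_subject_rsfc(
            small_geometry, self._cells(200), sd.EffectSpec(beta_int=beta_int),
            noise_sd=0.5, seed=3, feature_index=fidx,
        )
        t_m, p_m = posthoc_contrasts(ds, "M")
        assert t_m[3] > 0 and p_m[3] < 1e-6

    def test_site_shift_visible_before_harmonization(self, small_geometry):
        noise_sd = 0.5
        ds, _ = sd.simulate_subject_rsfc(
            small_geometry, self._cells(100, sites=("A", "B")),
            sd.EffectSpec(site_shifts={"A": 0.0, "B": 2 * noise_sd}),
            noise_sd=noise_sd, seed=4,
        )
        site = ds.metadata["site"].to_numpy()
        diff = ds.features[site == "B"].mean(axis=0) - ds.features[site == "A"].mean(axis=0)
        assert np.allclose(diff.mean(), 2 * noise_sd, atol=0.1 * noise_sd)

    def test_sample_moments_match_spec(self, small_geometry):
        ds, _ = sd.simulate_subject_rsfc(
            small_geometry, self._cells(500),
            sd.EffectSpec(baseline=0.2, beta_sex=0.1, beta_mdd=0.3, beta_int=-0.2),
            noise_sd=1.0, seed=5,
        )
        meta = ds.metadata
        se = 1.0 / np.sqrt(500)
        cell = ds.features[((meta.sex == "M") & (meta.diagnosis == "MDD")).to_numpy()]
        assert abs(cell.mean() - (0.2 + 0.1 + 0.3 - 0.2)) < 3 * se

    def test_small_cell_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            sd.simulate_subject_rsfc(
                small_geometry, {("M", "HC", "A"): 1}, sd.EffectSpec(), 1.0, seed=0,
            )

    def test_interaction_requires_full_design(self, small_geometry):
        with pytest.raises(ValueError):
            sd.simulate_subject_rsfc(
                small_geometry, {("M", "HC", "A"): 10, ("M", "MDD", "A"): 10},
                sd.EffectSpec(beta_int=0.5), 1.0, seed=0,
            )


class TestPlantGeneAssociation:
    def test_noiseless_limit(self, small_X):
        Xa, genes = small_X.analysis_matrix()
        effect, truth = sd.plant_gene_association(
            Xa, genes, small_X.covered_parcel_ids, sparsity=0.1, snr=np.inf, seed=1,
        )
        w = np.array([truth.gene_weights[g] for g in genes])
        assert abs(np.corrcoef(Xa @ w, effect.t_values)[0, 1] - 1) < 1e-9

    def test_sparsity_count(self, small_X):
        Xa, genes = small_X.analysis_matrix()
        _, truth = sd.plant_gene_association(
            Xa, genes, small_X.covered_parcel_ids, sparsity=10 / len(genes), snr=1.0, seed=2,
        )
        assert sum(v != 0 for v in truth.gene_weights.values()) == 10

    def test_snr_realized_variance_ratio(self, small_X):
        Xa, genes = small_X.analysis_matrix()
        ratios = []
        for seed in range(100):
            effect, truth = sd.plant_gene_association(
                Xa, genes, small_X.covered_parcel_ids, sparsity=0.1, snr=1.0, seed=seed,
            )
            w = np.array([truth.gene_weights[g] for g in genes])
            signal = Xa @ w
            signal -= signal.mean()
            noise = effect.t_values - signal
            ratios.append(signal.var() / noise.var())
        ratios = np.array(ratios)
        assert np.all((ratios > 0.8) & (ratios < 1.25))

    def test_invalid_snr(self, small_X):
        Xa, genes = small_X.analysis_matrix()
        with pytest.raises(ValueError):
            sd.plant_gene_association(Xa, genes, small_X.covered_parcel_ids, 0.1, 0.0, seed=1)


class TestSimulateGeneSets:
    def test_planted_set_concentrated_in_decile(self):
        genes = [f"g{i}" for i in range(1000)]
        coll, truth = sd.simulate_gene_sets(genes, [(50, 1, "up")], 0, seed=1)
        name = next(iter(truth.enriched_sets))
        members = coll.sets[name]
        top_decile = set(genes[:100])
        frac = sum(g in top_decile for g in members) / len(members)
        assert frac >= 0.8

    def test_random_set_uniform_expectation(self):
        genes = [f"g{i}" for i in range(1000)]
        rng = np.random.default_rng(0)
        counts = np.zeros(10)
        for seed in range(50):
            coll, _ = sd.simulate_gene_sets(genes, [], 1, seed=seed)
            members = next(iter(coll.sets.values()))
            idx = [int(g[1:]) for g in members]
            counts += np.bincount(np.array(idx) * 10 // 1000, minlength=10) / len(members)
        counts /= 50
        assert np.allclose(counts, 0.1, atol=0.03)

    def test_full_universe_set_refused(self):
        genes = [f"g{i}" for i in range(100)]
        with pytest.raises(ValueError):
            sd.simulate_gene_sets(genes, [(100, 1, "up")], 0, seed=1)

    def test_bad_decile_rejected(self):
        genes = [f"g{i}" for i in range(100)]
        with pytest.raises(ValueError):
            sd.simulate_gene_sets(genes, [(10, 11, "up")], 0, seed=1)


class TestSimulateGenotypes:
    def test_hwe_calibration(self):
        from imgtx.genotype_validation import hwe_chisq

        n_pass = 0
        reps = 200
        for seed in range(reps):
            table, _, _ = sd.simulate_genotypes(
                {"rs1": {"maf": 0.3}}, seed=seed, n_subjects=10_000,
            )
            col = table.counts[:, 0]
            counts = [int((col == g).sum()) for g in (0, 1, 2)]
            _, p = hwe_chisq(*counts)
            n_pass += p > 0.05
        assert n_pass / reps >= 0.90

    def test_hwe_violation_detected(self):
        from imgtx.genotype_validation import hwe_chisq

        table, _, _ = sd.simulate_genotypes(
            {"rs1": {"maf": 0.3, "hwe_violation": True}}, seed=1, n_subjects=5000,
        )
        col = table.counts[:, 0]
        counts = [int((col == g).sum()) for g in (0, 1, 2)]
        _, p = hwe_chisq(*counts)
        assert p < 1e-6

    def test_missingness_rate(self):
        table, _, _ = sd.simulate_genotypes(
            {"rs1": {"maf": 0.3, "missing_rate": 0.15}}, seed=2, n_subjects=5000,
        )
        assert abs(np.isnan(table.counts).mean() - 0.15) < 0.02

    def test_null_association_t_distribution(self, factorial_dataset):
        from imgtx.genotype_validation import risk_allele_score, score_fc_association
        import pandas as pd

        ds, _, _, fidx = factorial_dataset
        tvals = []
        for seed in range(40):
            table, ds2, _ = sd.simulate_genotypes(
                {"rs1": {"maf": 0.3}}, seed=seed, dataset=ds,
            )
            scores = risk_allele_score(table, ["rs1"])
            meta = ds2.metadata.set_index("subject_id")
            feat = pd.Series(ds2.features[:, 0], index=pd.Index(ds2.metadata["subject_id"]))
            res = score_fc_association(scores, feat, meta["age"])
            tvals.append(res["t"])
        _, p = stats.kstest(tvals, "t", args=(len(ds.metadata) - 3,))
        assert p > 0.01

    def test_causal_feature_must_exist(self, factorial_dataset):
        ds, *_ = factorial_dataset
        with pytest.raises(ValueError):
            sd.simulate_genotypes(
                {"rs1": {"maf": 0.3}}, seed=1, dataset=ds,
                causal_spec={"rs1": {"feature": ("nope", "nah"), "effect": 1.0, "sex": "M"}},
            )

    def test_invalid_maf(self):
        with pytest.raises(ValueError):
            sd.simulate_genotypes({"rs1": {"maf": 0.6}}, seed=1, n_subjects=100)
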