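import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from imgtx import synthetic_data as sd
from imgtx.connectivity_stats import (
    bh_fdr,
    classify_shared_specific,
    combat_harmonize,
    compute_rsfc,
    factorial_anova,
    posthoc_contrasts,
    seed_effect_map,
    sex_specificity_permutation,
    two_sample_t,
)
from imgtx.types import ConnectivityDataset


def _meta(n, sexes=None, dx=None, sites=None):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "sex": sexes if sexes is not None else rng.choice(["M", "F"], n),
            "diagnosis": dx if dx is not None else rng.choice(["HC", "MDD"], n),
            "site": sites if sites is not None else ["A"] * n,
            "age": rng.uniform(20, 60, n),
        }
    )


class TestComputeRsfc:
    def test_null_correlation_near_zero(self):
        rng = np.random.default_rng(1)
        n_inside = 0
        for rep in range(40):
            ts = pd.DataFrame(rng.standard_normal((2, 1000)), index=["a", "b"])
            ds = compute_rsfc({"s0": ts}, ["a"], ["b"], _meta(1))
            n_inside += abs(ds.features[0, 0]) < 0.1
        assert n_inside >= 0.9 * 40

    def test_feature_count(self, small_geometry):
        rng = np.random.default_rng(2)
        regions = [f"r{i}" for i in range(10)]
        ts = pd.DataFrame(rng.standard_normal((10, 50)), index=regions)
        ds = compute_rsfc({"s0": ts}, regions[:3], regions[3:], _meta(1))
        assert ds.n_features == 3 * 7

    def test_matches_corrcoef_atanh_oracle(self):
        ts_arr = sd.simulate_time_series(6, 80, seed=3)
        regions = [f"r{i}" for i in range(6)]
        ts = pd.DataFrame(ts_arr, index=regions)
        ds = compute_rsfc({"s0": ts}, regions[:2], regions[2:], _meta(1))
        r = np.corrcoef(ts_arr)
        for j, (s, t) in enumerate(ds.feature_index):
            expected = np.arctanh(r[regions.index(s), regions.index(t)])
            assert abs(ds.features[0, j] - expected) < 1e-10

    def test_perfect_correlation_clipped(self):
        x = np.arange(10, dtype=float)
        ts = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        ds = compute_rsfc({"s0": ts}, ["a"], ["b"], _meta(1))
        assert np.isfinite(ds.features[0, 0])

    def test_constant_series_missing(self):
        ts = pd.DataFrame([np.ones(10), np.arange(10.0)], index=["a", "b"])
        ds = compute_rsfc({"s0": ts}, ["a"], ["b"], _meta(1))
        assert np.isnan(ds.features[0, 0])


class TestCombat:
    def test_single_site_identity(self, small_geometry):
        cells = {(s, d, "A"): 20 for s in "MF" for d in ("HC", "MDD")}
        ds, _ = sd.simulate_subject_rsfc(small_geometry, cells, sd.EffectSpec(), 0.5, seed=1)
        out = combat_harmonize(ds)
        assert np.allclose(out.features, ds.features, atol=1e-10)

    def test_site_shift_removed(self, small_geometry):
        noise_sd = 0.5
        cells = {(s, d, site): 200 for s in "MF" for d in ("HC", "MDD") for site in "AB"}
        spec = sd.EffectSpec(site_shifts={"A": 0.0, "B": 2 * noise_sd})
        ds, _ = sd.simulate_subject_rsfc(small_geometry, cells, spec, noise_sd, seed=2)
        out = combat_harmonize(ds)
        site = out.metadata["site"].to_numpy()
        diff = np.abs(
            out.features[site == "B"].mean(axis=0) - out.features[site == "A"].mean(axis=0)
        )
        assert (diff < 0.1 * noise_sd).mean() >= 0.95

    def test_diagnosis_effect_preserved(self, small_geometry):
        beta = 0.4
        cells = {(s, d, site): 200 for s in "MF" for d in ("HC", "MDD") for site in "AB"}
        spec = sd.EffectSpec(beta_mdd=beta, site_shifts={"A": 0.0, "B": 1.0})
        ds, _ = sd.simulate_subject_rsfc(small_geometry, cells, spec, 0.5, seed=3)
        out = combat_harmonize(ds)
        mdd = (out.metadata["diagnosis"] == "MDD").to_numpy()
        est = out.features[mdd].mean(axis=0) - out.features[~mdd].mean(axis=0)
        assert abs(est.mean() - beta) < 0.1 * beta

    def test_metadata_and_shape_untouched(self, factorial_dataset):
        ds, *_ = factorial_dataset
        out = combat_harmonize(ds)
        assert out.features.shape == ds.features.shape
        pd.testing.assert_frame_equal(out.metadata, ds.metadata)

    def test_singleton_batch_rejected(self, small_geometry):
        cells = {(s, d, "A"): 10 for s in "MF" for d in ("HC", "MDD")}
        ds, _ = sd.simulate_subject_rsfc(small_geometry, cells, sd.EffectSpec(), 0.5, seed=4)
        meta = ds.metadata.copy()
        meta.loc[0, "site"] = "B"
        ds2 = ConnectivityDataset(ds.features, ds.feature_index, meta)
        with pytest.raises(ValueError):
            combat_harmonize(ds2)


class TestFactorialAnova:
    def test_null_rates(self, small_geometry):
        cells = {(s, d, "A"): 40 for s in "MF" for d in ("HC", "MDD")}
        ds, _ = sd.simulate_subject_rsfc(small_geometry, cells, sd.EffectSpec(), 1.0, seed=5)
        ct = factorial_anova(ds)
        assert ct["F_mdd"].mean() < 2.0
        assert ct["p_mdd"].mean() > 0.3

    def test_balanced_cell_means_oracle(self, factorial_dataset):
        ds, *_ = factorial_dataset
        ct = factorial_anova(ds)
        meta = ds.metadata
        male = (meta["sex"] == "M").to_numpy()
        mdd = (meta["diagnosis"] == "MDD").to_numpy()
        n = len(meta)
        for j in [0, 5, 17]:
            y = ds.features[:, j]
            # classic balanced two-way ANOVA from cell means
            cells = {}
            for a in (0, 1):
                for b in (0, 1):
                    cells[(a, b)] = y[(male == a) & (mdd == b)]
            nc = len(cells[(0, 0)])
            mean_all = y.mean()
            m_a = [np.concatenate([cells[(a, 0)], cells[(a, 1)]]).mean() for a in (0, 1)]
            m_b = [np.concatenate([cells[(0, b)], cells[(1, b)]]).mean() for b in (0, 1)]
            ss_a = 2 * nc * sum((m - mean_all) ** 2 for m in m_a)
            ss_b = 2 * nc * sum((m - mean_all) ** 2 for m in m_b)
            ss_cells = nc * sum(
                (cells[(a, b)].mean() - mean_all) ** 2 for a in (0, 1) for b in (0, 1)
            )
            ss_int = ss_cells - ss_a - ss_b
            ss_err = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
            ms_err = ss_err / (n - 4)
            assert np.isclose(ct["F_sex"][j], ss_a / ms_err, atol=1e-8)
            assert np.isclose(ct["F_mdd"][j], ss_b / ms_err, atol=1e-8)
            assert np.isclose(ct["F_interaction"][j], ss_int / ms_err, atol=1e-8)

    def test_q_at_least_p(self, factorial_dataset):
        ds, *_ = factorial_dataset
        ct = factorial_anova(ds)
        for term in ("sex", "mdd", "interaction"):
            assert (ct[f"q_{term}"] >= ct[f"p_{term}"] - 1e-12).all()

    def test_empty_cell_rejected(self, small_geometry):
        cells = {("M", "HC", "A"): 10, ("M", "MDD", "A"): 10, ("F", "HC", "A"): 10}
        ds, _ = sd.simulate_subject_rsfc(small_geometry, cells, sd.EffectSpec(), 1.0, seed=6)
        with pytest.raises(ValueError):
            factorial_anova(ds)


class TestPosthoc:
    def test_identical_groups_t_zero(self):
        x = np.tile(np.random.default_rng(0).standard_normal((4, 3)), (2, 1))
        group = np.array([True] * 4 + [False] * 4)
        t, p = two_sample_t(x, group)
        assert np.allclose(t, 0.0)

    def test_matches_scipy_pooled(self, factorial_dataset):
        ds, *_ = factorial_dataset
        t, p = posthoc_contrasts(ds, "M")
        meta = ds.metadata
        m = (meta["sex"] == "M").to_numpy()
        mdd = (meta["diagnosis"] == "MDD").to_numpy()
        ref = stats.ttest_ind(ds.features[m & mdd], ds.features[m & ~mdd])
        assert np.allclose(t, ref.statistic, atol=1e-10)
        assert np.allclose(p, ref.pvalue, atol=1e-10)

    def test_positive_t_means_increased_in_mdd(self, small_geometry):
        cells = {(s, d, "A"): 100 for s in "MF" for d in ("HC", "MDD")}
        ds, _ = sd.simulate_subject_rsfc(
            small_geometry, cells, sd.EffectSpec(beta_mdd=1.0), 0.3, seed=7,
        )
        t, _ = posthoc_contrasts(ds, "M")
        assert (t > 0).mean() > 0.99

    def test_planted_male_interaction(self, factorial_dataset):
        ds, truth, seedp, fidx = factorial_dataset
        t_m, _ = posthoc_contrasts(ds, "M")
        t_f, _ = posthoc_contrasts(ds, "F")
        assert abs(t_m[0]) > 2 * abs(t_f[0])

    def test_tiny_stratum_rejected(self, small_geometry):
        cells = {("M", "HC", "A"): 2, ("M", "MDD", "A"): 2,
                 ("F", "HC", "A"): 2, ("F", "MDD", "A"): 2}
        ds, _ = sd.simulate_subject_rsfc(small_geometry, cells, sd.EffectSpec(), 1.0, seed=8)
        male_hc = ((ds.metadata.sex == "M") & (ds.metadata.diagnosis == "HC")).to_numpy()
        keep = np.ones(8, dtype=bool)
        keep[np.flatnonzero(male_hc)[0]] = False  # leaves 1 male HC
        with pytest.raises(ValueError):
            posthoc_contrasts(ds.subset(keep), "M")


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q, rej = bh_fdr(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])
        assert rej.all()

    def test_all_ones_no_rejection(self):
        q, rej = bh_fdr(np.ones(10))
        assert not rej.any()
        assert np.allclose(q, 1.0)

    def test_single_p_identity(self):
        q, _ = bh_fdr(np.array([0.2]))
        assert q[0] == pytest.approx(0.2)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_properties(self, ps):
        p = np.array(ps)
        q, rej = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([-0.1]))


class TestClassifyShared:
    def test_all_null(self):
        t = np.zeros(10)
        p = np.ones(10)
        labels, counts = classify_shared_specific(t, p, t, p)
        assert all(v == 0 for v in counts.values())
        assert (labels == "none").all()

    def test_constructed_overlap(self):
        p_m = np.array([0.01, 0.01, 0.5, 0.01])
        p_f = np.array([0.01, 0.5, 0.01, 0.01])
        _, counts = classify_shared_specific(np.ones(4), p_m, np.ones(4), p_f)
        assert counts == {"male-specific": 1, "female-specific": 1, "shared": 2}

    def test_threshold_is_unadjusted_005(self):
        p = np.array([0.049, 0.051])
        labels, counts = classify_shared_specific(np.ones(2), p, np.ones(2), np.ones(2))
        assert counts["male-specific"] == 1


class TestSexSpecificityPermutation:
    def test_planted_male_effects_detected(self, small_geometry):
        fidx = sd.all_pair_feature_index([str(small_geometry.parcel_ids[0])],
                                         list(small_geometry.parcel_ids))
        beta = np.zeros(len(fidx))
        beta[:20] = 0.5
        cells = {(s, d, "A"): 150 for s in "MF" for d in ("HC", "MDD")}
        ds, _ = sd.simulate_subject_rsfc(
            small_geometry, cells, sd.EffectSpec(beta_int=beta), 0.5, seed=9, feature_index=fidx,
        )
        res = sex_specificity_permutation(ds, n_perm=200, seed=10)
        assert res["p_male_specific"] < 0.05

    def test_min_nperm_enforced(self, factorial_dataset):
        ds, *_ = factorial_dataset
        with pytest.raises(ValueError):
            sex_specificity_permutation(ds, n_perm=50, seed=1)


class TestSeedEffectMap:
    def test_single_seed_consistent_with_posthoc(self, factorial_dataset):
        ds, _, seedp, fidx = factorial_dataset
        em = seed_effect_map(ds, [seedp], "M")
        t, p = posthoc_contrasts(ds, "M")
        by_target = {t_: j for j, (s_, t_) in enumerate(ds.feature_index)}
        for pid, tv in zip(em.parcel_ids, em.t_values):
            assert np.isclose(tv, t[by_target[pid]], atol=1e-10)

    def test_map_length_equals_covered(self, factorial_dataset, small_X):
        ds, _, seedp, fidx = factorial_dataset
        covered = [p for p in small_X.covered_parcel_ids if p != seedp]
        em = seed_effect_map(ds, [seedp], "M", covered_parcel_ids=covered)
        assert len(em.parcel_ids) == len(covered)

    def test_empty_seed_rejected(self, factorial_dataset):
        ds, *_ = factorial_dataset
        with pytest.raises(ValueError):
            seed_effect_map(ds, [], "M")

    def test_multi_seed_average(self, small_geometry):
        seeds = [str(small_geometry.parcel_ids[0]), str(small_geometry.parcel_ids[1])]
        targets = [p for p in small_geometry.parcel_ids if p not in seeds]
        fidx = sd.all_pair_feature_index(seeds, targets)
        cells = {(s, d, "A"): 30 for s in "MF" for d in ("HC", "MDD")}
        ds, _ = sd.simulate_subject_rsfc(small_geometry, cells, sd.EffectSpec(), 0.5, seed=11,
                                         feature_index=fidx)
        em = seed_effect_map(ds, seeds, "F")
        # oracle: average the two seed features per target, then pooled t
        meta = ds.metadata
        strat = (meta["sex"] == "F").to_numpy()
        mdd = (meta.loc[strat, "diagnosis"] == "MDD").to_numpy()
        target = em.parcel_ids[5]
        cols = [j for j, (s_, t_) in enumerate(ds.feature_index) if t_ == target]
        avg = ds.features[strat][:, cols].mean(axis=1)
        ref = stats.ttest_ind(avg[mdd], avg[~mdd])
        assert np.isclose(em.t_values[5], ref.statistic, atol=1e-10)
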