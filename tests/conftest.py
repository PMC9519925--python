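import numpy as np
import pytest

from imgtx import synthetic_data as sd
from imgtx.expression_atlas import build_expression_matrix


@pytest.fixture(scope="session")
def small_geometry():
    return sd.make_parcellation(20, seed=11)


@pytest.fixture(scope="session")
def small_atlas(small_geometry):
    donors, truth = sd.simulate_expression_atlas(
        small_geometry, n_genes=80, n_donors=4, smoothness=0.5, probes_per_gene=2,
        right_hemi_donor_fraction=0.5, seed=12,
    )
    return donors, truth


@pytest.fixture(scope="session")
def small_X(small_geometry, small_atlas):
    donors, _ = small_atlas
    return build_expression_matrix(donors, small_geometry)


@pytest.fixture(scope="session")
def planted_fixture(small_X):
    Xa, gene_ids = small_X.analysis_matrix()
    effect, truth = sd.plant_gene_association(
        Xa, gene_ids, small_X.covered_parcel_ids, sparsity=0.1, snr=5.0, seed=13,
    )
    return effect, truth


@pytest.fixture(scope="session")
def factorial_dataset(small_geometry):
    """Balanced 2x2x(2 sites) dataset with a male-specific planted effect on
    feature 0 and a site shift, noise_sd = 0.5."""
    g = small_geometry
    seedp = str(g.parcel_ids[0])
    targets = [p for p in g.parcel_ids if p != seedp]
    fidx = sd.all_pair_feature_index([seedp], targets)
    beta_int = np.zeros(len(fidx))
    beta_int[0] = 0.8
    spec = sd.EffectSpec(beta_int=beta_int, site_shifts={"A": 0.0, "B": 0.4})
    n_per_cell = {(s, d, site): 25 for s in "MF" for d in ("HC", "MDD") for site in "AB"}
    ds, truth = sd.simulate_subject_rsfc(g, n_per_cell, spec, noise_sd=0.5, seed=14, feature_index=fidx)
    return ds, truth, seedp, fidx
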