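import numpy as np
import pytest
import scipy.sparse as sp

import cortexmpm as cm
from cortexmpm.phantom import EffectSpec


@pytest.fixture(scope="session")
def flat_model():
    return cm.make_cortical_model(100, 0.0, 1.0, 2, seed=0)


@pytest.fixture(scope="session")
def folded_model():
    return cm.make_cortical_model(400, 2.0, 1.0, 8, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def deterministic_spec(**overrides) -> EffectSpec:
    """EffectSpec with every random/age/cohort effect switched off."""
    zero = {"r1": 0.0, "delta": 0.0, "r2star": 0.0, "a": 0.0}
    base = dict(
        subject_sd=dict(zero),
        region_sd=dict(zero),
        depth_slope_sd=dict(zero),
        cohort2_offsets=dict(zero),
        r1_age_slope=0.0,
        delta_age_slope=0.0,
        noise_sd={"PDw": 0.0, "T1w": 0.0, "MTw": 0.0},
    )
    base.update(overrides)
    return EffectSpec(**base)


@pytest.fixture(scope="session")
def noiseless_volumes(folded_model):
    """One noiseless exact-Ernst simulated subject on the folded model."""
    spec = deterministic_spec()
    subject = cm.make_cohort(2, effect_spec=spec, seed=5, cohort2_fraction=0.0,
                             n_regions=folded_model.n_regions)[0]
    gt = cm.build_ground_truth(folded_model, subject, spec)
    fields = cm.FieldMaps(
        f_transmit=np.ones(folded_model.vol_shape),
        g_receive=np.ones(folded_model.vol_shape),
        affine=folded_model.affine,
    )
    vols = cm.simulate_weighted_volumes(
        gt, fields, cm.get_protocol(1), noise_sd=0.0, seed=0
    )
    return gt, fields, vols


def periodic_grid_adjacency(n: int) -> sp.csr_matrix:
    """4-neighbour adjacency of an n-by-n grid with wrap-around (uniform
    degree, so neighbour averaging is exactly mean-preserving)."""
    idx = np.arange(n * n).reshape(n, n)
    rows, cols = [], []
    for shift_axis in (0, 1):
        nb = np.roll(idx, 1, axis=shift_axis)
        rows.extend(idx.ravel())
        cols.extend(nb.ravel())
        rows.extend(nb.ravel())
        cols.extend(idx.ravel())
    a = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n * n, n * n)
    ).tocsr()
    a.sum_duplicates()
    a.data[:] = 1
    return a
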