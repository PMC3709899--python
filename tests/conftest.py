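import numpy as np
import pandas as pd
import pytest

from bayescnax.gibbs import GibbsSampler, McmcConfig, ModelArrays
from bayescnax.io import Dataset


def tiny_arrays():
    """4 probes / 2 genes / 6 samples skeleton with placeholder data."""
    B, G, T = 4, 2, 6
    return ModelArrays(
        Y=np.zeros((B, T)), Z=np.zeros((G, T)),
        gene_of=np.array([0, 0, 1, 1]),
        chain_start=np.array([True, False, False, False]),
        x=np.array([1, 1, 1, 0, 0, 0]),
        u=np.array([1.0, 0.0, np.nan, 1.0, np.nan, 0.0]),
        probe_ids=[f"p{i}" for i in range(B)],
        gene_ids=["gA", "gB"],
        sample_ids=[f"s{t}" for t in range(T)],
    )


def make_sampler(mode="differential", seed=0, warm=5, **kwargs):
    """Tiny sampler in a generic state (prior init, data drawn, warm sweeps)."""
    cfg = McmcConfig(n_iter=10, burn_in=1, mode=mode, seed=seed)
    s = GibbsSampler(tiny_arrays(), config=cfg, **kwargs)
    s.sample_data(s.rng)
    for _ in range(warm):
        s.sweep()
    return s


@pytest.fixture
def tiny_sampler():
    return make_sampler("differential", seed=3)


@pytest.fixture
def tiny_pred_sampler():
    return make_sampler("prediction", seed=4)


@pytest.fixture
def tiny_dataset():
    """Hand-sized validated Dataset: 4 probes / 2 genes / 6 samples."""
    rng = np.random.default_rng(0)
    samples = [f"s{t}" for t in range(6)]
    probes = ["pA1", "pA2", "pB1", "pB2"]
    genes = ["gA", "gB"]
    Y = pd.DataFrame(rng.normal(size=(4, 6)), index=pd.Index(probes, name="probe_id"),
                     columns=samples)
    Z = pd.DataFrame(rng.normal(size=(2, 6)), index=pd.Index(genes, name="gene_id"),
                     columns=samples)
    info = pd.DataFrame({
        "chromosome": ["1", "1", "2", "2"],
        "position": [100, 200, 100, 300],
        "gene_id": ["gA", "gA", "gB", "gB"],
    }, index=pd.Index(probes, name="probe_id"))
    covars = pd.DataFrame({
        "x": [1, 1, 1, 0, 0, 0],
        "u": [1.0, 0.0, np.nan, 1.0, np.nan, 0.0],
    }, index=pd.Index(samples, name="sample_id"))
    return Dataset(Y=Y, Z=Z, probe_info=info, covariates=covars)


@pytest.fixture
def reference_cohort():
    """Covariate table with the reference 121-patient breast-cancer cohort counts."""
    from bayescnax.simulate import cohort_from_counts

    return cohort_from_counts(20, 33, 3, 11, 52, 2)


def normalized(logw):
    logw = np.asarray(logw, dtype=float)
    w = np.exp(logw - logw.max())
    return w / w.sum()
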