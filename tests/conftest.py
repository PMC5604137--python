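import numpy as np
import pandas as pd
import pytest

from oxbstools.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across read-only tests."""
    return simulate_dataset(SimulationConfig(
        n_probes=600, n_samples=40, n_ddhp=20, n_modules=2, module_size=30,
        n_sex_probes=8, n_qtl=6, n_null_snps=10, seed=11))


@pytest.fixture
def toy_samples():
    rng = np.random.default_rng(5)
    n = 24
    return pd.DataFrame({
        "sample_id": [f"S{i:02d}" for i in range(n)],
        "dpc": np.round(rng.uniform(23, 184, n), 1),
        "sex": np.array(["M", "F"] * (n // 2)),
    })


def make_matrix(values, samples, probes=None):
    values = np.atleast_2d(np.asarray(values, float))
    probes = probes or [f"cg{i:04d}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=pd.Index(probes, name="probe"),
                        columns=samples["sample_id"])
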