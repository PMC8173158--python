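import numpy as np
import pandas as pd
import pytest

from epiaging import synthetic
from epiaging.dataset import MethylationDataset, make_meta


@pytest.fixture
def tiny_dataset():
    """6 samples x 4 sites with known entries and mixed groups."""
    values = pd.DataFrame(
        np.arange(24, dtype=float).reshape(6, 4),
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
        columns=["cg0", "cg1", "cg2", "cg3"],
    )
    meta = make_meta(
        values.index,
        age=[30, 40, 60, 70, 65, 75],
        group=["young", "young", "control", "control", "AD", "AD"],
    )
    return MethylationDataset(values, meta)


@pytest.fixture(scope="session")
def planted_cohort():
    """Medium cohort with aging + disease signal, reused across tests."""
    data, truth = synthetic.generate_dataset(
        n_young=80,
        n_old=100,
        n_per_disease={"AD": 80},
        n_cpg=200,
        n_aging_markers=20,
        n_disease_markers=8,
        aging_effect=0.5,
        disease_effect=0.8,
        seed=11,
    )
    return data, truth


def separable_fixture(seed=0, n=60, p=4, gap=3.0):
    """Two Gaussian clouds separated along the first feature."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, p))
    X[:, 0] += gap * y
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), y
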