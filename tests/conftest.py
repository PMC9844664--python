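import warnings

import numpy as np
import pandas as pd
import pytest

from symnet import (
    EstimationSettings,
    GeneratorSpec,
    generate_ordinal_dataset,
    generate_precision_matrix,
    generate_study,
)
from symnet.dataset import SymptomDataset
from symnet.simulate import default_thresholds


@pytest.fixture(autouse=True)
def _quiet_small_B_warnings():
    """Tests intentionally use small B/n_perm; silence the advisory warnings."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="B=")
        warnings.filterwarnings("ignore", message="n_perm=")
        warnings.filterwarnings("ignore", message="EBIC computed")
        yield


@pytest.fixture(scope="session")
def fast_settings():
    """Spearman input and a short penalty path: cheap refits for resampling."""
    return EstimationSettings(correlation_method="spearman", n_lambda=20)


@pytest.fixture(scope="session")
def small_study():
    """A modest three-stratum synthetic cohort with covariates."""
    spec = GeneratorSpec(n_per_group=(120, 120, 120), seed=42)
    data, truth = generate_study(spec)
    return data, truth


@pytest.fixture(scope="session")
def six_node_dataset():
    """n=800 draws from a known sparse 6-node latent network."""
    K = generate_precision_matrix(6, 0.4, (0.25, 0.4), seed=5)
    data = generate_ordinal_dataset(800, K, default_thresholds()[:6], seed=6)
    return data, K


def make_dataset(values, covariates=None, group=None, labels=None):
    values = np.asarray(values)
    labels = labels or [f"item_{j+1:02d}" for j in range(values.shape[1])]
    cov = None if covariates is None else pd.DataFrame(covariates)
    grp = None if group is None else pd.Series(group)
    return SymptomDataset(pd.DataFrame(values, columns=labels), cov, grp)
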