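import numpy as np
import pandas as pd
import pytest

from tspred.scorefile import FeatureMatrix, ScoreTable
from tspred.synthetic import EnsembleModel, generate_training_set, generate_wt_ensemble


@pytest.fixture(scope="session")
def wt_ensemble() -> ScoreTable:
    return generate_wt_ensemble(EnsembleModel(), seed=7)


@pytest.fixture(scope="session")
def small_training() -> FeatureMatrix:
    """A reduced synthetic training set (fast: 54 samples, 30-decoy
    ensembles) for model/evaluation unit tests."""
    return generate_training_set(n_ts=20, n_nonts=34, ensemble_size=30, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def random_feature_matrix(rng, n_samples, n_features, labelled=False) -> FeatureMatrix:
    data = pd.DataFrame(
        rng.normal(size=(n_samples, n_features)),
        index=[f"s{i:03d}" for i in range(n_samples)],
        columns=[f"f{j:03d}" for j in range(n_features)],
    )
    labels = None
    if labelled:
        lab = np.where(rng.uniform(size=n_samples) < 0.4, "ts", "non-ts")
        labels = pd.Series(lab, index=data.index)
    return FeatureMatrix(data, labels)
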