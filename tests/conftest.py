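import warnings

import numpy as np
import pandas as pd
import pytest

import voripk as vp

warnings.filterwarnings("ignore", message="catboost unavailable")
np.seterr(all="ignore")


@pytest.fixture(scope="session")
def study_df() -> pd.DataFrame:
    """One study-design cohort (76 subjects, ~110 troughs) with simulated DVs."""
    return vp.simulate_study(vp.CohortSpec(n_subjects=76, seed=3))


@pytest.fixture(scope="session")
def study_fit(study_df) -> vp.PopPKFit:
    return vp.fit_population(study_df)


@pytest.fixture(scope="session")
def feature_matrix(study_df, study_fit) -> pd.DataFrame:
    return vp.build_feature_matrix(study_df, study_fit.ebes)


@pytest.fixture(scope="session")
def ml_split(feature_matrix):
    return vp.split_data(feature_matrix, seed=9)


@pytest.fixture(scope="session")
def trained_models(ml_split):
    train, _ = ml_split
    return vp.train_all(train, seed=9)
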