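import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import maranet as mn
from maranet import pipeline

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL = mn.SyntheticConfig(
    n_datasets=2,
    n_motifs=8,
    n_promoters=150,
    n_regulator_promoters=8,
    replicates_per_condition=2,
    noise_sd=0.05,
    activity_effect_size=1.0,
    fraction_active_motifs=0.375,
    site_count_density=0.15,
    edges_per_active_motif=1,
    seed=7,
)

# the study conditions the default fixture emulates
DEFAULT = mn.SyntheticConfig(
    n_datasets=3,
    n_motifs=50,
    n_promoters=2000,
    replicates_per_condition=2,
    noise_sd=0.2,
    activity_effect_size=1.0,
    seed=0,
)


@pytest.fixture(scope="session")
def small_bundle():
    return mn.generate_bundle(SMALL)


@pytest.fixture(scope="session")
def small_models(small_bundle):
    return pipeline.fit_all(small_bundle.expression, small_bundle.sitecounts)


@pytest.fixture(scope="session")
def default_bundle():
    return mn.generate_bundle(DEFAULT)


def toy_model(activities: pd.DataFrame, errors: pd.DataFrame) -> mn.MaraModel:
    """Hand-built model for unit tests of the combination stage."""
    samples = activities.columns
    promoters = pd.Index(["p1", "p2"])
    return mn.MaraModel(
        sample_means=pd.Series(0.0, index=samples),
        promoter_baselines=pd.Series(0.0, index=promoters),
        activities=activities,
        activity_errors=errors,
        ridge_lambda=1.0,
        residual_variance=1.0,
    )
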