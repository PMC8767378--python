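import numpy as np
import pytest

from nasoform.synthetic import (PopulationParams, RenderConfig,
                                render_subject_views, sample_population)


@pytest.fixture(scope="session")
def population():
    """Moderate synthetic population with default (cohort-matched) parameters."""
    return sample_population(PopulationParams(n=400, seed=3))


@pytest.fixture(scope="session")
def rendered_subject(population):
    """One subject's three rendered views with ground truth."""
    rec = population[0]
    return rec, render_subject_views(rec, RenderConfig(), seed=17)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
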