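import warnings

import numpy as np
import pandas as pd
import pytest

from symptomnet import (
    GeneratorConfig,
    PipelineConfig,
    RatingMatrix,
    build_block_precision,
    sample_cohort,
)
from symptomnet.preprocessing import clean_scores

# sklearn's coordinate descent emits convergence chatter at the smallest
# penalties on the path; harmless for model selection
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")
try:
    from sklearn.exceptions import ConvergenceWarning
    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort with its ground truth (seed fixed)."""
    cfg = GeneratorConfig(seed=7)
    model = build_block_precision(cfg)
    data, record = sample_cohort(model, cfg, return_record=True)
    return cfg, model, data, record


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort (p=10, n=250) for pipeline smoke tests."""
    cfg = GeneratorConfig(
        n_persons=250, block_sizes=(3, 3, 2, 2), seed=11,
        n_univariate_outliers=1, n_multivariate_outliers=2,
        reverse_oriented=(8, 9), age_effect=[0.3] + [0.0] * 9,
    )
    model = build_block_precision(cfg)
    data = sample_cohort(model, cfg)
    return cfg, model, data


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """Fitted network on the small cohort, shared across tests."""
    from symptomnet import SymptomNetwork

    _, _, data = small_cohort
    config = PipelineConfig(n_lambda=40)
    return SymptomNetwork(data, config).fit()


@pytest.fixture()
def toy_network():
    """Hand-built 4-node network with mixed-sign weights."""
    from symptomnet import NetworkModel

    W = np.array([
        [0.0, 0.3, -0.2, 0.0],
        [0.3, 0.0, 0.1, 0.0],
        [-0.2, 0.1, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
    ])
    prec = np.eye(4) - W
    return NetworkModel(nodes=["A", "B", "C", "D"], precision=prec, adjacency=W,
                        lambda_selected=0.0, gamma=0.5)


def make_rating(values: np.ndarray, names=None, **kwargs) -> RatingMatrix:
    names = names or [f"V{j}" for j in range(values.shape[1])]
    return RatingMatrix(values=pd.DataFrame(values, columns=names), **kwargs)
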