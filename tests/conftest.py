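import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import songdrift as sd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return sd.default_catalog()


@pytest.fixture(scope="session")
def ref_params():
    return sd.REFERENCE_PARAMS


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Rates equal to the exact response probabilities at the reference truth."""
    from songdrift.datasets import ResponseDataset, ResponseRecord
    from songdrift.fitting import predict_probabilities

    records = []
    for cfg in sd.reference_stimulus_sets(seed=0):
        songs = sd.build_stimulus_set(cfg)
        shell = ResponseDataset(
            [ResponseRecord(s, 0.0, 20, 18, cfg.positive, cfg.negative) for s in songs]
        )
        p = predict_probabilities(shell, sd.REFERENCE_PARAMS)
        records += [
            ResponseRecord(s, float(pi), 20, 18, cfg.positive, cfg.negative)
            for s, pi in zip(songs, p)
        ]
    return ResponseDataset(records)
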