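"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from seizeeg import GeneratorConfig, features_table, generate_dataset, generate_record
from seizeeg.preprocess import bandpass

#: strongly separable world: default class balance (19.4% ictal), burst gain 5
SEPARABLE = dict(duration=120.0, ictal_gain=5.0, seed=11)


@pytest.fixture(scope="session")
def separable_records():
    """34 strongly separable records (510 labelled segments in total)."""
    return generate_dataset(34, GeneratorConfig(**SEPARABLE))


@pytest.fixture(scope="session")
def separable_table(separable_records):
    """Band-limited 13-feature table pooled over the separable records."""
    return pd.concat(
        [features_table(bandpass(r)) for r in separable_records], ignore_index=True
    )


@pytest.fixture(scope="session")
def small_record():
    """One short record for I/O and preprocessing tests."""
    return generate_record(GeneratorConfig(duration=30.0, n_channels=3, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
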