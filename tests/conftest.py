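import numpy as np
import pandas as pd
import pytest

from dentabc.trait_data import TraitDefinition, TraitObservationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def trait_defs_small():
    return [
        TraitDefinition("C6", "molar", "M1", ("M1", "M2"), breakpoint=2,
                        polarity="absence"),
        TraitDefinition("SHOV", "incisor", "I1", ("I1", "I2"), breakpoint=1,
                        polarity="presence"),
    ]


@pytest.fixture
def toy_matrix():
    """Eight specimens spread over four groups, two traits."""
    scores = pd.DataFrame(
        {
            "C6": [1, 0, 1, 1, 0, np.nan, 1, 0],
            "SHOV": [0, 1, np.nan, 1, 1, 1, 0, np.nan],
        },
        index=[f"S{i}" for i in range(8)],
    )
    metadata = pd.DataFrame(
        {
            "country": ["Spain", "Spain", "France", "Italy",
                        "Italy", "Austria", "Germany", "Israel"],
            "latitude": [40.0] * 8,
            "longitude": [0.0, 0.0, 2.0, 12.0, 12.0, 14.0, 9.0, 35.0],
            "age_mean": [30.0, 30.0, 20.0, 30.0, 10.0, 10.0, 10.0, 20.0],
        },
        index=scores.index,
    )
    return TraitObservationMatrix(scores, metadata)
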