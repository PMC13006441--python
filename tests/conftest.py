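import numpy as np
import pandas as pd
import pytest

from serumscape import synth
from serumscape.types import IntensityMatrix


@pytest.fixture()
def small_dataset():
    """35 samples x ~96 aptamers with planted class effects."""
    cfg = synth.GeneratorConfig(
        seed=11, n_me=20, n_hc=15, n_proteins=80, duplication_rate=0.2,
        effect_model={"intracellular": (-0.3, 0.1), "secreted": (0.3, 0.1)},
        noise_sd=0.4,
    )
    return synth.generate_dataset(cfg)


@pytest.fixture()
def null_dataset():
    """No planted effects anywhere."""
    cfg = synth.GeneratorConfig(seed=7, n_me=15, n_hc=12, n_proteins=60,
                                duplication_rate=0.0, covariate_effects={})
    return synth.generate_dataset(cfg)


@pytest.fixture()
def tiny_matrix():
    values = pd.DataFrame(
        [[100.0, 200.0], [110.0, 190.0], [95.0, 210.0]],
        index=["S1", "S2", "S3"], columns=["A1", "A2"],
    )
    return IntensityMatrix(values)
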