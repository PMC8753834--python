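import numpy as np
import pandas as pd
import pytest

from histosig import build_weighted_signature, differential_expression
from histosig.simulate import generate_pure_cohort


@pytest.fixture(scope="session")
def pure_small():
    """Small subtype-labeled cohort: 1000 genes, 60 planted per subtype."""
    return generate_pure_cohort(
        n_genes=1000, n_planted_per_subtype=60, effect_size=1.5, seed=7
    )


@pytest.fixture(scope="session")
def lepidic_signature(pure_small):
    x, ann, _ = pure_small
    prof = differential_expression(x, ann, "lepidic")
    return build_weighted_signature(prof, target_subtype="lepidic")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
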