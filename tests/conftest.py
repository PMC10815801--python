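import numpy as np
import pandas as pd
import pytest

from aptapanel import datasets
from aptapanel.shortlist import BindingPhenotype


@pytest.fixture(scope="session")
def tma_cohort() -> pd.DataFrame:
    """Per-sample expansion of the bundled TMA recognition marginals."""
    return datasets.load_tma_cohort()


@pytest.fixture(scope="session")
def phenotype() -> BindingPhenotype:
    """The aptamer panel's published cell-line recognition pattern."""
    return BindingPhenotype(
        recognized_lines=["MDA-MB-468", "BT-474", "MCF-7"],
        unrecognized_lines=["HCC-1937"],
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240110)
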