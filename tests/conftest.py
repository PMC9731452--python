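import numpy as np
import pandas as pd
import pytest

from startmer.construct import ConstructTemplate
from startmer.simulate import ALL_SEVENMERS, SimulationConfig


@pytest.fixture(scope="session")
def template() -> ConstructTemplate:
    """Default reporter construct (promoter + N7 cassette + constant UTR)."""
    return ConstructTemplate()


@pytest.fixture(scope="session")
def small_template() -> ConstructTemplate:
    """Compact construct for exhaustive enumeration tests.

    The constant region begins with the seed itself and continues
    aperiodically, so a read's first seed occurrence is always the true one
    and no alternative whole-read placement can be template-consistent.
    """
    return ConstructTemplate(
        promoter_seq="TGAACCGTC",
        cassette_len=7,
        downstream_seq="AGCCGCCGCCTAGTTACGAT",
        seed="AGCCGCCGCC",
        spikein_seq=None,
    )


@pytest.fixture(scope="session")
def sim_small() -> SimulationConfig:
    """Small-depth simulation sharing the default truth models."""
    return SimulationConfig(rng_seed=11, depth=100_000, count_depth=1_000_000)


def uniform_models() -> pd.DataFrame:
    """Degenerate truth models: every 7-mer identical (rate 1, P/SP 1,
    half-life 2 h in both conditions)."""
    n = len(ALL_SEVENMERS)
    return pd.DataFrame(
        {
            "rate": np.ones(n),
            "psp_control": np.ones(n),
            "psp_torin": np.ones(n),
            "hl_control": np.full(n, 2.0),
            "hl_torin": np.full(n, 2.0),
        },
        index=pd.Index(ALL_SEVENMERS),
    )
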