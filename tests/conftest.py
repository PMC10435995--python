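import numpy as np
import pandas as pd
import pytest

from thermoshift import syndata
from thermoshift.tpp import IntensityCube


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def make_cube(
    n_proteins=50,
    ladder=(37.0, 41.0, 45.0, 49.0, 53.0, 57.0),
    n_replicates=2,
    seed=0,
    **kwargs,
):
    """Small raw cube with truth, for fast unit tests."""
    cfg = syndata.SimConfig(
        n_proteins=n_proteins,
        ladder=ladder,
        n_replicates=n_replicates,
        seed=seed,
        **kwargs,
    )
    return syndata.gen_tpp(cfg)


@pytest.fixture
def small_cube():
    cube, truth = make_cube(frac_stabilized=0.0, frac_destabilized=0.0, noise_cv=0.05)
    return cube, truth


def manual_cube(intensities: dict, channel_rows: list) -> IntensityCube:
    """Cube from explicit per-channel intensity vectors, for oracle tests."""
    inten = pd.DataFrame(intensities)
    chans = pd.DataFrame(channel_rows).set_index("channel")
    return IntensityCube(inten, chans)
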