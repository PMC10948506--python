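import numpy as np
import pandas as pd
import pytest

from numadapt.io import EpochArray
from numadapt.montage import default_montage


@pytest.fixture(scope="session")
def montage():
    return default_montage()


def make_events(n_trials, condition="High", numerosity=16, participant=0):
    return pd.DataFrame(
        {
            "participant": participant,
            "block": 0,
            "trial": np.arange(n_trials),
            "adaptation": condition,
            "numerosity": numerosity,
        }
    )


def make_epochs(data, montage, condition="High", numerosity=16, sfreq=500.0, t0=-500.0):
    data = np.asarray(data, dtype=float)
    return EpochArray(
        data=data,
        events=make_events(data.shape[0], condition, numerosity),
        montage=montage,
        sfreq=sfreq,
        t0=t0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
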