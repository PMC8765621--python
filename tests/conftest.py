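import numpy as np
import pytest

import facefreq as ff


@pytest.fixture(scope="session")
def layout64():
    return ff.default_layout(64)


@pytest.fixture(scope="session")
def layout16():
    return ff.default_layout(16)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study configuration shared by integration-style tests."""
    return ff.SimConfig(
        n_per_group={"pTD": 5, "pASD": 6},
        n_trials_per_condition=12,
        n_channels=16,
        sfreq=125.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ff.simulate_cohort(small_config)


def _make_epochs(data, sfreq=250.0, conditions=None, group="pTD", pid="pTD00",
                 t0_ms=-500.0):
    """Wrap a raw array into an EpochSet with evenly spaced times."""
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, n_t = data.shape
    times = t0_ms + np.arange(n_t) * 1000.0 / sfreq
    if conditions is None:
        conditions = np.array((list(ff.CONDITIONS) * n_tr)[:n_tr], dtype=object)
    names = [f"E{i + 1}" for i in range(n_ch)]
    return ff.EpochSet(data=data, times=times, sfreq=sfreq, ch_names=names,
                       condition=np.asarray(conditions, dtype=object),
                       participant=pid, group=group)


@pytest.fixture(scope="session")
def make_epochs():
    """Factory fixture wrapping raw arrays into EpochSets."""
    return _make_epochs
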