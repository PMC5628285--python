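import numpy as np
import pytest

import cesdcat as cc


@pytest.fixture(scope="session")
def bank():
    """The packaged 17-item calibrated CES-D bank."""
    return cc.cesd_item_bank()


@pytest.fixture(scope="session")
def small_bank():
    """A 3-item toy bank with hand-set parameters."""
    return cc.ItemBank(
        [
            cc.GRMItem("i1", 1.0, [-1.0, 0.0, 1.0]),
            cc.GRMItem("i2", 2.0, [-0.5, 0.5, 1.5]),
            cc.GRMItem("i3", 0.8, [-2.0, -1.0, 0.5]),
        ]
    )


@pytest.fixture(scope="session")
def unidim_data(bank):
    """GRM responses from the packaged bank, theta ~ N(0,1), n=2000."""
    thetas = cc.draw_thetas(2000, seed=101)
    return cc.simulate_grm_responses(bank, thetas, seed=102)


@pytest.fixture(scope="session")
def fitted(unidim_data):
    """A calibration of the unidimensional dataset (shared, it is slow)."""
    return cc.fit_grm(unidim_data, compute_se=False)
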