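import logging

import numpy as np
import pytest

from spikemvar.mvar_core import MVARModel


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # pipeline telemetry (clip/truncation warnings) is expected in many tests
    logging.getLogger("spikemvar").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_stable_model(rng, p, m, radius_cap=0.9):
    """Random stable propagation-form model (rejection sampling on the radius)."""
    for _ in range(200):
        B = rng.uniform(-0.6, 0.6, size=(m, p, p))
        L = rng.standard_normal((p, p)) * 0.3
        Sigma = L @ L.T + np.eye(p)
        model = MVARModel.from_propagation(B, Sigma)
        rho = model.spectral_radius()
        if rho < radius_cap:
            return model
        # shrink toward stability instead of rejecting outright
        s = 0.8 * radius_cap / rho
        B = B * (s ** np.arange(1, m + 1))[:, None, None]
        model = MVARModel.from_propagation(B, Sigma)
        if model.spectral_radius() < radius_cap:
            return model
    raise RuntimeError("failed to draw a stable model")
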