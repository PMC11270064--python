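import numpy as np
import pytest

from hyperna.models import ToyParams, get_model, toy_model
from hyperna.protocols import PacingProtocol


@pytest.fixture(scope="session")
def toy():
    """Default analytic toy cell."""
    return toy_model(ToyParams())


@pytest.fixture(scope="session")
def toy_protocol():
    return PacingProtocol(rate=60.0, total_duration_min=0.05,
                          analysis_window_s=3.0)


@pytest.fixture(scope="session")
def short_protocol():
    """Three-beat pacing protocol for fast full-model exercises."""
    return PacingProtocol(rate=50.0, total_duration_min=0.06,
                          analysis_window_s=3.6)


@pytest.fixture(scope="session", params=["torord", "bps2020"])
def ionic_model(request):
    return get_model(request.param)


@pytest.fixture(scope="session")
def probe_state():
    """A mid-upstroke-ish probe state per model, for pinned-state current
    ratio checks (away from rest so every current is non-trivial)."""

    def _make(model):
        y = model.initial_state()
        y[0] = -20.0
        # partially open gates so conductance paths are active
        for i, name in enumerate(model.state_names):
            if name in ("m", "mL", "a", "d", "xrf", "xrs", "xs1", "xs2", "o",
                        "n"):
                y[i] = 0.5
        if "cass" in model.state_names:
            y[model.state_index("cass")] = 5e-4
            y[model.state_index("cai")] = 2e-4
        return y

    return _make
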