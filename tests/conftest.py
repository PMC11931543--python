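import numpy as np
import pytest

import swntpore as sp


@pytest.fixture(scope="session")
def geometry() -> sp.DeviceGeometry:
    """The 1.01 nm x 1.1 mm device geometry used throughout."""
    return sp.DeviceGeometry(length=1.1e-3, diameter=1.01e-9)


@pytest.fixture(scope="session")
def dopamine_params() -> sp.TransportParams:
    """Dopamine-like transport parameters (mu0, k_ads, k_des at pH 4.85)."""
    return sp.TransportParams(
        mobility_intrinsic=2.76e-5,
        voltage=1.0,
        k_ads=27.5,
        k_des=53.6,
        entry_rate=5.0,
    )


@pytest.fixture(scope="session")
def small_sim(geometry, dopamine_params):
    """A modest simulated trace + idealization shared by detection tests."""
    config = sp.TraceConfig(
        duration=5.0, sampling_rate=25_000.0, pbc_depth=30.0, noise_sd=2.0, seed=7
    )
    trace, truth = sp.simulate_trace(geometry, dopamine_params, config)
    filtered = sp.boxcar_filter(trace, 99)
    levels = sp.find_two_states(sp.current_histogram(filtered))
    table = sp.detect_events(filtered, levels, raw_trace=trace)
    return {
        "config": config,
        "trace": trace,
        "filtered": filtered,
        "levels": levels,
        "table": table,
        "truth": truth,
    }
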