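import numpy as np
import pytest

import xdflow as x


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Static-respiration 48^2 phantom with pulsatile flow."""
    cfg = x.PhantomConfig(
        grid_size=48, n_coils=6, scan_duration_s=60.0, TR_ms=4.0,
        vessel=x.VesselSpec(radius_mm=9.0, peak_velocity=80.0, pulsatility=0.3),
        seed=11,
    )
    return x.Phantom(cfg)


@pytest.fixture(scope="session")
def small_acquisition(small_phantom):
    """One simulated acquisition shared by recon/physio unit tests."""
    order = x.build_view_order(
        small_phantom.grid, n_cardiac=4, n_echoes=4,
        spokes_per_mask=60, density_exponent=0.3)
    return x.simulate_acquisition(small_phantom, order)
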