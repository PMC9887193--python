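"""Shared fixtures: protocols, phantom profiles, and the recovery battery.

The end-to-end recovery grid is expensive (six rendered images plus a
20-seed noisy batch), so it is computed once per session and shared
between the property tests and the acceptance tests.
"""

import numpy as np
import pytest

from lsdi import (
    AcquisitionProtocol,
    CardiacCycle,
    estimate_wbrv_from_image,
    phantom_profile,
    render_lsdi_image,
)

ETA_GRID = (2.0, 4.0, 8.0)
LAMBDA_GRID = (0.85, 0.9)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def cycle():
    return CardiacCycle(T_C=160.0)


@pytest.fixture(scope="session")
def recovery_grid(protocol, cycle):
    """Noise-free end-to-end estimates over the (eta_r, lambda) battery."""
    results = {}
    for eta in ETA_GRID:
        for lam in LAMBDA_GRID:
            profile = phantom_profile(eta, lam)
            image = render_lsdi_image(profile, protocol, cycle, 0.0, 1)
            results[(eta, lam)] = estimate_wbrv_from_image(image, protocol, cycle)
    return results


@pytest.fixture(scope="session")
def noisy_estimates(protocol, cycle):
    """Estimates for eta_r = 4, lambda = 0.9 with Gaussian noise, 20 seeds."""
    profile = phantom_profile(4.0, 0.9)
    etas = []
    for seed in range(20):
        image = render_lsdi_image(profile, protocol, cycle, 0.05, seed)
        etas.append(estimate_wbrv_from_image(image, protocol, cycle).eta_r)
    return np.array(etas)
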