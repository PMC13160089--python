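import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fripkit.barrier_kinetics import uniform_barrier_set
from fripkit.extrusion import (
    SimParams,
    scan_cohesin_abundance,
    scan_ctcf_abundance,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

COHESIN_RATIOS = (0.1, 0.25, 0.5, 1.0, 1.5, 2.0)
CTCF_RATIOS = (0.0, 0.25, 0.5, 0.75, 1.0)
N_SCAN_SEEDS = 20


@pytest.fixture(scope="session")
def baseline_params():
    return SimParams()


@pytest.fixture(scope="session")
def homogeneous_barriers():
    """The baseline barrier block: occupancy 0.625 (bound 780 s / unbound
    468 s), total target occupancy 13 per Mb."""
    return uniform_barrier_set(0.625, 13.0, sites_per_replica=4000, seed=1,
                               bound_time=780.0)


@pytest.fixture(scope="session")
def cohesin_scan(baseline_params, homogeneous_barriers):
    """Simulated FRiP vs cohesin abundance, 20 seeds per ratio (shared across
    the stochastic trend tests)."""
    return scan_cohesin_abundance(
        COHESIN_RATIOS, baseline_params, homogeneous_barriers,
        seeds=list(range(N_SCAN_SEEDS)),
    )


@pytest.fixture(scope="session")
def ctcf_scan(baseline_params, homogeneous_barriers):
    return scan_ctcf_abundance(
        CTCF_RATIOS, baseline_params, homogeneous_barriers,
        seeds=list(range(N_SCAN_SEEDS)),
    )
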