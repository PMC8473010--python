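import numpy as np
import pytest

from forcemapper import (
    CurveSimParams,
    ForceCurve,
    MapSimParams,
    analyse_grid,
    simulate_force_grid,
)


@pytest.fixture(scope="session")
def noiseless_curve_and_truth():
    from forcemapper import simulate_force_curve

    return simulate_force_curve(CurveSimParams(noise_sd=0.0))


@pytest.fixture(scope="session")
def default_grid_and_truth():
    """A 16x16 two-phase grid with the default two-disc Lo layout."""
    return simulate_force_grid(MapSimParams(seed=3))


@pytest.fixture(scope="session")
def default_grid_analysis(default_grid_and_truth):
    grid, _ = default_grid_and_truth
    return analyse_grid(grid)


def make_curve(z, F, **kwargs):
    return ForceCurve(z=np.asarray(z, float), F=np.asarray(F, float), **kwargs)


@pytest.fixture
def sharp_breakthrough_curve():
    """Noiseless approach curve with a genuine force drop at rupture.

    z descends 30 -> 0 nm; force ramps 0 -> 3 nN between z=20 and z=10,
    drops to 2.4 nN across a 4 nm plateau ending at z=6, then climbs a
    hard wall.  The onset at z=10 is a true local force maximum, visible
    without any rotation.
    """
    z = np.linspace(30.0, 0.0, 601)  # 0.05 nm steps
    F = np.zeros_like(z)
    ramp = (z <= 20) & (z >= 10)
    F[ramp] = 0.3 * (20 - z[ramp])
    plateau = (z < 10) & (z >= 6)
    F[plateau] = 3.0 - 0.15 * (10 - z[plateau])
    wall = z < 6
    F[wall] = 2.4 + 5.0 * (6 - z[wall])
    return make_curve(z, F), {"z_onset": 10.0, "force": 3.0, "z_completion": 6.0}
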