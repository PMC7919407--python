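import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssrox import (
    DamageModel,
    DriftModel,
    HitModel,
    NoiseModel,
    ScanGeometry,
    UnitCell,
    default_config,
    enumerate_unique_hkl,
    generate_truth,
    simulate_stream,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tet_cell():
    return UnitCell.tetragonal(78.4, 38.4)


@pytest.fixture(scope="session")
def coarse_truth(tet_cell):
    """Small truth set (d_min 2.5 Å) shared by stream-level tests."""
    return generate_truth(tet_cell, 2.5, 13.0, 100.0, "4/mmm", seed=101)


@pytest.fixture(scope="session")
def mini_stream(coarse_truth):
    """A 300-image acquisition under the default reference condition."""
    cfg = default_config()
    return simulate_stream(
        coarse_truth,
        ScanGeometry(2, 150),
        cfg.beam,
        HitModel(),
        DriftModel.tetragonal_drift(78.44, 78.34, 38.38, 38.79, jitter=0.02),
        DamageModel(),
        NoiseModel(obs_fraction=0.2),
        seed=7,
    )


@pytest.fixture(scope="session")
def coarse_possible(tet_cell):
    return enumerate_unique_hkl(tet_cell, 2.5, "4/mmm")


def shell_wilson_slope(s, intensities, n_shells=12):
    """Independent regression oracle: slope of ln(shell mean I) vs shell mean s."""
    edges = np.quantile(s, np.linspace(0, 1, n_shells + 1))
    which = np.clip(np.searchsorted(edges[1:-1], s, "left"), 0, n_shells - 1)
    mean_i = np.array([intensities[which == j].mean() for j in range(n_shells)])
    mean_s = np.array([s[which == j].mean() for j in range(n_shells)])
    return np.polyfit(mean_s, np.log(mean_i), 1)[0]
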