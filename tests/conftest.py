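"""Shared fixtures: coarse grids and a small, fast run configuration.

The small configuration keeps the full study structure (forced 3%/7%
mixtures, constituent-aware CV, pure shell targets) but shrinks the grid
and sample counts so unit tests run in well under a second each.
"""

import copy

import numpy as np
import pytest

from nutshell import (Band, EndmemberModel, WavenumberGrid, default_config)


@pytest.fixture(scope="session")
def coarse_grid() -> WavenumberGrid:
    """Instrument span at 40 cm^-1 spacing: 191 channels."""
    return WavenumberGrid(start=11550.0, stop=3950.0, step=40.0)


@pytest.fixture(scope="session")
def small_grid() -> WavenumberGrid:
    """A 101-channel toy grid for hand-built spectra."""
    return WavenumberGrid(start=5000.0, stop=4000.0, step=10.0)


@pytest.fixture(scope="session")
def tiny_config() -> dict:
    """4 nutmeg + 2 shell samples, 14 mixtures, 2 CV repeats, coarse grid."""
    cfg = copy.deepcopy(default_config())
    cfg["grid"] = {"start": 11550.0, "stop": 3950.0, "step": 40.0}
    cfg["design"] = {
        "n_nutmeg": 4,
        "n_shell": 2,
        "forced_levels": [3.0, 7.0],
        "per_level_counts": {1.0: 2, 5.0: 2, 10.0: 2},
        "min_per_nutmeg": 2,
        "min_per_shell": 3,
        "count_range": [1, 23],
    }
    cfg["n_repeats"] = 2
    return cfg


@pytest.fixture(scope="session")
def endmember_models(tiny_config) -> tuple[EndmemberModel, EndmemberModel]:
    """The default nutmeg/shell band models (full band set)."""
    from nutshell.configload import endmember_from_config

    return (endmember_from_config(tiny_config, "nutmeg"),
            endmember_from_config(tiny_config, "shell"))


def make_linear_spectra(grid: WavenumberGrid, fractions, base_amp=1.0,
                        signal_amp=0.05):
    """Spectra exactly linear in shell fraction along one direction.

    base profile and signal direction are smooth, zero-covariance curves;
    returns (matrix, base, direction)."""
    t = np.linspace(0, 2 * np.pi, len(grid))
    base = base_amp * (1.5 + np.sin(t))
    direction = signal_amp * np.cos(2 * t)  # orthogonal to sin(t) and to 1
    x = np.array([base + f * direction for f in np.atleast_1d(fractions)])
    return x, base, direction
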