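"""Shared fixtures: synthetic sessions reused across test modules.

Session-scoped so the expensive default synthetic session is generated
once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from lfpspace import grid_layout, utah_array
from lfpspace.preprocess import build_epoch_grid, zscore_channels
from lfpspace.simulate import default_params, generate_session
from lfpspace.spatial import session_distance_function

DEFAULT_SEED = 11
DEFAULT_N_EPOCHS = 360


@pytest.fixture(scope="session")
def layout96():
    return utah_array()


@pytest.fixture(scope="session")
def toy_layout():
    """Fully wired 4x4 grid for brute-force oracles."""
    return grid_layout(4, 4, pitch_um=400.0)


@pytest.fixture(scope="session")
def default_session(layout96):
    """Default 360-epoch synthetic session with ground truth."""
    params = default_params()
    rec, truth = generate_session(
        layout96, params, n_epochs=DEFAULT_N_EPOCHS, seed=DEFAULT_SEED
    )
    return rec, truth, params


@pytest.fixture(scope="session")
def default_zscored(default_session):
    rec, truth, params = default_session
    return zscore_channels(rec), truth, params


@pytest.fixture(scope="session")
def default_grid(default_zscored):
    rec, _, params = default_zscored
    return build_epoch_grid(rec, params.epoch_s)


@pytest.fixture(scope="session")
def default_dcf(default_zscored, default_grid, layout96):
    rec, _, _ = default_zscored
    return session_distance_function(rec, layout96, default_grid)


@pytest.fixture(scope="session")
def default_fits(default_dcf):
    from lfpspace.decay import fit_all_epochs

    return fit_all_epochs(
        default_dcf,
        ("exponential", "powerlaw", "gaussian", "linear"),
        exclude_frac=0.2,
    )


@pytest.fixture(scope="session")
def default_staging(default_zscored, default_grid):
    from lfpspace.preprocess import make_virtual_lfp
    from lfpspace.staging import stage_epochs

    rec, _, _ = default_zscored
    return stage_epochs(make_virtual_lfp(rec), rec.fs, default_grid, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
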