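"""Shared fixtures: small synthetic datasets reused across the suite.

Heavy full-scale study runs (8 simulated subjects) are session-scoped so the
acceptance tests share one computation; unit tests use small grids and short
recordings.
"""

from __future__ import annotations

import numpy as np
import pytest

import emgmap as eg


@pytest.fixture(scope="session")
def wrist_sim():
    """One default 20-cycle wrist recording (seed 1), neutral position."""
    cfg = eg.wrist_config(1)
    return cfg, eg.simulate_recording(cfg, "neutral")


@pytest.fixture(scope="session")
def wrist_task(wrist_sim):
    """The processed version of :func:`wrist_sim` (envelope kept, decimated)."""
    _cfg, sim = wrist_sim
    return eg.process_task(
        sim.emg, sim.angle_raw, sim.kinematics_fs, keep_envelope=True
    )


@pytest.fixture(scope="session")
def wrist_decomposition(wrist_task):
    """N=3 best-of-20-restarts factorization of the seed-1 wrist task."""
    from emgmap.pipeline import _fit_on_tasks

    dec, _ = _fit_on_tasks(
        {"wrist_flex_ext": wrist_task}, n_modules=3, n_restarts=20, seed=1
    )
    return dec


@pytest.fixture(scope="session")
def wrist_study_results():
    """Full 8-subject two-position wrist study (shared by acceptance tests)."""
    from emgmap.study import wrist_study

    return wrist_study(select_modules=True)


@pytest.fixture(scope="session")
def finger_study_results():
    """Full 8-subject finger-separability study."""
    from emgmap.study import finger_study

    return finger_study()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
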