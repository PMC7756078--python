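from __future__ import annotations

import time

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from artdose import (
    ExperimentConfig,
    GridSpec,
    PhantomSpec,
    build_phantom,
    run_experiment,
)

# compact thorax used by unit tests: same topology as the default phantom,
# ~half scale, so courses and plans run in seconds
SMALL_SPEC = PhantomSpec(
    gtv_radius_mm=18.0,
    gtv_volume_cm3=None,
    body_semiaxes_mm=(75.0, 62.0),
    lung_semiaxes_mm=(26.0, 30.0, 55.0),
    lung_offset_mm=36.0,
    heart_center_mm=(-12.0, 6.0, -15.0),
    heart_semiaxes_mm=(20.0, 18.0, 25.0),
    esophagus_center_xy_mm=(0.0, 20.0),
    esophagus_radius_mm=4.0,
    cord_center_xy_mm=(0.0, 55.0),
    cord_radius_mm=4.0,
)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec.centered((32, 32, 32), (5.0, 5.0, 5.0))


@pytest.fixture(scope="session")
def small_phantom(small_grid):
    return build_phantom(SMALL_SPEC, small_grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_report():
    """Full default experiment (10 patients, 64³, three arms), timed.

    Shared by the cohort-level acceptance checks so the experiment runs once
    per session.  Returns (report, wall_seconds).
    """
    t0 = time.perf_counter()
    report = run_experiment(ExperimentConfig(seed=1))
    return report, time.perf_counter() - t0
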