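import numpy as np
import pytest

from circstereo import RigConfig, ScenarioSpec, default_intrinsics, run_protocol


@pytest.fixture(scope="session")
def intrinsics():
    return default_intrinsics()


@pytest.fixture(scope="session")
def rig():
    return RigConfig()


@pytest.fixture(scope="session")
def grid_scene(rig):
    """One noise-free fronto-parallel 8x8 grid scene (with fiducial)."""
    return run_protocol(ScenarioSpec(kind="grid"), rig)[0]


@pytest.fixture(scope="session")
def tilted_scene(rig):
    """A 45-degree tilted grid scene (strong eccentricity regime)."""
    scenes = run_protocol(ScenarioSpec(kind="testB", repeats=1), rig)
    return next(s for s in scenes if s.meta["step"] == 45.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
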