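import warnings

import numpy as np
import pytest

import vesiq as vq

# the detector warns when the expected diameter under-samples the coarse z
# axis (true for the 0.5 μm sections used throughout); keep test output clean
warnings.filterwarnings("ignore", message="expected diameter")


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale scene (10×160×160) that keeps every stage exercised."""
    return vq.steadystate_config(
        seed=1,
        image_shape_zyx=(10, 160, 160),
        vessel_inner_radius=1.2,
        shell_thickness=0.5,
        vesicle_density=0.15,
        lysosome_density=0.15,
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    stack, manifest = vq.generate_vessel_stack(small_config)
    return stack, manifest


@pytest.fixture(scope="session")
def small_mask(small_scene):
    stack, _ = small_scene
    return vq.segment_stack(stack)


@pytest.fixture(scope="session")
def steady_scene():
    """One full-size steady-state fixture stack (the default acquisition)."""
    stack, manifest = vq.generate_vessel_stack(vq.steadystate_config(seed=1))
    return stack, manifest


@pytest.fixture(scope="session")
def steady_mask(steady_scene):
    stack, _ = steady_scene
    return vq.segment_stack(stack)


@pytest.fixture(scope="session")
def bright_config():
    """Steady-state geometry with uniformly bright puncta (all SNR >= 10)."""
    return vq.steadystate_config(
        seed=1, intensity_lognormal=(float(np.log(20000.0)), 0.4))


@pytest.fixture(scope="session")
def bright_scene(bright_config):
    stack, manifest = vq.generate_vessel_stack(bright_config)
    return stack, manifest
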