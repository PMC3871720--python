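import dataclasses

import pytest

from lactoscan import SceneParams, generate_scene, render_channels


@pytest.fixture(scope="session")
def default_scene():
    """Default 512x512 test field: 200 globules, 6% incidence, 10 cells."""
    return generate_scene(SceneParams(seed=1))


@pytest.fixture(scope="session")
def default_stack(default_scene):
    return render_channels(default_scene)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, blur-free render for exactness checks."""
    params = dataclasses.replace(SceneParams(seed=2), blur_sigma=0.0, noise="none")
    return generate_scene(params)


@pytest.fixture(scope="session")
def clean_stack(clean_scene):
    return render_channels(clean_scene)
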