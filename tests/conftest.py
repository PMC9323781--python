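"""Shared synthetic fixtures.

Small fruit (radius 60 px) keep unit tests fast; acceptance tests
build their own orange-sized (125 px) sequences.
"""

import numpy as np
import pytest
from hypothesis import settings

from fruitmap.synthetic import generate_sequence, make_scene

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# texture band-limited to the render resolution of a 60 px fruit, so
# reconstruction error measures geometry, not texture aliasing
SMOOTH = {"sigma_px": 8.0, "fine_sigma_px": 3.0}


@pytest.fixture(scope="session")
def sphere_bundle():
    """13 views x 30 deg of a textured sphere, radius 60 px."""
    scene = make_scene(
        geometry="spherical", radius=60, n_views=13, step_deg=30,
        texture_kind="noise", texture_params=dict(SMOOTH), seed=11,
        image_size=150,
    )
    return generate_sequence(scene)


@pytest.fixture(scope="session")
def oblate_bundle():
    """13 views of an oblate spheroid (60, 45.6, 60 px)."""
    scene = make_scene(
        geometry="oblate", radius=60, n_views=13, step_deg=30,
        texture_kind="noise", texture_params=dict(SMOOTH), seed=12,
        image_size=150,
    )
    return generate_sequence(scene)


@pytest.fixture(scope="session")
def prolate_bundle():
    """13 views of a prolate spheroid (60, 78.9, 60 px)."""
    scene = make_scene(
        geometry="prolate", radius=60, n_views=13, step_deg=30,
        texture_kind="noise", texture_params=dict(SMOOTH), seed=13,
        image_size=180,
    )
    return generate_sequence(scene)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
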