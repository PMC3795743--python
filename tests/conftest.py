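import numpy as np
import pytest
from hypothesis import settings

import spherecut as sc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def icosahedron():
    """Level-0 template: 12 rays, 20 triangles, 30 edges."""
    return sc.build_template(0)


@pytest.fixture(scope="session")
def template_level2():
    return sc.build_template(2)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free 150/50 sphere of radius 15 mm in a 64^3 1 mm grid."""
    spec = sc.PhantomSpec(
        shape="sphere",
        dims=(64, 64, 64),
        spacing_mm=(1.0, 1.0, 1.0),
        center_mm=(31.5, 31.5, 31.5),
        radius_mm=(15.0,),
        fg_intensity=150.0,
        bg_intensity=50.0,
        noise_sd=0.0,
        rng_seed=0,
    )
    volume, truth = sc.make_phantom(spec)
    return spec, volume, truth


def triangle_template():
    """Three mutually adjacent rays (one spherical triangle): the smallest
    instance on which the smoothness constraint is non-trivial."""
    dirs = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    return sc.SphericalTemplate(
        directions=dirs,
        triangles=np.array([[0, 1, 2]]),
        neighbor_pairs=frozenset({(0, 1), (0, 2), (1, 2)}),
        subdivision_level=0,
    )


@pytest.fixture
def three_rays():
    return triangle_template()


def cost_field(c):
    return sc.CostField(c=np.asarray(c, dtype=float), mean_estimate=0.0)
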