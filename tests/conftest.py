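import numpy as np
import pytest

import morphable as M
from morphable.fixtures import (DemographicGroup, FixtureSpec,
                                generate_population, make_template)


@pytest.fixture(scope="session")
def template():
    """Resolution-1 synthetic face template with its landmark set."""
    return make_template(1)


@pytest.fixture(scope="session")
def warp_population():
    """Noise-free, remeshed, smoothly warped targets with ground truth —
    the cleanest conditions for correspondence-recovery checks."""
    spec = FixtureSpec(n_subjects=4, seed=7, noise_sd=0.0,
                       demographics=(DemographicGroup("A", 1.0, 0.0),),
                       remesh=True)
    return spec, generate_population(spec)


@pytest.fixture(scope="session")
def registered_warp(template, warp_population):
    """NICP registrations of the warp population (computed once)."""
    tmpl, tlms = template
    _, pop = warp_population
    return [(s, M.nicp_register(tmpl, s.raw, tlms, s.landmarks))
            for s in pop]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_valid_mesh(rng, n=12, m=15, colors=False):
    """Small random valid triangle mesh for I/O round-trip tests."""
    pts = rng.normal(0.0, 10.0, (n, 3))
    tris = []
    while len(tris) < m:
        t = rng.choice(n, 3, replace=False)
        tris.append(t)
    return M.TriangleMesh(
        points=pts, trilist=np.array(tris),
        colors=rng.uniform(0, 1, (n, 3)) if colors else None)
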