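import numpy as np
import pytest

from connalign import (
    SyntheticSpec,
    bilateral_mesh,
    build_searchlights,
    generate_cohort,
    make_icosphere,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def ico1_pair():
    return bilateral_mesh(
        make_icosphere(1, 25.0, "left"), make_icosphere(1, 25.0, "right")
    )


@pytest.fixture(scope="session")
def ico2_pair():
    return bilateral_mesh(
        make_icosphere(2, 25.0, "left"), make_icosphere(2, 25.0, "right")
    )


@pytest.fixture(scope="session")
def ico2_atlas(ico2_pair):
    # radius a bit over one edge length (~13 mm) -> center + first ring
    return build_searchlights(ico2_pair, 15.0)


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-scale-in-miniature generator spec used across tests."""
    return SyntheticSpec(
        subdivision=2,
        sphere_radius_mm=25.0,
        n_subjects=4,
        n_timepoints=120,
        n_sessions=2,
        mixing_radius_mm=14.0,
        smoothness_mm=20.0,
        noise_sd=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


def random_orthogonal(m, rng):
    """Haar orthogonal matrix for test constructions."""
    q, r = np.linalg.qr(rng.standard_normal((m, m)))
    return q * np.sign(np.diag(r))
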