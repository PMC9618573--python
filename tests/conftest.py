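import numpy as np
import pytest

from ansamer.core import MolecularSystem
from ansamer.descriptor import M_ANSA, P_ANSA
from ansamer.synth_fixtures import FixtureSpec, make_amatoxin_like, make_bridged_macrocycle


@pytest.fixture
def amatoxin():
    """Amatoxin-topology fixture, bridge apex on +z, N->C counter-clockwise."""
    return make_amatoxin_like(bridge_height=3.0)


@pytest.fixture
def octapeptide():
    return make_bridged_macrocycle(FixtureSpec())


@pytest.fixture
def monocycle():
    return make_bridged_macrocycle(FixtureSpec(bridge_span=None))


def random_fixture_spec(rng: np.random.Generator) -> FixtureSpec:
    """Randomized bridged fixture: ring size 6-12, varying span/height/noise."""
    n_res = int(rng.integers(6, 13))
    i = int(rng.integers(1, n_res + 1))
    j = int(rng.integers(1, n_res + 1))
    while j == i:
        j = int(rng.integers(1, n_res + 1))
    span = (min(i, j), max(i, j))
    height = float(rng.uniform(1.5, 4.0)) * (1 if rng.random() < 0.5 else -1)
    return FixtureSpec(
        n_residues=n_res,
        bridge_span=span,
        bridge_height=height,
        n_bridge_atoms=int(rng.integers(1, 6)),
        noise=float(rng.uniform(0.0, 0.2)),
        seed=int(rng.integers(0, 2**31 - 1)),
        sense="CCW" if rng.random() < 0.5 else "CW",
    )


def expected_descriptor(spec: FixtureSpec) -> str:
    """Closed-form oracle from the construction geometry.

    The ring lies in z=0; a CCW N->C traversal gives a +z oriented normal,
    CW gives -z.  The leading atom sits at z of the same sign as the bridge
    height, so the side sign is sign(height) for CCW and -sign(height) for
    CW; positive side means M_ansa under the package convention.
    """
    side = (1 if spec.bridge_height > 0 else -1) * (1 if spec.sense == "CCW" else -1)
    return M_ANSA if side > 0 else P_ANSA


def rigid_transform(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rotation = Rotation.random(random_state=rng).as_matrix()
    translation = rng.uniform(-50.0, 50.0, size=3)
    return coords @ rotation.T + translation


def tiny_system(coords, elements, names=None, resids=None, bonds=()):
    """Small ad-hoc MolecularSystem for geometric unit tests."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[-2]
    return MolecularSystem(
        elements=list(elements),
        names=list(names) if names is not None else list(elements),
        resnames=["MOL"] * n,
        resids=list(resids) if resids is not None else [1] * n,
        coords=coords,
        bonds=list(bonds),
    )
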