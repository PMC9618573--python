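"""Synthetic bridged-macrocycle fixtures.

Generates idealized bridged macrolactams: the backbone atoms (N, CA, C' per
residue) sit evenly on a circle in the z=0 plane, and a side-chain bridge
arc connects the alpha carbons of two chosen residues with its apex at a
signed height h above (+) or below (-) the ring plane.  The sign of h and
the N->C traversal sense (CCW or CW viewed from +z) fully determine the
expected ansamer descriptor, which makes these fixtures exact oracles for
the assignment code.

These are geometric idealizations, not chemically valid conformers: bond
lengths are uniform and side chains beyond the bridge are omitted.  Every
algorithm in this package is purely geometric/topological, so that is
sufficient.  Bonds are emitted explicitly; no perception is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Ensemble, MolecularSystem
from .errors import InputError

__all__ = [
    "FixtureSpec",
    "AMATOXIN_RESIDUES",
    "make_bridged_macrocycle",
    "make_amatoxin_like",
    "mirror",
    "make_ensemble",
]

#: Residue names of the simplified amatoxin scaffold (Ile3-amaninamide-like).
AMATOXIN_RESIDUES = ("Asn", "Hyp", "Ile", "Trp", "Gly", "Ile", "Gly", "Cys")


@dataclass
class FixtureSpec:
    """Parameters of a synthetic bridged macrolactam.

    ``bridge_span`` gives the two bridged residues (1-based); ``None``
    produces a monocycle.  ``bridge_height`` is signed: positive puts the
    bridge apex on the +z side.  ``sense`` is the N->C traversal direction
    seen from +z.  With a fixed ``seed`` the output is bit-reproducible.
    """

    n_residues: int = 8
    ring_radius: float | None = None  # default: 1.5 A bond length spacing
    bridge_span: tuple[int, int] | None = (4, 8)
    bridge_height: float = 3.0
    n_bridge_atoms: int = 3
    noise: float = 0.0
    seed: int = 0
    sense: str = "CCW"
    residue_names: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise InputError("need at least 3 residues")
        if self.sense not in ("CCW", "CW"):
            raise InputError("sense must be CCW or CW")
        if self.noise < 0:
            raise InputError("noise sigma must be nonnegative")
        if self.bridge_span is not None:
            i, j = self.bridge_span
            if i == j:
                raise InputError("bridge span endpoints must differ")
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                raise InputError("bridge span outside residue range")
            if self.bridge_height == 0:
                raise InputError("bicyclic fixture needs a nonzero bridge height")
            if self.n_bridge_atoms < 1:
                raise InputError("bridge needs at least one atom")


def _ring_coordinates(spec: FixtureSpec) -> np.ndarray:
    n_atoms = 3 * spec.n_residues
    radius = (
        spec.ring_radius
        if spec.ring_radius is not None
        else n_atoms * 1.5 / (2.0 * np.pi)
    )
    angles = 2.0 * np.pi * np.arange(n_atoms) / n_atoms
    if spec.sense == "CW":
        angles = -angles
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n_atoms)]
    )


def make_bridged_macrocycle(spec: FixtureSpec | None = None, **overrides) -> MolecularSystem:
    """Build a (possibly bridged) macrolactam fixture from a spec.

    The backbone ring carries standard N/CA/C names.  The bridge runs from
    CB of the first spanned residue through intermediate atoms to CB of the
    second, along a chord with a sinusoidal z-profile peaking at
    ``bridge_height``; a three-atom bridge is CB-SG-CB (the tryptathionine
    shape).  Gaussian noise of the requested sigma is added to every
    coordinate (seeded).
    """
    if spec is None:
        spec = FixtureSpec(**overrides)
    elif overrides:
        raise InputError("pass either a spec or keyword overrides, not both")
    rng = np.random.default_rng(spec.seed)

    coords = list(_ring_coordinates(spec))
    names = []
    elements = []
    resids = []
    residue_names = spec.residue_names or tuple(
        "GLY" for _ in range(spec.n_residues)
    )
    if len(residue_names) != spec.n_residues:
        raise InputError("one residue name per residue required")
    resnames = []
    for r in range(spec.n_residues):
        for name in ("N", "CA", "C"):
            names.append(name)
            elements.append(name[0])
            resids.append(r + 1)
            resnames.append(residue_names[r])
    n_ring = len(coords)
    bonds = [(i, (i + 1) % n_ring) for i in range(n_ring)]

    if spec.bridge_span is not None:
        res_i, res_j = spec.bridge_span
        ca_i = 3 * (res_i - 1) + 1
        ca_j = 3 * (res_j - 1) + 1
        k = spec.n_bridge_atoms
        start, end = np.asarray(coords[ca_i]), np.asarray(coords[ca_j])
        ts = np.arange(1, k + 1) / (k + 1)
        previous = ca_i
        for b, t in enumerate(ts):
            position = (1 - t) * start + t * end
            position[2] += spec.bridge_height * np.sin(np.pi * t)
            if b == 0:
                name, element, resid = "CB", "C", res_i
            elif b == k - 1:
                name, element, resid = "CB", "C", res_j
            else:
                name, element = ("SG", "S") if k == 3 and b == 1 else (f"CG{b}", "C")
                resid = res_j if name == "SG" else res_i
            index = len(coords)
            coords.append(position)
            names.append(name)
            elements.append(element)
            resids.append(resid)
            resnames.append(residue_names[resid - 1])
            bonds.append((previous, index))
            previous = index
        bonds.append((previous, ca_j))

    xyz = np.asarray(coords)
    if spec.noise > 0:
        xyz = xyz + rng.normal(0.0, spec.noise, size=xyz.shape)
    return MolecularSystem(
        elements=elements,
        names=names,
        resnames=resnames,
        resids=resids,
        coords=xyz[None],
        bonds=bonds,
    )


def make_amatoxin_like(**overrides) -> MolecularSystem:
    """Amatoxin-topology fixture: 8 residues, CB-SG-CB bridge between 4 and 8.

    Residue names follow the Ile3-amaninamide scaffold; topology perception
    finds the bridgeheads on the alpha carbons of residues 4 and 8, with
    the leading atom L = CB of residue 4.
    """
    defaults = dict(
        n_residues=8,
        bridge_span=(4, 8),
        n_bridge_atoms=3,
        residue_names=AMATOXIN_RESIDUES,
    )
    defaults.update(overrides)
    return make_bridged_macrocycle(FixtureSpec(**defaults))


def mirror(system: MolecularSystem) -> MolecularSystem:
    """Reflect all models through the z=0 plane (atom table and bonds unchanged)."""
    coords = system.coords.copy()
    coords[..., 2] *= -1.0
    return system.with_coords(coords)


def make_ensemble(
    spec: FixtureSpec | None = None,
    n_frames: int = 10,
    noise: float = 0.1,
    seed: int = 0,
    rigid_motion: bool = True,
    **overrides,
) -> Ensemble:
    """Noisy conformational ensemble of a fixture.

    Each frame is the base fixture plus i.i.d. Gaussian coordinate noise
    plus (by default) an independent uniformly random proper rotation and a
    random translation, so invariance claims are exercised honestly.
    """
    if n_frames < 1:
        raise InputError("need at least one frame")
    if noise < 0:
        raise InputError("noise sigma must be nonnegative")
    if spec is None:
        spec = FixtureSpec(**overrides)
    base_system = make_bridged_macrocycle(spec)
    base = base_system.model(0)
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, base.shape[0], 3))
    for f in range(n_frames):
        xyz = base + rng.normal(0.0, noise, size=base.shape) if noise > 0 else base.copy()
        if rigid_motion:
            rotation = Rotation.random(random_state=rng).as_matrix()
            translation = rng.uniform(-20.0, 20.0, size=3)
            xyz = xyz @ rotation.T + translation
        frames[f] = xyz
    return Ensemble(system=base_system.with_coords(frames))
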