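"""Plane fitting, inter-plane angles, bridge-side tests and superposition.

The three-plane model of a bridged bicycle fits one least-squares plane to
each ring arc (A and B) and one to the bridge, each with an *oriented*
normal: the right-hand rule applied to the ordered atom traversal (N->C
around the ring arcs, alpha -> second bridgehead along the bridge).  Angles
between oriented normals live in [0, 180] degrees and are deliberately not
folded to [0, 90] - flipping one plane over is a 180-degree event, which is
exactly what distinguishes the two ansamers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import MolecularSystem
from .errors import AmbiguousGeometryError, DegenerateGeometryError, GeometryError
from .topology import Bridge

__all__ = [
    "PlaneFit",
    "AngleTriple",
    "SuperpositionResult",
    "fit_plane",
    "plane_angle",
    "angle_triple",
    "bridge_side",
    "superpose",
]

IN_PLANE_TOLERANCE = 1e-6  # Angstrom; smaller projections are ambiguous


@dataclass
class PlaneFit:
    """Least-squares plane: centroid, oriented unit normal, RMS residual (A)."""

    centroid: np.ndarray
    normal: np.ndarray
    residual: float
    atom_indices: list | None = None


@dataclass
class AngleTriple:
    """The three pairwise plane angles (degrees): A/C, C/B and A/B."""

    theta_ac: float
    theta_cb: float
    theta_ab: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.theta_ac, self.theta_cb, self.theta_ab)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _newell_normal(points: np.ndarray) -> np.ndarray:
    """Polygon normal of an ordered traversal (closed), right-hand rule."""
    shifted = np.roll(points, -1, axis=0)
    return np.cross(points, shifted).sum(axis=0)


def fit_plane(
    points: np.ndarray,
    orient: bool = True,
    atom_indices: list | None = None,
) -> PlaneFit:
    """Fit a least-squares plane through >=3 non-collinear ordered points.

    The plane is the smallest principal axis of the centered point cloud
    (SVD).  With ``orient=True`` the normal is flipped, if necessary, to
    agree with the right-hand-rule circulation of the point order (the
    traversal is treated as a closed polygon); otherwise the sign is made
    deterministic by pointing the largest-magnitude component positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs >=3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, sing, vt = np.linalg.svd(centered, full_matrices=False)
    if sing[1] <= max(sing[0] * 1e-8, 1e-10):
        raise DegenerateGeometryError("points are (near-)collinear")
    normal = vt[2]
    residual = float(sing[2] / np.sqrt(len(pts)))
    if orient:
        reference = _newell_normal(centered)
        if np.linalg.norm(reference) < 1e-12:
            raise DegenerateGeometryError(
                "ordered traversal encloses no area; cannot orient the normal"
            )
        if float(normal @ reference) < 0:
            normal = -normal
    else:
        k = int(np.argmax(np.abs(normal)))
        if normal[k] < 0:
            normal = -normal
    normal = normal / np.linalg.norm(normal)
    return PlaneFit(
        centroid=centroid,
        normal=normal,
        residual=residual,
        atom_indices=list(atom_indices) if atom_indices is not None else None,
    )


def plane_angle(p: PlaneFit, q: PlaneFit) -> float:
    """Angle in degrees between oriented plane normals, in [0, 180]."""
    dot = float(np.clip(p.normal @ q.normal, -1.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


def angle_triple(
    coords: np.ndarray,
    segment_a: list[int],
    segment_b: list[int],
    bridge: Bridge,
) -> AngleTriple:
    """The three-plane angles of one conformer.

    Planes A and B are fitted to the backbone atoms of the two ring arcs
    (ordered N->C), plane C to the bridge path plus both bridgeheads
    (ordered alpha -> second bridgehead).
    """
    coords = np.asarray(coords, dtype=float)
    bridge_atoms = [bridge.bridgeheads[0], *bridge.path, bridge.bridgeheads[1]]
    pa = fit_plane(coords[segment_a], atom_indices=segment_a)
    pb = fit_plane(coords[segment_b], atom_indices=segment_b)
    pc = fit_plane(coords[bridge_atoms], atom_indices=bridge_atoms)
    return AngleTriple(
        theta_ac=plane_angle(pa, pc),
        theta_cb=plane_angle(pc, pb),
        theta_ab=plane_angle(pa, pb),
    )


def bridge_side(main_plane: PlaneFit, leading_position: np.ndarray) -> tuple[int, float]:
    """Which side of the main-cycle plane carries the leading atom L.

    Returns ``(sign, projection)`` where ``sign`` is +1 when L lies on the
    side the N->C right-hand-rule normal points to, -1 otherwise, and
    ``projection`` is the signed distance (A) of L from the plane.  A
    projection below 1e-6 A is ambiguous.
    """
    projection = float(
        (np.asarray(leading_position, dtype=float) - main_plane.centroid)
        @ main_plane.normal
    )
    if abs(projection) < IN_PLANE_TOLERANCE:
        raise AmbiguousGeometryError(
            f"leading atom lies in the main-cycle plane (|proj| = {abs(projection):.2e} A)"
        )
    return (1 if projection > 0 else -1), projection


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | list | None = None,
) -> SuperpositionResult:
    """Kabsch optimal rigid superposition of ``mobile`` onto ``reference``.

    The rotation/translation minimize the RMSD over the selected atoms
    (all atoms by default); the rotation is always proper (det = +1).  The
    reported RMSD is computed over the selection after the fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise GeometryError("mobile and reference must have the same shape")
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise GeometryError("superposition needs >=3 selected atoms")
    mob = mobile[sel]
    ref = reference[sel]
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    rotation = rot.as_matrix()
    translation = ref_c - rotation @ mob_c
    fitted = mob @ rotation.T + translation
    rmsd = float(np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def main_cycle_plane(system: MolecularSystem, cycle_atoms: list[int], model: int = 0) -> PlaneFit:
    """Oriented plane of the whole main cycle for one model (N->C circulation)."""
    return fit_plane(system.model(model)[cycle_atoms], atom_indices=cycle_atoms)
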