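"""Conformational-ensemble measurements for bridged cyclic peptides.

Covers the analyses used to characterize ansamer pairs: distributions of
the three inter-plane angles over an ensemble, geometric hydrogen-bond
detection with population filtering and pairwise co-occurrence, per-atom
solvent-accessible surface area (Shrake-Rupley) with amide exposure
classes, variable-temperature NMR amide slope classes, backbone dihedrals
with cis/trans amide calls, and RMSF after Kabsch superposition.

Classification thresholds (strict inequalities):

* amide SASA: < 0.02 nm^2 shielded, > 0.04 nm^2 exposed, else intermediate;
* VT-NMR amide temperature coefficient: > -3.0 ppb/K H-bonded,
  < -4.6 ppb/K exposed, else weak;
* H-bond records kept when their ensemble population exceeds 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import Ensemble, MolecularSystem
from .errors import AnsamerError, DegenerateGeometryError, GeometryError, InputError
from .geometry import AngleTriple, angle_triple, superpose
from .topology import Bridge, bond_graph

__all__ = [
    "AngleDistribution",
    "HBondRecord",
    "AmideExposure",
    "VTSlopeClass",
    "DihedralRecord",
    "VDW_RADII",
    "SASA_SHIELDED_NM2",
    "SASA_EXPOSED_NM2",
    "VT_HBONDED_PPB_PER_K",
    "VT_EXPOSED_PPB_PER_K",
    "HBOND_MIN_POPULATION",
    "angle_distributions",
    "detect_hbonds",
    "hbond_populations",
    "filter_populations",
    "hbond_cooccurrence",
    "sasa",
    "amide_sasa",
    "classify_amide_exposure",
    "classify_vt_slope",
    "dihedral",
    "backbone_dihedrals",
    "rmsf",
]

# Bondi van der Waals radii (Angstrom).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Se": 1.90,
}

SASA_SHIELDED_NM2 = 0.02
SASA_EXPOSED_NM2 = 0.04
VT_HBONDED_PPB_PER_K = -3.0
VT_EXPOSED_PPB_PER_K = -4.6
HBOND_MIN_POPULATION = 0.10
HBOND_DMAX = 3.5  # donor-acceptor distance, Angstrom
HBOND_ANGLE_MIN = 120.0  # D-H...A angle, degrees
ANGSTROM2_TO_NM2 = 0.01


@dataclass
class AngleDistribution:
    """Normalized histogram of one inter-plane angle over an ensemble."""

    label: str
    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_frames_used: int
    n_frames_skipped: int = 0


@dataclass
class HBondRecord:
    """One donor->acceptor hydrogen bond and its per-frame presence."""

    donor: int
    hydrogen: int
    acceptor: int
    presence: np.ndarray
    population: float


@dataclass
class AmideExposure:
    residue: int
    mean_sasa_nm2: float
    exposure_class: str


@dataclass
class VTSlopeClass:
    residue: int
    slope_ppb_per_k: float
    slope_class: str


@dataclass
class DihedralRecord:
    residue: int
    phi: float
    psi: float
    omega: float
    omega_class: str


# --------------------------------------------------------------------------
# inter-plane angle distributions


def angle_distributions(
    ensemble: Ensemble,
    segment_a: list[int],
    segment_b: list[int],
    bridge: Bridge,
    bin_width: float = 5.0,
) -> tuple[dict[str, AngleDistribution], list[AngleTriple | None]]:
    """Histogram the three plane angles over all frames (default 5-degree bins).

    Frames with degenerate geometry are skipped with a warning and counted
    in the returned distributions.  Also returns the raw per-frame
    :class:`~ansamer.geometry.AngleTriple` list (``None`` for skipped
    frames).
    """
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    if edges[-1] < 180.0:
        edges = np.append(edges, 180.0)
    triples: list[AngleTriple | None] = []
    skipped = 0
    for i in range(ensemble.n_frames):
        try:
            triples.append(
                angle_triple(ensemble.frame(i), segment_a, segment_b, bridge)
            )
        except DegenerateGeometryError as exc:
            warnings.warn(f"frame {i} skipped: {exc}", stacklevel=2)
            triples.append(None)
            skipped += 1
    used = [t for t in triples if t is not None]
    if not used:
        raise GeometryError("no frame yielded a valid angle triple")
    labels = ["theta_AC", "theta_CB", "theta_AB"]
    out = {}
    for k, label in enumerate(labels):
        values = np.array([t.as_tuple()[k] for t in used])
        counts, _ = np.histogram(values, bins=edges)
        out[label] = AngleDistribution(
            label=label,
            bin_edges=edges,
            frequencies=counts / len(used),
            n_frames_used=len(used),
            n_frames_skipped=skipped,
        )
    return out, triples


# --------------------------------------------------------------------------
# hydrogen bonds


def _donor_hydrogens(system: MolecularSystem, coords, donor: int, graph):
    """Explicit bonded hydrogens of a donor, or one implicit amide H.

    The implicit H is placed 1.01 A from N along the outward bisector of
    its two heavy-atom neighbors (the standard planar sp2 amide geometry);
    used when the structure carries no hydrogens.
    """
    hydrogens = [
        (n, coords[n])
        for n in graph.neighbors(donor)
        if str(system.elements[n]) == "H"
    ]
    if hydrogens:
        return hydrogens
    heavy = [n for n in graph.neighbors(donor) if str(system.elements[n]) != "H"]
    if len(heavy) != 2:
        return []
    u1 = coords[heavy[0]] - coords[donor]
    u2 = coords[heavy[1]] - coords[donor]
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    bisector = -(u1 + u2)
    norm = np.linalg.norm(bisector)
    if norm < 1e-9:
        return []
    return [(-1, coords[donor] + 1.01 * bisector / norm)]


def detect_hbonds(
    system: MolecularSystem,
    model: int = 0,
    donors: list[int] | None = None,
    acceptors: list[int] | None = None,
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> set[tuple[int, int, int]]:
    """Geometric H-bond detection on one frame.

    A bond is recorded when the donor-acceptor distance is at most
    ``d_max`` (default 3.5 A) and the D-H...A angle is at least
    ``angle_min`` (default 120 degrees).  Donors default to all nitrogen
    atoms, acceptors to all oxygen atoms; hydrogens are taken from the bond
    list, or placed implicitly on two-coordinate amide nitrogens.  Returned
    tuples are ``(donor, hydrogen, acceptor)`` with hydrogen = -1 when
    implicit.
    """
    coords = system.model(model)
    graph = bond_graph(system)
    if donors is None:
        donors = [i for i in range(system.n_atoms) if str(system.elements[i]) == "N"]
    if acceptors is None:
        acceptors = [i for i in range(system.n_atoms) if str(system.elements[i]) == "O"]
    found = set()
    for donor in donors:
        hydrogens = _donor_hydrogens(system, coords, donor, graph)
        if not hydrogens:
            continue
        for acceptor in acceptors:
            if acceptor == donor or graph.has_edge(donor, acceptor):
                continue
            if np.linalg.norm(coords[acceptor] - coords[donor]) > d_max:
                continue
            for h_idx, h_pos in hydrogens:
                if h_idx == acceptor:
                    continue
                v1 = coords[donor] - h_pos
                v2 = coords[acceptor] - h_pos
                cos = float(
                    v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
                if angle >= angle_min:
                    found.add((int(donor), int(h_idx), int(acceptor)))
                    break
    return found


def hbond_populations(
    ensemble: Ensemble,
    donors: list[int] | None = None,
    acceptors: list[int] | None = None,
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
    min_population: float = HBOND_MIN_POPULATION,
) -> list[HBondRecord]:
    """Per-ensemble H-bond populations, filtered at ``population > min_population``.

    The filter is a strict inequality: a bond present in exactly 10% of the
    frames is dropped at the default threshold.  Populations are
    weight-averaged presence fractions (uniform weights by default).
    """
    per_frame = [
        detect_hbonds(
            ensemble.system,
            model=i,
            donors=donors,
            acceptors=acceptors,
            d_max=d_max,
            angle_min=angle_min,
        )
        for i in range(ensemble.n_frames)
    ]
    keys = sorted({(d, a) for frame in per_frame for (d, _h, a) in frame})
    records = []
    for donor, acceptor in keys:
        presence = np.array(
            [
                any(d == donor and a == acceptor for (d, _h, a) in frame)
                for frame in per_frame
            ]
        )
        hydrogen = next(
            h
            for frame in per_frame
            for (d, h, a) in frame
            if d == donor and a == acceptor
        )
        records.append(
            HBondRecord(
                donor=donor,
                hydrogen=hydrogen,
                acceptor=acceptor,
                presence=presence,
                population=float(presence @ ensemble.weights),
            )
        )
    return filter_populations(records, min_population)


def filter_populations(
    records: list[HBondRecord], min_population: float
) -> list[HBondRecord]:
    """Keep records with population strictly above the threshold."""
    return [r for r in records if r.population > min_population]


def hbond_cooccurrence(records: list[HBondRecord]) -> np.ndarray:
    """Pairwise Pearson phi matrix of H-bond presence bits.

    Symmetric, entries in [-1, 1]; mutually exclusive bonds come out
    negative.  Bonds with zero variance (always or never present) yield
    NaN rows/columns, reported as missing rather than fabricated.
    """
    if len(records) < 2:
        raise InputError("co-occurrence needs at least two H-bond records")
    bits = np.array([r.presence.astype(float) for r in records])
    if bits.shape[1] < 2:
        raise InputError("co-occurrence needs at least two frames")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = np.corrcoef(bits)
    variances = bits.var(axis=1)
    matrix[variances == 0, :] = np.nan
    matrix[:, variances == 0] = np.nan
    np.fill_diagonal(matrix, np.where(variances == 0, np.nan, 1.0))
    return matrix


# --------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    coords: np.ndarray,
    elements,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Angstrom^2 (Shrake-Rupley).

    Each atom's van der Waals sphere is inflated by the probe radius and
    sampled with a deterministic golden-spiral point grid; a point is
    accessible when it lies outside every neighbor's inflated sphere.
    """
    coords = np.asarray(coords, dtype=float)
    table = VDW_RADII if radii is None else radii
    try:
        r = np.array([table[str(el)] for el in elements]) + probe_radius
    except KeyError as exc:
        raise AnsamerError(f"no van der Waals radius for element {exc}") from None
    sphere = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    out = np.zeros(len(coords))
    r_max = r.max()
    for i in range(len(coords)):
        neighbors = [
            j for j in tree.query_ball_point(coords[i], r[i] + r_max) if j != i
        ]
        points = coords[i] + r[i] * sphere
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(points - coords[j], axis=1)
            accessible &= d >= r[j]
        out[i] = 4.0 * np.pi * r[i] ** 2 * accessible.mean()
    return out


def amide_sasa(
    ensemble: Ensemble,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> list[AmideExposure]:
    """Mean per-residue amide SASA over the ensemble, classified in nm^2.

    The amide group area is the sum over the backbone nitrogen and its
    bonded hydrogens.  Angstrom^2 values are converted with the exact
    factor 0.01 A^2/nm^2 at the classification boundary.
    """
    system = ensemble.system
    graph = bond_graph(system)
    amide_atoms: dict[int, list[int]] = {}
    for i in range(system.n_atoms):
        if str(system.names[i]) == "N":
            members = [i] + [
                n for n in graph.neighbors(i) if str(system.elements[n]) == "H"
            ]
            amide_atoms[int(system.resids[i])] = members
    totals = {res: 0.0 for res in amide_atoms}
    for f in range(ensemble.n_frames):
        areas = sasa(
            ensemble.frame(f),
            system.elements,
            probe_radius=probe_radius,
            n_sphere_points=n_sphere_points,
        )
        for res, members in amide_atoms.items():
            totals[res] += ensemble.weights[f] * areas[members].sum()
    return [
        AmideExposure(
            residue=res,
            mean_sasa_nm2=totals[res] * ANGSTROM2_TO_NM2,
            exposure_class=classify_amide_exposure(totals[res] * ANGSTROM2_TO_NM2),
        )
        for res in sorted(totals)
    ]


def classify_amide_exposure(mean_sasa_nm2: float) -> str:
    """Amide exposure class from its mean SASA in nm^2 (strict bounds)."""
    if mean_sasa_nm2 < 0:
        raise InputError("SASA cannot be negative")
    if mean_sasa_nm2 < SASA_SHIELDED_NM2:
        return "shielded"
    if mean_sasa_nm2 > SASA_EXPOSED_NM2:
        return "exposed"
    return "intermediate"


def classify_vt_slope(slope_ppb_per_k: float) -> str:
    """Amide class from its VT-NMR temperature coefficient (ppb/K)."""
    if not np.isfinite(slope_ppb_per_k):
        raise InputError("VT slope must be finite")
    if slope_ppb_per_k > VT_HBONDED_PPB_PER_K:
        return "H-bonded"
    if slope_ppb_per_k < VT_EXPOSED_PPB_PER_K:
        return "exposed"
    return "weak"


# --------------------------------------------------------------------------
# dihedrals


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    # project the outer bonds onto the plane perpendicular to the axis;
    # IUPAC sign: positive = clockwise looking from p1 toward p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    angle = float(np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w)))
    return 180.0 if np.isclose(angle, -180.0) else angle


def backbone_dihedrals(
    system: MolecularSystem,
    model: int = 0,
    cyclic: bool = True,
) -> list[DihedralRecord]:
    """Phi/psi/omega per residue with cis/trans amide classification.

    phi = C'(i-1)-N(i)-CA(i)-C'(i), psi = N(i)-CA(i)-C'(i)-N(i+1),
    omega = CA(i-1)-C'(i-1)-N(i)-CA(i).  For head-to-tail cycles the
    neighbors wrap around.  |omega| <= 90 degrees is called cis, otherwise
    trans.  Residues with missing backbone atoms are skipped with a warning.
    """
    coords = system.model(model)
    atom_of: dict[tuple[int, str], int] = {}
    for i in range(system.n_atoms):
        atom_of.setdefault((int(system.resids[i]), str(system.names[i])), i)
    residues = sorted({int(r) for r in system.resids})
    records = []
    for k, res in enumerate(residues):
        prev_res = residues[k - 1] if (k > 0 or cyclic) else None
        next_res = (
            residues[(k + 1) % len(residues)]
            if (k + 1 < len(residues) or cyclic)
            else None
        )
        needed = {
            "N": (res, "N"),
            "CA": (res, "CA"),
            "C": (res, "C"),
        }
        try:
            n_i = atom_of[needed["N"]]
            ca_i = atom_of[needed["CA"]]
            c_i = atom_of[needed["C"]]
            c_prev = atom_of[(prev_res, "C")] if prev_res is not None else None
            ca_prev = atom_of[(prev_res, "CA")] if prev_res is not None else None
            n_next = atom_of[(next_res, "N")] if next_res is not None else None
        except KeyError as exc:
            warnings.warn(f"residue {res}: missing backbone atom {exc}", stacklevel=2)
            continue
        if c_prev is None or n_next is None or ca_prev is None:
            warnings.warn(
                f"residue {res}: chain terminus, dihedrals undefined", stacklevel=2
            )
            continue
        phi = dihedral(coords[c_prev], coords[n_i], coords[ca_i], coords[c_i])
        psi = dihedral(coords[n_i], coords[ca_i], coords[c_i], coords[n_next])
        omega = dihedral(coords[ca_prev], coords[c_prev], coords[n_i], coords[ca_i])
        records.append(
            DihedralRecord(
                residue=res,
                phi=phi,
                psi=psi,
                omega=omega,
                omega_class="cis" if abs(omega) <= 90.0 else "trans",
            )
        )
    return records


# --------------------------------------------------------------------------
# RMSF


def rmsf(
    ensemble: Ensemble,
    reference: int = 0,
    selection: np.ndarray | list | None = None,
    fit_selection: np.ndarray | list | None = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Angstrom) after superposition.

    Every frame is first Kabsch-fitted onto the reference frame using
    ``fit_selection`` (all atoms by default; pass backbone indices to
    reproduce a backbone fit), then RMSF_i = sqrt(mean_t |x_i(t) -
    <x_i>|^2) is computed over ``selection`` (default all atoms).
    """
    if ensemble.n_frames < 2:
        raise InputError("RMSF needs at least two frames")
    ref = ensemble.frame(reference)
    fitted = np.empty_like(ensemble.system.coords)
    for i in range(ensemble.n_frames):
        result = superpose(ensemble.frame(i), ref, selection=fit_selection)
        fitted[i] = result.apply(ensemble.frame(i))
    sel = (
        np.arange(ensemble.system.n_atoms)
        if selection is None
        else np.asarray(selection)
    )
    sub = fitted[:, sel, :]
    mean = sub.mean(axis=0)
    return np.sqrt(((sub - mean) ** 2).sum(axis=2).mean(axis=0))
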