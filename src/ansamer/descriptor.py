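"""Ansamer stereodescriptor assignment (P_ansa / M_ansa).

A bridged macrolactam has two configurations distinguished by which face of
the main ring carries the bridge.  The assignment follows four steps:

1. find the main cycle and orient it N->C (``topology.find_main_cycle``);
2. find the bridge, its first bridgehead alpha and leading atom L
   (``topology.find_bridge``);
3. determine the sense (clockwise / counter-clockwise) in which the N->C
   traversal appears when the ring is viewed from L;
4. map that sense to the descriptor.

Step 3 is computed as the sign of the projection of L onto the oriented
main-cycle plane normal: the normal follows the right-hand rule for the
N->C circulation, so L on the normal side (+1) sees the traversal
counter-clockwise and L on the opposite side (-1) sees it clockwise.

The clockwise sense maps to P_ansa (P = plus = right-handed, as in
helicity nomenclature); this calibration is a single module constant
(:data:`DESCRIPTOR_FOR_POSITIVE_SIDE`), so recalibrating against a
reference crystal structure flips one sign, not the code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core import Ensemble, MolecularSystem
from .errors import AmbiguousGeometryError, DegenerateGeometryError
from .geometry import fit_plane
from .topology import (
    BACKBONE_NAMES,
    Bridge,
    MainCycle,
    find_bridge,
    find_main_cycle,
    perceive_bonds,
)

__all__ = [
    "P_ANSA",
    "M_ANSA",
    "DESCRIPTOR_FOR_POSITIVE_SIDE",
    "AnsamerAssignment",
    "EnsembleAssignment",
    "flip",
    "assign_ansamer",
    "assign_ensemble",
]

P_ANSA = "P_ansa"
M_ANSA = "M_ansa"

#: Descriptor assigned when L lies on the side the N->C right-hand-rule
#: normal points to (counter-clockwise traversal seen from L).  The single
#: calibration point of the sign convention.
DESCRIPTOR_FOR_POSITIVE_SIDE = M_ANSA


def flip(descriptor: str) -> str:
    """Exchange P_ansa <-> M_ansa (an involution)."""
    if descriptor == P_ANSA:
        return M_ANSA
    if descriptor == M_ANSA:
        return P_ANSA
    raise ValueError(f"not an ansamer descriptor: {descriptor!r}")


@dataclass
class AnsamerAssignment:
    """Descriptor plus the diagnostics needed to audit the call."""

    descriptor: str
    alpha: int
    leading: int
    side: int
    main_cycle_size: int
    plane_residual: float
    projection: float


@dataclass
class EnsembleAssignment:
    """Per-frame descriptors of an ensemble and whether they are constant."""

    descriptors: list
    constant: bool
    n_ambiguous: int


def _topology(system: MolecularSystem, backbone_names) -> tuple[MainCycle, Bridge]:
    if not system.bonds:
        system = perceive_bonds(system)
    cycle = find_main_cycle(system, backbone_names=backbone_names)
    bridge = find_bridge(system, cycle)
    return cycle, bridge


def assign_ansamer(
    system: MolecularSystem,
    model: int = 0,
    backbone_names: tuple[str, str, str] = BACKBONE_NAMES,
    _topo: tuple[MainCycle, Bridge] | None = None,
) -> AnsamerAssignment:
    """Assign P_ansa or M_ansa to one model of a bridged macrolactam.

    Raises the topology errors of :mod:`ansamer.topology` when the molecule
    is not a single-bridge macrolactam, and
    :class:`~ansamer.errors.AmbiguousGeometryError` when the leading atom
    lies in the mean ring plane.
    """
    cycle, bridge = _topo if _topo is not None else _topology(system, backbone_names)
    coords = system.model(model)
    plane = fit_plane(coords[cycle.atoms], atom_indices=cycle.atoms)
    projection = float((coords[bridge.leading] - plane.centroid) @ plane.normal)
    if abs(projection) < 1e-6:
        raise AmbiguousGeometryError(
            "leading atom lies in the main-cycle plane; descriptor ambiguous"
        )
    side = 1 if projection > 0 else -1
    descriptor = (
        DESCRIPTOR_FOR_POSITIVE_SIDE if side > 0 else flip(DESCRIPTOR_FOR_POSITIVE_SIDE)
    )
    return AnsamerAssignment(
        descriptor=descriptor,
        alpha=bridge.alpha,
        leading=bridge.leading,
        side=side,
        main_cycle_size=cycle.size,
        plane_residual=plane.residual,
        projection=projection,
    )


def assign_ensemble(
    ensemble: Ensemble,
    backbone_names: tuple[str, str, str] = BACKBONE_NAMES,
) -> EnsembleAssignment:
    """Descriptor per frame, plus a constancy flag.

    Frames with ambiguous or degenerate geometry get ``None`` and are
    excluded from the constancy vote (a warning is emitted).  The flag is
    true iff all assignable frames agree.
    """
    topo = _topology(ensemble.system, backbone_names)
    descriptors: list = []
    n_ambiguous = 0
    for i in range(ensemble.n_frames):
        try:
            result = assign_ansamer(
                ensemble.system, model=i, backbone_names=backbone_names, _topo=topo
            )
            descriptors.append(result.descriptor)
        except (AmbiguousGeometryError, DegenerateGeometryError) as exc:
            warnings.warn(f"frame {i}: {exc}", stacklevel=2)
            descriptors.append(None)
            n_ambiguous += 1
    assigned = [d for d in descriptors if d is not None]
    constant = bool(assigned) and len(set(assigned)) == 1
    return EnsembleAssignment(
        descriptors=descriptors, constant=constant, n_ambiguous=n_ambiguous
    )
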