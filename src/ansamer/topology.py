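"""Bond perception and bridged-macrolactam topology.

The ansamer descriptor needs three topological facts about a bridged cyclic
peptide: the main macrolactam cycle (the head-to-tail backbone ring) with
its N->C traversal direction, the bridge (the side-chain cross-link arc)
with its two bridgehead atoms on the cycle, and the two main-cycle arcs the
bridgeheads delimit.  All of it is pure graph work on the covalent bond
list, done here with NetworkX.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .core import MolecularSystem
from .errors import (
    AmbiguousCycleError,
    MonocycleError,
    MultiBridgeError,
    NotMacrolactamError,
    TopologyError,
)

__all__ = [
    "COVALENT_RADII",
    "BACKBONE_NAMES",
    "MainCycle",
    "Bridge",
    "perceive_bonds",
    "bond_graph",
    "find_main_cycle",
    "find_bridge",
    "split_segments",
]

# Single-bond covalent radii (Angstrom), Cordero et al. 2008 values for the
# elements that occur in peptides and common cross-links.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Ca": 1.76,
    "Fe": 1.32,
    "Zn": 1.22,
    "Se": 1.20,
    "Br": 1.20,
    "I": 1.39,
}

#: Atom names treated as peptide backbone (amide N, alpha carbon, carbonyl C').
BACKBONE_NAMES: tuple[str, ...] = ("N", "CA", "C")

BOND_TOLERANCE = 1.15  # bonded iff d <= (r_i + r_j) * BOND_TOLERANCE


@dataclass
class MainCycle:
    """Ordered macrolactam backbone ring, traversed N->C.

    ``atoms`` starts at the amide N of the lowest-index residue and repeats
    the N, CA, C' pattern once per member residue.
    """

    atoms: list[int]
    residues: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.atoms)

    def position(self, atom: int) -> int:
        return self.atoms.index(atom)


@dataclass
class Bridge:
    """Side-chain cross-link between two main-cycle bridgeheads.

    ``alpha`` is the bridgehead reached first when walking the main cycle
    N->C from its start atom; ``leading`` (the atom L) is the unique bridge
    atom bonded to it.  ``path`` runs from L to the atom bonded to the
    other bridgehead and contains no main-cycle atoms.
    """

    bridgeheads: tuple[int, int]
    path: list[int]
    alpha: int
    leading: int


def bond_graph(system: MolecularSystem) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(range(system.n_atoms))
    graph.add_edges_from(system.bonds)
    return graph


def perceive_bonds(system: MolecularSystem, model: int = 0) -> MolecularSystem:
    """Return a copy of ``system`` with distance-based bonds added.

    Atoms i, j are bonded iff their distance in the given model is at most
    1.15x the sum of their covalent radii.  Bonds already present (e.g.
    from CONECT records) are kept.
    """
    radii = []
    for el in system.elements:
        try:
            radii.append(COVALENT_RADII[str(el)])
        except KeyError:
            raise TopologyError(f"no covalent radius for element {el!r}") from None
    radii = np.asarray(radii)
    xyz = system.model(model)
    dist = cdist(xyz, xyz)
    cutoff = (radii[:, None] + radii[None, :]) * BOND_TOLERANCE
    ii, jj = np.nonzero((dist <= cutoff) & (dist > 0.4))
    new_bonds = list(system.bonds) + [(int(i), int(j)) for i, j in zip(ii, jj) if i < j]
    out = system.copy()
    out.bonds = sorted(set((min(i, j), max(i, j)) for i, j in new_bonds))
    return out


def _backbone_cycles(system, graph, backbone_names):
    mask = [str(n) in backbone_names for n in system.names]
    sub = graph.subgraph([i for i, keep in enumerate(mask) if keep])
    return [c for c in nx.simple_cycles(sub) if len(c) >= 3]


def _orient_cycle(system, graph, cycle_atoms, backbone_names) -> MainCycle:
    """Order a backbone cycle N->C starting at the lowest-residue amide N."""
    cycle_set = set(cycle_atoms)
    adjacency = {a: [b for b in graph.neighbors(a) if b in cycle_set] for a in cycle_atoms}
    if any(len(v) != 2 for v in adjacency.values()):
        raise NotMacrolactamError("backbone cycle is not a simple ring")
    n_name, ca_name, c_name = backbone_names
    starts = [a for a in cycle_atoms if str(system.names[a]) == n_name]
    if not starts:
        raise NotMacrolactamError("cycle contains no amide nitrogen")
    start = min(starts, key=lambda a: (int(system.resids[a]), a))
    nxt = [
        b
        for b in adjacency[start]
        if str(system.names[b]) == ca_name and system.resids[b] == system.resids[start]
    ]
    if len(nxt) != 1:
        raise NotMacrolactamError("cannot orient cycle N->C at the start residue")
    ordered = [start, nxt[0]]
    while len(ordered) < len(cycle_atoms):
        prev, cur = ordered[-2], ordered[-1]
        succ = [b for b in adjacency[cur] if b != prev]
        if len(succ) != 1:
            raise NotMacrolactamError("backbone cycle is not a simple ring")
        ordered.append(succ[0])
    pattern = [n_name, ca_name, c_name]
    for k, atom in enumerate(ordered):
        if str(system.names[atom]) != pattern[k % 3]:
            raise NotMacrolactamError(
                "backbone ring does not follow the N-CA-C' repeat"
            )
    residues = sorted({int(system.resids[a]) for a in ordered})
    return MainCycle(atoms=ordered, residues=residues)


def find_main_cycle(
    system: MolecularSystem,
    backbone_names: tuple[str, str, str] = BACKBONE_NAMES,
) -> MainCycle:
    """Find the macrolactam: the largest all-backbone simple cycle, oriented N->C.

    Equal-size candidates are ranked by their sorted residue-index tuple;
    genuinely distinct candidates that tie on both counts raise
    :class:`AmbiguousCycleError`.
    """
    graph = bond_graph(system)
    cycles = _backbone_cycles(system, graph, backbone_names)
    if not cycles:
        raise NotMacrolactamError("no backbone cycle found: not a macrolactam")
    best_len = max(len(c) for c in cycles)
    candidates = {frozenset(c) for c in cycles if len(c) == best_len}
    if len(candidates) > 1:
        keyed = sorted(
            candidates,
            key=lambda cand: tuple(sorted(int(system.resids[a]) for a in cand)),
        )
        key0 = tuple(sorted(int(system.resids[a]) for a in keyed[0]))
        key1 = tuple(sorted(int(system.resids[a]) for a in keyed[1]))
        if key0 == key1:
            raise AmbiguousCycleError(
                f"{len(candidates)} equal-size main-cycle candidates: "
                + "; ".join(str(sorted(c)) for c in candidates)
            )
        chosen = keyed[0]
    else:
        chosen = next(iter(candidates))
    return _orient_cycle(system, graph, sorted(chosen), backbone_names)


def find_bridge(system: MolecularSystem, main_cycle: MainCycle) -> Bridge:
    """Locate the single side-chain cross-link over the main cycle.

    A bridge is a connected component of non-cycle atoms attached to exactly
    two distinct cycle atoms.  Dangling side chains (one attachment) are
    ignored.  No bridge raises :class:`MonocycleError`; more than one, or a
    component touching >2 cycle atoms, raises :class:`MultiBridgeError`.
    """
    graph = bond_graph(system)
    cycle_set = set(main_cycle.atoms)
    rest = graph.subgraph([a for a in graph.nodes if a not in cycle_set])
    candidates = []
    for comp in nx.connected_components(rest):
        attach = {
            c
            for a in comp
            for c in graph.neighbors(a)
            if c in cycle_set
        }
        if len(attach) == 2:
            candidates.append((set(comp), attach))
        elif len(attach) > 2:
            raise MultiBridgeError(
                "bridge component attaches to more than two main-cycle atoms"
            )
    if not candidates:
        raise MonocycleError("no bridge found: monocycle, descriptor undefined")
    if len(candidates) > 1:
        raise MultiBridgeError(f"{len(candidates)} independent bridges found")

    comp, attach = candidates[0]
    first, second = sorted(attach, key=main_cycle.position)
    alpha, other = first, second
    ends_alpha = [a for a in comp if graph.has_edge(a, alpha)]
    ends_other = [a for a in comp if graph.has_edge(a, other)]
    if len(ends_alpha) != 1:
        raise MultiBridgeError(
            "bridgehead carries more than one bridge substituent; "
            "leading atom undefined"
        )
    sub = graph.subgraph(comp)
    path = nx.shortest_path(sub, ends_alpha[0], ends_other[0])
    return Bridge(
        bridgeheads=(alpha, other),
        path=[int(a) for a in path],
        alpha=int(alpha),
        leading=int(ends_alpha[0]),
    )


def split_segments(
    main_cycle: MainCycle, bridge: Bridge
) -> tuple[list[int], list[int]]:
    """Split the main cycle at the bridgeheads into the two ring arcs.

    Both arcs include both bridgeheads and are listed in N->C order.
    Segment A is the arc entered immediately after the first bridgehead
    (alpha) in N->C traversal; segment B is the complementary arc.
    """
    atoms = main_cycle.atoms
    i = main_cycle.position(bridge.bridgeheads[0])
    j = main_cycle.position(bridge.bridgeheads[1])
    seg_a = atoms[i : j + 1]
    seg_b = atoms[j:] + atoms[: i + 1]
    return seg_a, seg_b
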