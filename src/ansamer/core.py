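"""Core in-memory containers: :class:`MolecularSystem` and :class:`Ensemble`.

A :class:`MolecularSystem` is a flat atom table (element, PDB-style atom
name, residue name/index) shared by one or more coordinate models, plus an
explicit covalent bond list.  Coordinates are in Angstrom throughout the
package.  An :class:`Ensemble` interprets the models of a system as frames
of a conformational ensemble with (by default uniform) statistical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["MolecularSystem", "Ensemble"]


def _normalize_bonds(bonds, n_atoms: int) -> list[tuple[int, int]]:
    out = set()
    for i, j in bonds:
        i, j = int(i), int(j)
        if i == j:
            raise InputError(f"self-bond on atom {i}")
        if not (0 <= i < n_atoms and 0 <= j < n_atoms):
            raise InputError(f"bond ({i},{j}) references a missing atom")
        out.add((min(i, j), max(i, j)))
    return sorted(out)


@dataclass
class MolecularSystem:
    """Atom table + bonds + one or more coordinate models.

    Parameters
    ----------
    elements, names, resnames : array-like of str, length ``n_atoms``
    resids : array-like of int, length ``n_atoms``
    coords : array of shape ``(n_models, n_atoms, 3)`` in Angstrom
    bonds : iterable of atom-index pairs (0-based)
    serials : optional original file serial numbers (for reporting only)
    """

    elements: np.ndarray
    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    coords: np.ndarray
    bonds: list = field(default_factory=list)
    serials: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must have shape (n_models, n_atoms, 3)")
        n = self.coords.shape[1]
        if n == 0:
            raise InputError("system has no atoms")
        for arr, what in [
            (self.elements, "elements"),
            (self.names, "names"),
            (self.resnames, "resnames"),
            (self.resids, "resids"),
        ]:
            if len(arr) != n:
                raise InputError(f"{what} length {len(arr)} != atom count {n}")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates")
        self.bonds = _normalize_bonds(self.bonds, n)
        if self.serials is None:
            self.serials = np.arange(1, n + 1)
        else:
            self.serials = np.asarray(self.serials, dtype=int)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def model(self, index: int = 0) -> np.ndarray:
        """Coordinates of one model, shape ``(n_atoms, 3)``."""
        return self.coords[index]

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        """Same atom table and bonds with replaced coordinates."""
        return MolecularSystem(
            elements=self.elements.copy(),
            names=self.names.copy(),
            resnames=self.resnames.copy(),
            resids=self.resids.copy(),
            coords=np.asarray(coords, dtype=float).copy(),
            bonds=list(self.bonds),
            serials=self.serials.copy(),
        )

    def copy(self) -> "MolecularSystem":
        return self.with_coords(self.coords)


@dataclass
class Ensemble:
    """A conformational ensemble: the models of ``system`` are the frames."""

    system: MolecularSystem
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.system.n_models < 1:
            raise InputError("ensemble needs at least one frame")
        n = self.system.n_models
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != n:
                raise InputError("one weight per frame required")
            if np.any(self.weights < 0):
                raise InputError("frame weights must be nonnegative")
            total = self.weights.sum()
            if not np.isclose(total, 1.0):
                raise InputError("frame weights must sum to 1")

    @property
    def n_frames(self) -> int:
        return self.system.n_models

    def frame(self, index: int) -> np.ndarray:
        return self.system.model(index)
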