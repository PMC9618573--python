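"""Reading and writing structure files and analysis reports.

PDB files (ATOM/HETATM/MODEL/ENDMDL/CONECT records, wwPDB v3.3 fixed
columns) are parsed with MDAnalysis; multi-model files become multi-model
:class:`~ansamer.core.MolecularSystem` objects and CONECT records become
bonds.  Plain XYZ (single- or multi-frame) is accepted for toy systems.
Internally everything is Angstrom and 0-based atom indices; original PDB
serial numbers are kept for reporting.
"""

from __future__ import annotations

import dataclasses
import io
import json
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .core import Ensemble, MolecularSystem
from .errors import FormatError, InputError

__all__ = [
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_report",
]

# Fallback when the PDB element column (77-78) is blank: strip digits and
# take the leading letter(s); two-letter symbols that actually occur in
# peptide work are recognized explicitly, everything else maps to its first
# letter (so "CA" -> C, "SG" -> S via the name's first character).
_TWO_LETTER = {"CL", "BR", "SE", "NA", "MG", "ZN", "FE", "MN", "CU"}


def _element_from_name(name: str) -> str:
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if stripped[:2].upper() in _TWO_LETTER:
        sym = stripped[:2]
        return sym[0].upper() + sym[1].lower()
    return stripped[0].upper()


def _is_path(source) -> bool:
    if isinstance(source, (Path, os.PathLike)):
        return True
    return isinstance(source, str) and "\n" not in source and len(source) < 4096


def _source_text(source) -> str:
    if isinstance(source, str) and not source.strip():
        raise InputError("empty input")
    if _is_path(source):
        p = Path(source)
        if not p.is_file():
            raise InputError(f"no such file: {p}")
        return p.read_text()
    return str(source)


def _validate_pdb_models(text: str) -> None:
    """Reject multi-model PDB text whose models differ in atom count."""
    counts, current, in_model, seen_model = [], 0, False, False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            seen_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if seen_model and in_model:  # MODEL without ENDMDL
        counts.append(current)
    if not seen_model:
        counts = [current]
    if sum(counts) == 0:
        raise InputError("no atoms found in input")
    if len(set(counts)) > 1:
        raise FormatError(f"models have inconsistent atom counts: {counts}")


def _validate_xyz(text: str) -> None:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InputError("no atoms found in input")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError("XYZ file must start with an atom count") from None
    if n <= 0:
        raise InputError("no atoms found in input")


def read_structure(source, format: str | None = None) -> MolecularSystem:
    """Read a PDB or XYZ file (path or literal text) into a MolecularSystem.

    ``format`` is inferred from the file suffix when omitted; literal text
    requires it.  Multi-model PDB yields one model per MODEL block and
    CONECT records populate the bond list.
    """
    import MDAnalysis as mda

    if format is None:
        if _is_path(source):
            format = Path(source).suffix.lstrip(".").lower()
        else:
            raise InputError("format must be given for literal text input")
    format = format.lower()
    if format not in ("pdb", "xyz"):
        raise InputError(f"unsupported format {format!r} (pdb or xyz)")

    text = _source_text(source)
    if format == "pdb":
        _validate_pdb_models(text)
    else:
        _validate_xyz(text)

    with tempfile.NamedTemporaryFile(
        "w", suffix=f".{format}", delete=False
    ) as handle:
        handle.write(text)
        tmp = handle.name
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                universe = mda.Universe(tmp)
            except Exception as exc:  # noqa: BLE001 - normalize parser errors
                raise FormatError(f"cannot parse {format} input: {exc}") from exc
            atoms = universe.atoms
            if len(atoms) == 0:
                raise InputError("no atoms found in input")
            names = [str(n) for n in atoms.names]
            try:
                elements = [str(e) for e in atoms.elements]
            except Exception:  # noqa: BLE001 - element column absent
                elements = [""] * len(atoms)
            elements = [
                el.capitalize() if el.strip() else _element_from_name(nm)
                for el, nm in zip(elements, names)
            ]
            if format == "xyz":
                resnames = ["MOL"] * len(atoms)
                resids = [1] * len(atoms)
                serials = list(range(1, len(atoms) + 1))
            else:
                resnames = [str(r) for r in atoms.resnames]
                resids = [int(r) for r in atoms.resids]
                try:
                    serials = [int(i) for i in atoms.ids]
                except Exception:  # noqa: BLE001
                    serials = list(range(1, len(atoms) + 1))
            coords = np.stack(
                [atoms.positions.astype(float).copy() for _ in universe.trajectory]
            )
            try:
                bonds = [tuple(map(int, b)) for b in universe.bonds.indices]
            except Exception:  # noqa: BLE001 - no CONECT records
                bonds = []
    finally:
        os.unlink(tmp)

    return MolecularSystem(
        elements=elements,
        names=names,
        resnames=resnames,
        resids=resids,
        coords=coords,
        bonds=bonds,
        serials=serials,
    )


def read_ensemble(source, format: str | None = None) -> Ensemble:
    """Read a multi-model PDB or multi-frame XYZ as a uniformly weighted ensemble."""
    system = read_structure(source, format=format)
    return Ensemble(system=system)


def _pdb_atom_line(serial, name, resname, resid, xyz, element) -> str:
    name = str(name)
    field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {serial:>5d} {field}{str(resname)[:3]:>4s} A{int(resid):>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {str(element)[:2]:>2s}"
    )


def write_structure(system: MolecularSystem, path=None, format: str = "pdb") -> str:
    """Serialize a MolecularSystem to PDB or XYZ text; optionally write to ``path``.

    The PDB writer emits fixed-width ATOM records (wwPDB v3.3 columns),
    MODEL/ENDMDL blocks for multi-model systems and CONECT records for the
    explicit bond list, so a write/read round trip preserves the atom table
    and coordinates to PDB precision (3 decimals).
    """
    format = format.lower()
    lines: list[str] = []
    if format == "pdb":
        multi = system.n_models > 1
        for m in range(system.n_models):
            if multi:
                lines.append(f"MODEL     {m + 1:>4d}")
            for i in range(system.n_atoms):
                lines.append(
                    _pdb_atom_line(
                        int(system.serials[i]),
                        system.names[i],
                        system.resnames[i],
                        system.resids[i],
                        system.coords[m, i],
                        system.elements[i],
                    )
                )
            if multi:
                lines.append("ENDMDL")
        partners: dict[int, list[int]] = {}
        for i, j in system.bonds:
            partners.setdefault(i, []).append(j)
            partners.setdefault(j, []).append(i)
        for i in sorted(partners):
            js = sorted(partners[i])
            for k in range(0, len(js), 4):
                row = js[k : k + 4]
                lines.append(
                    "CONECT"
                    + f"{int(system.serials[i]):>5d}"
                    + "".join(f"{int(system.serials[j]):>5d}" for j in row)
                )
        lines.append("END")
    elif format == "xyz":
        for m in range(system.n_models):
            lines.append(str(system.n_atoms))
            lines.append(f"model {m + 1}")
            for i in range(system.n_atoms):
                x, y, z = system.coords[m, i]
                lines.append(f"{system.elements[i]} {x:.6f} {y:.6f} {z:.6f}")
    else:
        raise InputError(f"unsupported format {format!r} (pdb or xyz)")

    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(result, parameters: dict | None = None, format: str = "json") -> str:
    """Render any analysis record as a machine-readable report.

    JSON reports wrap the record with the tool name/version and the echoed
    parameters.  TSV reports render a list of records as a table (one row
    per record) or a single record as key/value rows; an empty record list
    yields a header-only table.
    """
    payload = {
        "tool": "ansamer",
        "version": __version__,
        "parameters": _jsonable(parameters or {}),
        "result": _jsonable(result),
    }
    if format == "json":
        return json.dumps(payload, indent=2, sort_keys=False) + "\n"
    if format != "tsv":
        raise InputError(f"unsupported report format {format!r}")

    buf = io.StringIO()
    buf.write(f"# tool\tansamer\t{__version__}\n")
    for key, value in (payload["parameters"] or {}).items():
        buf.write(f"# param\t{key}\t{value}\n")
    record = payload["result"]
    if isinstance(record, list):
        if record and isinstance(record[0], dict):
            cols = list(record[0].keys())
            buf.write("\t".join(cols) + "\n")
            for row in record:
                buf.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")
        else:
            buf.write("value\n")
            for row in record:
                buf.write(f"{row}\n")
    elif isinstance(record, dict):
        for key, value in record.items():
            buf.write(f"{key}\t{value}\n")
    else:
        buf.write(f"value\t{record}\n")
    return buf.getvalue()
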