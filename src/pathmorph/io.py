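"""Reading and writing coordinate files (PDB and GRO) via MDAnalysis.

All coordinates are held internally in Ångström; GRO files (nm on disk) are
converted on read and write by the MDAnalysis backends.  Multi-model PDB
files represent paths and trajectories: :func:`read_path` returns one
:class:`~pathmorph.frames.StructureFrame` per MODEL, :func:`write_path`
emits one MODEL per frame.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .frames import AtomRecord, StructureFrame, guess_element

__all__ = ["read_structure", "write_structure", "read_path", "write_path"]

_FORMATS = {"pdb", "gro"}


class ParseError(ValueError):
    pass


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {sorted(_FORMATS)}")
    return fmt


def _universe_to_records(u: "mda.Universe") -> list[AtomRecord]:
    ag = u.atoms
    names = ag.names
    resnames = ag.resnames
    resids = ag.resids
    try:
        chains = [c if c.strip() else "A" for c in ag.chainIDs]
    except (AttributeError, mda.exceptions.NoDataError):
        chains = ["A"] * len(ag)
    try:
        elements = list(ag.elements)
    except (AttributeError, mda.exceptions.NoDataError):
        elements = [""] * len(ag)
    records = []
    for i in range(len(ag)):
        el = str(elements[i]).strip()
        if not el:
            el = guess_element(str(names[i]))
        records.append(AtomRecord(
            serial=i + 1,
            name=str(names[i]),
            element=el.capitalize() if len(el) > 1 else el.upper(),
            residue_name=str(resnames[i]),
            residue_number=int(resids[i]),
            chain=str(chains[i]),
        ))
    return records


def _box_from_universe(u: "mda.Universe") -> np.ndarray | None:
    dims = u.dimensions
    if dims is None or not np.any(dims[:3]):
        return None
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ParseError("only orthorhombic boxes are supported")
    return np.array(dims[:3], dtype=float)


def _load_universe(path: str | Path, fmt: str) -> "mda.Universe":
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path), format=fmt, topology_format=fmt)
    except FileNotFoundError:
        raise
    except Exception as exc:  # surface the backend's message with the file name
        raise ParseError(f"could not parse {path} as {fmt.upper()}: {exc}") from exc


def read_structure(path: str | Path, format: str | None = None) -> StructureFrame:
    """Read a single conformation from a PDB or GRO file.

    For multi-model PDB files the first model is returned; use
    :func:`read_path` for the full sequence.  Coordinates are in Å
    regardless of the on-disk unit.
    """
    fmt = _infer_format(path, format)
    u = _load_universe(path, fmt)
    records = _universe_to_records(u)
    _check_unique_keys(records, path)
    return StructureFrame(records, u.atoms.positions.astype(float),
                          _box_from_universe(u))


def read_path(path: str | Path, format: str | None = None) -> list[StructureFrame]:
    """Read every model of a (multi-model) coordinate file as a list of frames."""
    fmt = _infer_format(path, format)
    u = _load_universe(path, fmt)
    records = _universe_to_records(u)
    _check_unique_keys(records, path)
    box = _box_from_universe(u)
    frames = []
    for _ in u.trajectory:
        frames.append(StructureFrame(records, u.atoms.positions.astype(float), box))
    return frames


def _check_unique_keys(records: Sequence[AtomRecord], path) -> None:
    seen: dict[tuple, int] = {}
    for rec in records:
        if rec.key in seen:
            raise ParseError(
                f"{path}: duplicate atom identity {rec.key} "
                "(alternate locations / insertion codes are not supported)")
        seen[rec.key] = rec.serial


def _frame_to_universe(frame: StructureFrame) -> "mda.Universe":
    n = len(frame)
    res_keys: list[tuple] = []
    resindex = np.empty(n, dtype=int)
    for i, a in enumerate(frame.atoms):
        key = (a.chain, a.residue_number, a.residue_name)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        resindex[i] = len(res_keys) - 1
    nres = len(res_keys)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=nres, atom_resindex=resindex,
            residue_segindex=np.zeros(nres, dtype=int), trajectory=True)
        u.add_TopologyAttr("names", [a.name for a in frame.atoms])
        u.add_TopologyAttr("elements", [a.element for a in frame.atoms])
        u.add_TopologyAttr("chainIDs", [a.chain[:1] or "A" for a in frame.atoms])
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("segids", ["SYS"])
        u.add_TopologyAttr("occupancies", np.ones(n))
        u.add_TopologyAttr("tempfactors", np.zeros(n))
        u.atoms.positions = frame.coords
        if frame.box is not None:
            u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    return u


def write_structure(frame: StructureFrame, path: str | Path,
                    format: str | None = None) -> None:
    """Write one frame as a PDB or GRO file (fixed-width standard records)."""
    fmt = _infer_format(path, format)
    u = _frame_to_universe(frame)
    if fmt == "gro" and frame.box is None:
        u.dimensions = [0.0, 0.0, 0.0, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_path(frames: Sequence[StructureFrame], path: str | Path) -> None:
    """Write a sequence of same-topology frames as one multi-model PDB."""
    if not frames:
        raise ValueError("empty frame sequence")
    first = frames[0]
    for f in frames[1:]:
        if not f.same_topology(first):
            raise ValueError("all frames in a path must share one topology")
    u = _frame_to_universe(first)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=len(first), multiframe=True) as w:
            for f in frames:
                u.atoms.positions = f.coords
                w.write(u.atoms)
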