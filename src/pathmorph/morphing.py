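"""Linear coordinate morphing between two end-state conformations.

The morph is the first stage of path generation: for corresponding atoms
``i`` the intermediate ``n`` of ``N`` windows is the convex combination

    X_i(n) = (1 - f) X_i(start) + f X_i(end),   f = n / (N - 1)

so window 0 is the start state and window N-1 the end state, exactly.  The
end states must be superposed beforehand (the pipeline superposes on Cα by
default); the morph itself is frame-agnostic.  Intermediates are in general
geometrically unphysical — bond lengths and angles interpolate linearly —
and are repaired afterwards by the model-ensemble stage.

A ligand present in both end states is carried along rigidly: its internal
conformation is the start pose and its heavy-atom center of mass is
translated by the window fraction of the start→end COM displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .frames import AtomRecord, Selection, StructureFrame, select

__all__ = ["MorphPath", "check_correspondence", "linear_morph", "interpolate_ligand"]

DEFAULT_N_WINDOWS = 24


class CorrespondenceError(ValueError):
    pass


@dataclass
class MorphPath:
    """An ordered sequence of same-topology frames from state A to state B."""

    frames: list[StructureFrame]

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("a path needs at least 2 windows")
        first = self.frames[0]
        for f in self.frames[1:]:
            if not f.same_topology(first):
                raise ValueError("path frames must share one topology")

    @property
    def n_windows(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> StructureFrame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    def reversed(self) -> "MorphPath":
        return MorphPath([f.copy() for f in self.frames[::-1]])


def check_correspondence(start: StructureFrame, end: StructureFrame) -> np.ndarray:
    """Bijective atom mapping between two end states.

    Atoms correspond by their ``(chain, residue_number, atom_name)`` triple
    (serials differ between deposited structures).  Returns an index array
    ``m`` with ``end.atoms[m[i]]`` matching ``start.atoms[i]``.  Any atom
    present in only one frame raises :class:`CorrespondenceError` naming the
    offenders.
    """
    end_index = {a.key: i for i, a in enumerate(end.atoms)}
    start_keys = {a.key for a in start.atoms}
    missing_in_end = [a.key for a in start.atoms if a.key not in end_index]
    missing_in_start = [a.key for a in end.atoms if a.key not in start_keys]
    if missing_in_end or missing_in_start:
        msgs = []
        if missing_in_end:
            msgs.append(f"absent from end state: {missing_in_end[:10]}")
        if missing_in_start:
            msgs.append(f"absent from start state: {missing_in_start[:10]}")
        raise CorrespondenceError("atom correspondence failed; " + "; ".join(msgs))
    return np.array([end_index[a.key] for a in start.atoms], dtype=int)


def linear_morph(start: StructureFrame, end: StructureFrame,
                 n_windows: int = DEFAULT_N_WINDOWS) -> MorphPath:
    """Linear interpolation of corresponding coordinates over ``n_windows``.

    The endpoint frames carry the input coordinates bitwise; interior frames
    are exact convex combinations, so consecutive frames are displaced by the
    same per-atom vector and the path is evenly spaced.  All atoms are
    interpolated, hydrogens included (downstream geometry fixing needs
    complete structures); the path adopts the start state's atom ordering.
    """
    if n_windows < 2:
        raise ValueError(f"n_windows must be >= 2, got {n_windows}")
    mapping = check_correspondence(start, end)
    x0 = start.coords
    x1 = end.coords[mapping]
    frames = [start.copy()]
    for n in range(1, n_windows - 1):
        f = n / (n_windows - 1)
        frames.append(start.with_coords((1.0 - f) * x0 + f * x1))
    frames.append(start.with_coords(x1.copy()))
    return MorphPath(frames)


def _merged_records(protein: StructureFrame, ligand: StructureFrame) -> list[AtomRecord]:
    prot_keys = {a.key for a in protein.atoms}
    clash = [a.key for a in ligand.atoms if a.key in prot_keys]
    if clash:
        raise ValueError(f"ligand/protein atom identity clash: {clash[:5]}")
    serial = max(a.serial for a in protein.atoms)
    merged = list(protein.atoms)
    for a in ligand.atoms:
        serial += 1
        merged.append(replace(a, serial=serial))
    return merged


def interpolate_ligand(path: MorphPath, ligand_start: StructureFrame,
                       ligand_end: StructureFrame,
                       rigid: bool = True) -> MorphPath:
    """Insert a ligand into every window of a protein path.

    In the default rigid mode the ligand keeps the internal conformation of
    its start pose; at window ``n`` it is rigidly translated so its
    heavy-atom center of mass is the fraction ``n/(N-1)`` of the way from the
    start COM to the end COM.  The alternative ``rigid=False`` mode instead
    interpolates the ligand's atomic coordinates linearly with no shape
    preservation (useful only when a downstream energy minimisation will
    repair the geometry).
    """
    mapping = check_correspondence(ligand_start, ligand_end)
    records = _merged_records(path[0], ligand_start)
    n = path.n_windows
    heavy = ligand_start.heavy
    com_start = ligand_start.center_of_mass(heavy)
    com_end = StructureFrame(ligand_start.atoms,
                             ligand_end.coords[mapping]).center_of_mass(heavy)
    frames = []
    for w, frame in enumerate(path):
        f = w / (n - 1)
        if rigid:
            lig_coords = ligand_start.coords + f * (com_end - com_start)
        else:
            lig_coords = (1.0 - f) * ligand_start.coords + f * ligand_end.coords[mapping]
        coords = np.vstack([frame.coords, lig_coords])
        frames.append(StructureFrame(records, coords,
                                     None if frame.box is None else frame.box.copy()))
    return MorphPath(frames)
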