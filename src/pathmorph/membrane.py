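"""Embedding protein conformations into a pre-equilibrated lipid membrane.

A membrane protein intermediate cannot be morphed together with its lipids;
instead one end state is provided embedded in a bilayer and every other
window is re-embedded into that template by an inflate/deflate procedure:
stretch the membrane in its plane (default 15%) so the new conformation fits
with room to spare, delete any lipid still overlapping the protein, then run
cycles (default 5) of in-plane compression (default 4% each) followed by a
clash-relaxation pass, until the bilayer packs snugly around the protein.

Lipids move only as rigid bodies in the membrane plane — their COMs are
scaled or displaced while internal geometry and z-coordinates stay fixed.
The built-in relaxer does steepest descent on per-lipid in-plane
displacements under a soft-sphere repulsion against the protein and the
other lipids; a force-field minimiser can be substituted through the same
callable contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .frames import AtomRecord, StructureFrame
from .geometry import superpose

__all__ = [
    "LipidMolecule",
    "MembraneSystem",
    "EmbedParams",
    "scale_membrane",
    "clash_count",
    "relax_clashes",
    "embed",
    "soft_sphere_relaxer",
]

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "BEA",  # BEA: bead-chain fixture residues
}


@dataclass
class LipidMolecule:
    """One lipid: atom records plus coordinates; moved only rigidly in-plane."""

    atoms: tuple[AtomRecord, ...]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.atoms = tuple(self.atoms)

    @property
    def com_xy(self) -> np.ndarray:
        m = np.array([a.mass for a in self.atoms])
        return (self.coords[:, :2] * m[:, None]).sum(axis=0) / m.sum()

    def heavy_coords(self) -> np.ndarray:
        mask = np.array([a.is_heavy for a in self.atoms])
        return self.coords[mask]

    def translated_xy(self, shift_xy: np.ndarray) -> "LipidMolecule":
        coords = self.coords.copy()
        coords[:, :2] += shift_xy
        return LipidMolecule(self.atoms, coords)


@dataclass
class MembraneSystem:
    """Protein (optional) + lipids + orthorhombic periodic box."""

    protein: StructureFrame | None
    lipids: list[LipidMolecule]
    box_xy: np.ndarray
    box_z: float

    def __post_init__(self):
        self.box_xy = np.asarray(self.box_xy, dtype=float)

    @property
    def box(self) -> np.ndarray:
        return np.array([self.box_xy[0], self.box_xy[1], self.box_z])

    def copy(self) -> "MembraneSystem":
        return MembraneSystem(
            None if self.protein is None else self.protein.copy(),
            [LipidMolecule(l.atoms, l.coords.copy()) for l in self.lipids],
            self.box_xy.copy(), self.box_z)

    def wrap(self) -> None:
        """Translate whole lipids so their COMs lie inside the periodic box."""
        for i, lip in enumerate(self.lipids):
            com = lip.com_xy
            shift = -np.floor(com / self.box_xy) * self.box_xy
            if np.any(shift):
                self.lipids[i] = lip.translated_xy(shift)

    def to_frame(self) -> StructureFrame:
        """Flatten to a single frame (protein first, then lipids), renumbered."""
        records: list[AtomRecord] = []
        coords: list[np.ndarray] = []
        if self.protein is not None:
            records.extend(self.protein.atoms)
            coords.append(self.protein.coords)
        for lip in self.lipids:
            records.extend(lip.atoms)
            coords.append(lip.coords)
        serial = 0
        renumbered = []
        for rec in records:
            serial += 1
            renumbered.append(replace(rec, serial=serial))
        return StructureFrame(renumbered, np.vstack(coords), self.box)

    @classmethod
    def from_frame(cls, frame: StructureFrame,
                   lipid_resnames: Sequence[str] | None = None,
                   box_z: float | None = None) -> "MembraneSystem":
        """Split a flat system frame into protein and per-residue lipids.

        Residues with names in ``lipid_resnames`` (default: any residue name
        that is not a standard amino acid) become lipids, grouped by
        (chain, residue number).
        """
        if frame.box is None and box_z is None:
            raise ValueError("membrane systems need a periodic box")
        box = frame.box if frame.box is not None else np.array([0.0, 0.0, box_z])
        is_lipid = [
            (a.residue_name in lipid_resnames) if lipid_resnames is not None
            else (a.residue_name not in _AMINO_ACIDS)
            for a in frame.atoms]
        prot_idx = [i for i, fl in enumerate(is_lipid) if not fl]
        protein = None
        if prot_idx:
            protein = StructureFrame([frame.atoms[i] for i in prot_idx],
                                     frame.coords[prot_idx])
        lipids: list[LipidMolecule] = []
        current_key, cur_atoms, cur_idx = None, [], []
        for i, fl in enumerate(is_lipid):
            if not fl:
                continue
            a = frame.atoms[i]
            key = (a.chain, a.residue_number)
            if key != current_key and cur_atoms:
                lipids.append(LipidMolecule(cur_atoms, frame.coords[cur_idx]))
                cur_atoms, cur_idx = [], []
            current_key = key
            cur_atoms.append(a)
            cur_idx.append(i)
        if cur_atoms:
            lipids.append(LipidMolecule(cur_atoms, frame.coords[cur_idx]))
        return cls(protein, lipids, box[:2], float(box[2]))


@dataclass(frozen=True)
class EmbedParams:
    """Tunables of the stretch/compress embedding procedure."""

    stretch_fraction: float = 0.15
    n_cycles: int = 5
    compress_fraction: float = 0.04
    clash_cutoff: float = 2.0
    minimizer: str = "soft_sphere"
    relax_max_steps: int = 200

    def __post_init__(self):
        if self.stretch_fraction <= 0:
            raise ValueError("stretch_fraction must be > 0")
        if not 0 < self.compress_fraction < 1:
            raise ValueError("compress_fraction must be in (0, 1)")


def scale_membrane(system: MembraneSystem, factor: float) -> MembraneSystem:
    """Affine in-plane scaling of lipid COMs about the box center.

    Each lipid is rigidly translated so its in-plane COM satisfies
    ``com' = c + factor * (com - c)`` with ``c`` the in-plane box center;
    the box is scaled by the same factor.  Internal lipid geometry and all
    z-coordinates are untouched.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    out = system.copy()
    center = system.box_xy / 2.0
    for i, lip in enumerate(out.lipids):
        com = lip.com_xy
        out.lipids[i] = lip.translated_xy(center + factor * (com - center) - com)
    out.box_xy = system.box_xy * factor
    out.wrap()
    return out


def _heavy_coords(frame: StructureFrame) -> np.ndarray:
    mask = np.array([a.is_heavy for a in frame.atoms])
    return frame.coords[mask]


def _pairs_within(a: np.ndarray, b: np.ndarray, cutoff: float,
                  box: np.ndarray) -> int:
    """Count minimum-image pairs (one from a, one from b) closer than cutoff."""
    if len(a) == 0 or len(b) == 0:
        return 0
    box = np.asarray(box, float)
    ta = cKDTree(np.mod(a, box), boxsize=box)
    tb = cKDTree(np.mod(b, box), boxsize=box)
    return int(ta.count_neighbors(tb, cutoff))


def clash_count(system: MembraneSystem, cutoff: float = 2.0) -> int:
    """Number of protein-heavy / lipid-heavy atom pairs within ``cutoff`` (MIC)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if system.protein is None or not system.lipids:
        return 0
    prot = _heavy_coords(system.protein)
    lip = np.vstack([l.heavy_coords() for l in system.lipids])
    # strict inequality: count pairs at distance < cutoff
    tree_cut = np.nextafter(cutoff, 0.0)
    return _pairs_within(prot, lip, tree_cut, system.box)


def soft_sphere_relaxer(system: MembraneSystem, cutoff: float,
                        max_steps: int = 200) -> MembraneSystem:
    """Steepest descent on rigid per-lipid in-plane displacements.

    Overlapping heavy-atom pairs within ``1.2 * cutoff`` exert a linear
    repulsive force ``(range - d)`` on the lipid COM, projected into the
    membrane plane.  A move is kept only if the protein–lipid clash count
    does not increase; otherwise the step size is halved.  Stops when no
    pair (protein–lipid or lipid–lipid) remains within ``cutoff``.
    """
    sys_ = system.copy()
    box = sys_.box
    rng_cut = 1.2 * cutoff
    step = 0.5
    prot = _heavy_coords(sys_.protein) if sys_.protein is not None else np.empty((0, 3))
    prot_w = np.mod(prot, box)
    prot_tree = cKDTree(prot_w, boxsize=box) if len(prot) else None
    best_clashes = clash_count(sys_, cutoff)
    for _ in range(max_steps):
        lip_coords = [l.heavy_coords() for l in sys_.lipids]
        lip_all = np.vstack(lip_coords)
        owner = np.repeat(np.arange(len(sys_.lipids)),
                          [len(c) for c in lip_coords])
        lip_w = np.mod(lip_all, box)
        lip_tree = cKDTree(lip_w, boxsize=box)
        forces = np.zeros((len(sys_.lipids), 2))
        worst = 0.0
        # lipid-lipid overlaps
        for i, j in lip_tree.query_pairs(rng_cut):
            if owner[i] == owner[j]:
                continue
            d_vec = lip_w[i] - lip_w[j]
            d_vec -= box * np.round(d_vec / box)
            d = float(np.linalg.norm(d_vec))
            if d < 1e-9 or d >= rng_cut:
                continue
            f = (rng_cut - d) / d
            forces[owner[i], :] += f * d_vec[:2]
            forces[owner[j], :] -= f * d_vec[:2]
            if d < cutoff:
                worst = max(worst, cutoff - d)
        # protein-lipid overlaps
        if prot_tree is not None:
            for li, neigh in enumerate(lip_tree.query_ball_tree(prot_tree, rng_cut)):
                for pi in neigh:
                    d_vec = lip_w[li] - prot_w[pi]
                    d_vec -= box * np.round(d_vec / box)
                    d = float(np.linalg.norm(d_vec))
                    if d < 1e-9 or d >= rng_cut:
                        continue
                    forces[owner[li], :] += (rng_cut - d) / d * d_vec[:2]
                    if d < cutoff:
                        worst = max(worst, cutoff - d)
        if worst == 0.0 and best_clashes == 0:
            break
        norms = np.linalg.norm(forces, axis=1)
        max_f = norms.max()
        if max_f < 1e-12:
            break
        trial = sys_.copy()
        for li in range(len(trial.lipids)):
            if norms[li] > 0:
                trial.lipids[li] = trial.lipids[li].translated_xy(
                    step * forces[li] / max_f)
        trial.wrap()
        trial_clashes = clash_count(trial, cutoff)
        if trial_clashes <= best_clashes:
            sys_ = trial
            best_clashes = trial_clashes
        else:
            step *= 0.5
            if step < 1e-4:
                break
    return sys_


_RELAXERS: dict[str, Callable] = {"soft_sphere": soft_sphere_relaxer}


def relax_clashes(system: MembraneSystem, minimizer: str = "soft_sphere",
                  max_steps: int = 200, cutoff: float = 2.0) -> MembraneSystem:
    """Run the named relaxation backend; protein–lipid clash count never increases."""
    try:
        fn = _RELAXERS[minimizer]
    except KeyError:
        raise ValueError(f"unknown minimizer {minimizer!r}; "
                         f"available: {sorted(_RELAXERS)}") from None
    before = clash_count(system, cutoff)
    relaxed = fn(system, cutoff, max_steps)
    after = clash_count(relaxed, cutoff)
    if after > before:  # backend contract violation; fall back to input
        warnings.warn(f"relaxer {minimizer!r} increased clashes; keeping input")
        return system.copy()
    if after > 0:
        warnings.warn(f"{after} residual clash pairs after relaxation")
    return relaxed


@dataclass
class EmbedReport:
    cycles: pd.DataFrame
    lipids_deleted: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# per-cycle embedding report: stage, box area (A^2), "
                     "clash pairs, lipid count\n")
            self.cycles.to_csv(fh, sep="\t", index=False)


def embed(protein: StructureFrame | None, template: MembraneSystem,
          params: EmbedParams = EmbedParams(),
          align: bool = True) -> tuple[MembraneSystem, EmbedReport]:
    """Embed a protein conformation into a membrane template.

    Pipeline: replace the template's protein with the new conformation
    (superposed onto it on shared atoms when ``align``) → stretch the
    membrane in-plane by ``1 + stretch_fraction`` → delete lipids still
    clashing with the protein → ``n_cycles`` × [compress in-plane by
    ``1 - compress_fraction``; relax clashes].  Residual clashes after the
    final cycle produce a warning, not a failure.
    """
    system = template.copy()
    if protein is not None:
        new_prot = protein.copy()
        if align and system.protein is not None:
            # match atoms by identity key so differing orderings still align
            old_index = {a.key: i for i, a in enumerate(system.protein.atoms)}
            pairs = [(i, old_index[a.key]) for i, a in enumerate(new_prot.atoms)
                     if a.key in old_index]
            if len(pairs) >= 3:
                mob_idx = [i for i, _ in pairs]
                ref_idx = [j for _, j in pairs]
                mob = StructureFrame([new_prot.atoms[i] for i in mob_idx],
                                     new_prot.coords[mob_idx])
                ref = StructureFrame([system.protein.atoms[j] for j in ref_idx],
                                     system.protein.coords[ref_idx])
                sup = superpose(mob, ref)
                new_prot = new_prot.with_coords(
                    new_prot.coords @ sup.rotation.T + sup.translation)
        system.protein = new_prot
    rows = []

    def record(stage: str, s: MembraneSystem) -> None:
        rows.append({"stage": stage,
                     "box_area": float(s.box_xy[0] * s.box_xy[1]),
                     "clashes": clash_count(s, params.clash_cutoff),
                     "n_lipids": len(s.lipids)})

    record("input", system)
    system = scale_membrane(system, 1.0 + params.stretch_fraction)
    n_before = len(system.lipids)
    if system.protein is not None:
        prot = _heavy_coords(system.protein)
        kept = []
        for lip in system.lipids:
            if _pairs_within(prot, lip.heavy_coords(),
                             np.nextafter(params.clash_cutoff, 0.0),
                             system.box) == 0:
                kept.append(lip)
        system.lipids = kept
    deleted = n_before - len(system.lipids)
    record("stretched+filtered", system)
    for cycle in range(params.n_cycles):
        system = scale_membrane(system, 1.0 - params.compress_fraction)
        system = relax_clashes(system, params.minimizer,
                               params.relax_max_steps, params.clash_cutoff)
        record(f"cycle_{cycle + 1}", system)
    final_clashes = clash_count(system, params.clash_cutoff)
    if final_clashes > 0:
        warnings.warn(f"{final_clashes} clash pairs remain after "
                      f"{params.n_cycles} compression cycles")
    return system, EmbedReport(pd.DataFrame(rows), deleted)
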