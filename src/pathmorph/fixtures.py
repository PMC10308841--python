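"""Deterministic desk-scale synthetic systems with known ground truth.

Every pipeline stage can be exercised without downloading anything:

* :func:`make_polyalanine` — an all-atom (backbone + CB) polyalanine chain
  built from ideal internal coordinates at requested (phi, psi) dihedrals,
  with α-helical and extended presets.  This is the classic toy peptide for
  validating transition-path machinery on a helix ⇄ extended change.
* :func:`make_bead_chain` — a Cα-only bead chain, the default annealer
  fixture (cheap, unambiguous geometry).
* :func:`make_planted_ensemble` — a model ensemble in which one secret model
  per window lies exactly on a smooth morph while all decoys carry at least
  a prescribed jitter, so the globally smoothest path is known by
  construction and verified at generation time.
* :func:`make_toy_membrane` — a periodic lattice of vertical bead-chain
  "lipids" for the embedding operators, plus a bead cylinder standing in
  for a membrane protein.

All generators are pure functions of their arguments (and seed): identical
inputs give bitwise-identical fixtures.
"""

from __future__ import annotations

import math

import numpy as np

from .annealing import EdgeCosts, PathState
from .ensembles import ModelEnsemble
from .frames import AtomRecord, StructureFrame
from .membrane import LipidMolecule, MembraneSystem
from .morphing import MorphPath, linear_morph

__all__ = [
    "make_polyalanine",
    "HELIX", "EXTENDED",
    "make_bead_chain",
    "make_bead_morph",
    "make_planted_ensemble",
    "make_random_ensemble",
    "make_toy_membrane",
    "make_bead_cylinder",
]

# canonical backbone dihedral presets (degrees)
HELIX = (-57.0, -47.0)
EXTENDED = (-139.0, 135.0)

# ideal backbone internal coordinates (lengths Å, angles degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.521
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_N_CA_CB = 110.5
_OMEGA = 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position atom d with |cd| = bond, angle(b,c,d), torsion(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_polyalanine(n_res: int, phi: float = HELIX[0], psi: float = HELIX[1],
                     chain: str = "A") -> StructureFrame:
    """All-atom-backbone polyalanine at uniform (phi, psi) dihedrals.

    Each residue carries N, CA, C, O and CB placed by ideal bond lengths and
    angles; omega is trans.  ``make_polyalanine(10, *HELIX)`` and
    ``make_polyalanine(10, *EXTENDED)`` are matched end states for morphing.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C = CA + np.array([-_B_CA_C * math.cos(ang), _B_CA_C * math.sin(ang), 0.0])
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 0

    def add(name: str, element: str, resnum: int, xyz: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(serial, name, element, "ALA", resnum, chain))
        coords.append(xyz)

    prev_N, prev_CA, prev_C = N, CA, C
    for res in range(1, n_res + 1):
        if res > 1:
            Nn = _place_atom(prev_N, prev_CA, prev_C, _B_C_N, _A_CA_C_N, psi)
            CAn = _place_atom(prev_CA, prev_C, Nn, _B_N_CA, _A_C_N_CA, _OMEGA)
            Cn = _place_atom(prev_C, Nn, CAn, _B_CA_C, _A_N_CA_C, phi)
            prev_N, prev_CA, prev_C = Nn, CAn, Cn
        add("N", "N", res, prev_N)
        add("CA", "C", res, prev_CA)
        add("C", "C", res, prev_C)
        # carbonyl O anti to the next N (trans peptide)
        add("O", "O", res, _place_atom(prev_N, prev_CA, prev_C,
                                       _B_C_O, _A_CA_C_O, psi + 180.0))
        add("CB", "C", res, _place_atom(prev_C, prev_N, prev_CA,
                                        _B_CA_CB, _A_N_CA_CB, 123.0))
    return StructureFrame(atoms, np.array(coords))


def make_bead_chain(n_beads: int, spacing: float = 3.8,
                    shape: str = "line", amplitude: float = 6.0,
                    chain: str = "A", resname: str = "BEA") -> StructureFrame:
    """Cα-only bead chain along x, optionally bent into an arc or sine wave."""
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    x = np.arange(n_beads) * spacing
    if shape == "line":
        y = np.zeros(n_beads)
    elif shape == "sine":
        y = amplitude * np.sin(np.linspace(0.0, math.pi, n_beads))
    elif shape == "arc":
        y = amplitude * (1.0 - np.cos(np.linspace(0.0, math.pi, n_beads)))
    else:
        raise ValueError(f"unknown shape {shape!r}")
    coords = np.column_stack([x, y, np.zeros(n_beads)])
    atoms = [AtomRecord(i + 1, "CA", "C", resname, i + 1, chain)
             for i in range(n_beads)]
    return StructureFrame(atoms, coords)


def make_bead_morph(n_windows: int, n_beads: int = 10,
                    spacing: float = 3.8) -> MorphPath:
    """A smooth line → sine-wave bead-chain morph (shared topology)."""
    start = make_bead_chain(n_beads, spacing, "line")
    end = make_bead_chain(n_beads, spacing, "sine")
    return linear_morph(start, end, n_windows)


def make_planted_ensemble(n_windows: int, n_models: int, jitter: float,
                          seed: int = 0, n_beads: int = 10,
                          ) -> tuple[ModelEnsemble, PathState]:
    """Ensemble with a hidden smooth path: the annealer's ground-truth fixture.

    One model per interior window (at a secret, seed-dependent index) lies
    exactly on a smooth bead-chain morph; every decoy is that window's morph
    frame plus Gaussian noise rescaled so its heavy-atom RMSD from the target
    is at least ``jitter`` Å.  Endpoints are pinned.  For ``jitter > 0`` the
    planted path is verified at generation time to beat every single-model
    swap, which (decoys being independent) makes it the global optimum with
    overwhelming margin.
    """
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    path = make_bead_morph(n_windows, n_beads)
    windows: list[list[StructureFrame]] = []
    planted = np.zeros(n_windows, dtype=int)
    for w, target in enumerate(path):
        if w in (0, n_windows - 1):
            windows.append([target.copy()])
            continue
        secret = int(rng.integers(n_models))
        planted[w] = secret
        models = []
        for m in range(n_models):
            if m == secret:
                models.append(target.copy())
                continue
            noise = rng.normal(0.0, 1.0, size=target.coords.shape)
            r = math.sqrt(np.mean(np.sum(noise ** 2, axis=1)))
            # at least `jitter` RMSD from the target, up to 1.5x
            factor = (jitter if jitter > 0 else 0.0) * (1.0 + 0.5 * rng.random())
            models.append(target.with_coords(
                target.coords + (factor / r if r > 0 else 0.0) * noise))
        windows.append(models)
    ensemble = ModelEnsemble(windows, n_models, pinned_endpoints=True)
    truth = PathState(planted)
    if jitter > 0:
        _verify_planted(ensemble, truth)
    return ensemble, truth


def _verify_planted(ensemble: ModelEnsemble, truth: PathState) -> None:
    costs = EdgeCosts.from_ensemble(ensemble)
    base = costs.sumsq(truth.p)
    for w in costs.interior_windows():
        for m in range(costs.sizes[w]):
            if m == truth.p[w]:
                continue
            alt = truth.p.copy()
            alt[w] = m
            if costs.sumsq(alt) <= base:
                raise AssertionError(
                    f"planted path is not a strict local optimum at window {w}")


def make_random_ensemble(n_windows: int, n_models: int, jitter: float = 1.0,
                         seed: int = 0, n_beads: int = 10) -> ModelEnsemble:
    """Random annealer test instance: every model jittered, none planted."""
    rng = np.random.default_rng(seed)
    path = make_bead_morph(n_windows, n_beads)
    windows: list[list[StructureFrame]] = []
    for w, target in enumerate(path):
        if w in (0, n_windows - 1):
            windows.append([target.copy()])
            continue
        windows.append([
            target.with_coords(target.coords +
                               rng.normal(0.0, jitter, size=target.coords.shape))
            for _ in range(n_models)])
    return ModelEnsemble(windows, n_models, pinned_endpoints=True)


def make_toy_membrane(nx: int, ny: int, spacing: float = 8.0,
                      lipid_beads: int = 4, bead_spacing: float = 2.5,
                      box_z: float = 40.0) -> MembraneSystem:
    """An nx × ny lattice of identical vertical bead-chain "lipids".

    Lipid ``(i, j)`` stands at in-plane position ``((i+0.5)s, (j+0.5)s)``;
    the periodic box is ``nx*s × ny*s × box_z``.
    """
    if nx < 1 or ny < 1:
        raise ValueError("lattice dimensions must be >= 1")
    lipids = []
    resnum = 0
    z0 = box_z / 2.0 - (lipid_beads - 1) * bead_spacing / 2.0
    for i in range(nx):
        for j in range(ny):
            resnum += 1
            x = (i + 0.5) * spacing
            y = (j + 0.5) * spacing
            atoms = tuple(
                AtomRecord(b + 1, f"L{b + 1}", "C", "LIP", resnum, "L")
                for b in range(lipid_beads))
            coords = np.array([[x, y, z0 + b * bead_spacing]
                               for b in range(lipid_beads)])
            lipids.append(LipidMolecule(atoms, coords))
    return MembraneSystem(None, lipids,
                          np.array([nx * spacing, ny * spacing]), box_z)


def make_bead_cylinder(radius: float = 6.0, n_per_ring: int = 8,
                       n_rings: int = 4, ring_spacing: float = 3.0,
                       center_xy: np.ndarray | None = None,
                       box_z: float = 40.0) -> StructureFrame:
    """A hollow bead cylinder standing in for a membrane protein."""
    center_xy = np.array([0.0, 0.0]) if center_xy is None else np.asarray(center_xy)
    z0 = box_z / 2.0 - (n_rings - 1) * ring_spacing / 2.0
    atoms = []
    coords = []
    serial = 0
    for r in range(n_rings):
        for k in range(n_per_ring):
            serial += 1
            theta = 2.0 * math.pi * k / n_per_ring
            atoms.append(AtomRecord(serial, "CA", "C", "BEA", serial, "P"))
            coords.append([center_xy[0] + radius * math.cos(theta),
                           center_xy[1] + radius * math.sin(theta),
                           z0 + r * ring_spacing])
    return StructureFrame(atoms, np.array(coords))
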