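"""Turning unphysical morph intermediates into ensembles of candidate models.

Linear morphing distorts local geometry, so each intermediate is handed to a
*fixing backend* that generates ``n_models`` physically more plausible
structures near the morphed target.  In production that backend is a
template-based modelling program driven with the protein sequence aligned
onto itself (wrapped here as :class:`CommandBackend`); for self-contained
work and testing the package ships :class:`JitterBackend`, which perturbs
heavy atoms with Gaussian noise and optionally re-regularises bonded
distances — enough to exercise every downstream stage, including the spread
in candidate structures that the path annealer resolves.

Endpoints are pinned by default: windows 0 and N-1 keep exactly the end-state
frame, so the final path terminates at the experimental structures.
"""

from __future__ import annotations

import abc
import shlex
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .frames import Selection, StructureFrame
from .geometry import rmsd
from .morphing import MorphPath

__all__ = [
    "ModelEnsemble",
    "FixBackend",
    "JitterBackend",
    "CommandBackend",
    "generate_ensembles",
    "regularize_geometry",
    "chain_bond_table",
    "save_ensemble",
    "load_ensemble",
]

DEFAULT_N_MODELS = 50


class BackendError(RuntimeError):
    pass


@dataclass
class ModelEnsemble:
    """Per-window candidate structures sharing one topology.

    ``windows[n]`` is the list of candidate frames for window ``n``.  With
    ``pinned_endpoints`` the first and last windows hold exactly one frame
    each (the untouched end states); interior windows hold ``n_models``.
    """

    windows: list[list[StructureFrame]]
    n_models: int
    pinned_endpoints: bool = True

    def __post_init__(self):
        if len(self.windows) < 2:
            raise ValueError("an ensemble needs at least 2 windows")
        ref = self.windows[0][0]
        for w, models in enumerate(self.windows):
            if not models:
                raise ValueError(f"window {w} has no models")
            for m in models:
                if not m.same_topology(ref):
                    raise ValueError(f"topology mismatch in window {w}")
        if self.pinned_endpoints:
            if len(self.windows[0]) != 1 or len(self.windows[-1]) != 1:
                raise ValueError("pinned endpoint windows must hold exactly one frame")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def sizes(self) -> list[int]:
        return [len(w) for w in self.windows]

    def frame(self, window: int, model: int) -> StructureFrame:
        return self.windows[window][model]

    @property
    def topology(self) -> StructureFrame:
        return self.windows[0][0]


class FixBackend(abc.ABC):
    """Contract for geometry-fixing model generators.

    ``generate`` must return ``n_models`` frames sharing the target topology,
    each within ``rmsd_bound(...)`` heavy-atom RMSD of the target, and must be
    deterministic for a given seed.
    """

    name: str = "abstract"

    @abc.abstractmethod
    def generate(self, target: StructureFrame, n_models: int,
                 seed: int) -> list[StructureFrame]:
        ...

    @abc.abstractmethod
    def rmsd_bound(self) -> float:
        """Declared upper bound on heavy-atom RMSD of any model to its target (Å)."""


def chain_bond_table(frame: StructureFrame,
                     ideal: float | None = None) -> list[tuple[int, int, float]]:
    """Bond table connecting consecutive atoms of each residue chain.

    A minimal connectivity model for bead-chain fixtures: successive atoms
    within the same chain are bonded, with the ideal length taken from the
    input geometry unless given explicitly.
    """
    table = []
    for i in range(len(frame) - 1):
        a, b = frame.atoms[i], frame.atoms[i + 1]
        if a.chain != b.chain:
            continue
        d = ideal if ideal is not None else float(
            np.linalg.norm(frame.coords[i + 1] - frame.coords[i]))
        table.append((i, i + 1, d))
    return table


def regularize_geometry(frame: StructureFrame,
                        bond_table: Sequence[tuple[int, int, float]],
                        tolerance: float = 0.01,
                        max_iters: int = 200) -> StructureFrame:
    """Project bonded distances toward their ideal values (SHAKE-like).

    Each sweep moves the two partners of every bond symmetrically along the
    bond axis to the ideal length; sweeps repeat until every bonded distance
    is within ``tolerance`` Å of ideal or ``max_iters`` is reached (then a
    warning reports the residual).  Non-bonded structure is perturbed only
    through the bonded moves, which is the minimal correction.
    """
    coords = frame.coords.copy()
    n = len(coords)
    for i, j, _ in bond_table:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"bond ({i}, {j}) outside frame of {n} atoms")
    residual = 0.0
    for _ in range(max_iters):
        residual = 0.0
        for i, j, d0 in bond_table:
            v = coords[j] - coords[i]
            d = float(np.linalg.norm(v))
            if d < 1e-12:
                # coincident atoms: push apart along x
                v = np.array([d0, 0.0, 0.0])
                d = d0
                coords[j] = coords[i] + v
            err = d - d0
            residual = max(residual, abs(err))
            shift = 0.5 * err / d * v
            coords[i] += shift
            coords[j] -= shift
        # recheck after the sweep: moving later bonds disturbs earlier ones
        post = max((abs(float(np.linalg.norm(coords[j] - coords[i])) - d0)
                    for i, j, d0 in bond_table), default=0.0)
        if post <= tolerance:
            return frame.with_coords(coords)
    warnings.warn(f"bond regularization did not converge: residual {post:.3g} Å")
    return frame.with_coords(coords)


@dataclass
class JitterBackend(FixBackend):
    """Gaussian-perturbation backend for self-contained pipelines and tests.

    Heavy atoms receive isotropic Gaussian noise of standard deviation
    ``scale`` Å per Cartesian component, so the expected heavy-atom RMSD to
    the target is ``scale * sqrt(3)`` (hydrogens follow their targets
    unchanged).  With ``regularize=True`` a bonded-distance projection pass
    restores ideal bond lengths afterwards, mimicking a modelling program
    that stays near the target while keeping stereochemistry sane.
    """

    scale: float = 0.3
    regularize: bool = False
    bond_table_fn: Callable[[StructureFrame], list] = field(
        default=chain_bond_table)
    tolerance: float = 0.01
    name: str = "jitter"

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    def rmsd_bound(self) -> float:
        # mean heavy-atom RMSD is scale*sqrt(3); 3*scale leaves ~sqrt(3) sigma slack
        return max(3.0 * self.scale, 1e-9)

    def generate(self, target: StructureFrame, n_models: int,
                 seed: int) -> list[StructureFrame]:
        rng = np.random.default_rng(seed)
        heavy_mask = np.array([a.is_heavy for a in target.atoms])
        bond_table = self.bond_table_fn(target) if self.regularize else None
        models = []
        for _ in range(n_models):
            noise = rng.normal(0.0, self.scale, size=target.coords.shape)
            noise[~heavy_mask] = 0.0
            model = target.with_coords(target.coords + noise)
            if self.regularize and bond_table:
                model = regularize_geometry(model, bond_table, self.tolerance)
            models.append(model)
        return models


@dataclass
class CommandBackend(FixBackend):
    """Adapter around an external modelling program.

    Runs ``command`` (a shell template with ``{input}``, ``{output_dir}``,
    ``{n_models}`` and ``{seed}`` placeholders) on each morphed target written
    as a PDB, then reads ``{output_dir}/model_*.pdb`` back.  The declared
    RMSD bound is supplied by the user, since how tightly an external program
    restrains its models to the template is program- and option-dependent.
    """

    command: str
    bound: float = 5.0
    name: str = "command"

    def rmsd_bound(self) -> float:
        return self.bound

    def generate(self, target: StructureFrame, n_models: int,
                 seed: int) -> list[StructureFrame]:
        from . import io as _io
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "target.pdb"
            out = Path(tmp) / "models"
            out.mkdir()
            _io.write_structure(target, inp)
            cmd = self.command.format(input=inp, output_dir=out,
                                      n_models=n_models, seed=seed)
            proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
            if proc.returncode != 0:
                raise BackendError(
                    f"backend command failed ({proc.returncode}): {proc.stderr[-500:]}")
            paths = sorted(out.glob("model_*.pdb"))
            if len(paths) < n_models:
                raise BackendError(
                    f"backend produced {len(paths)} models, expected {n_models}")
            return [_io.read_structure(p) for p in paths[:n_models]]


def generate_ensembles(path: MorphPath, backend: FixBackend,
                       n_models: int = DEFAULT_N_MODELS, seed: int = 0,
                       pinned_endpoints: bool = True) -> ModelEnsemble:
    """Generate candidate-model ensembles for every window of a morph path.

    Window ``w`` uses the derived seed ``seed + w`` so any window can be
    regenerated independently.  With ``pinned_endpoints`` (default) the end
    windows are not re-modelled and keep the exact end-state frames.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    windows: list[list[StructureFrame]] = []
    last = path.n_windows - 1
    for w, target in enumerate(path):
        if pinned_endpoints and w in (0, last):
            windows.append([target.copy()])
            continue
        try:
            models = backend.generate(target, n_models, seed + w)
        except Exception as exc:
            raise BackendError(f"backend {backend.name!r} failed on window {w}: {exc}") from exc
        if len(models) != n_models:
            raise BackendError(
                f"backend {backend.name!r} returned {len(models)} models "
                f"for window {w}, expected {n_models}")
        windows.append(models)
    return ModelEnsemble(windows, n_models, pinned_endpoints)


def save_ensemble(ensemble: ModelEnsemble, directory: str | Path,
                  backend_name: str = "unknown", seed: int = 0,
                  targets: MorphPath | None = None) -> Path:
    """Persist an ensemble as ``window_###/model_###.pdb`` plus a manifest.

    The manifest (tab-separated) records window, model, backend, derived seed
    and — when the morph ``targets`` are supplied — each model's heavy-atom
    RMSD to its morphed target.
    """
    from . import io as _io
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for w, models in enumerate(ensemble.windows):
        wdir = directory / f"window_{w:03d}"
        wdir.mkdir(exist_ok=True)
        for m, frame in enumerate(models):
            _io.write_structure(frame, wdir / f"model_{m:03d}.pdb")
            rows.append({
                "window": w, "model": m, "backend": backend_name,
                "seed": seed + w,
                "rmsd_to_target": (rmsd(frame, targets[w], "heavy", fit=False)
                                   if targets is not None else float("nan")),
            })
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_ensemble(directory: str | Path) -> ModelEnsemble:
    """Load an ensemble written by :func:`save_ensemble`."""
    from . import io as _io
    directory = Path(directory)
    wdirs = sorted(directory.glob("window_*"))
    if not wdirs:
        raise FileNotFoundError(f"no window_* directories under {directory}")
    windows = []
    for wdir in wdirs:
        models = [_io.read_structure(p) for p in sorted(wdir.glob("model_*.pdb"))]
        windows.append(models)
    n_models = max(len(w) for w in windows)
    pinned = len(windows[0]) == 1 and len(windows[-1]) == 1 and n_models > 1
    return ModelEnsemble(windows, n_models, pinned_endpoints=pinned)
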