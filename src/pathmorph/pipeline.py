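"""End-to-end path generation: orchestration, restraint centers, manifests.

``run_pipeline`` wires the stages together: superpose the end states,
linear-morph, optionally carry a ligand, generate per-window model
ensembles, anneal replicates to pick the smoothest path, optionally
re-embed every window into a membrane template, and emit per-window
coordinate files, the chosen path, annealing traces, a restraint-center
table for umbrella sampling, and a manifest from which the run can be
re-executed.

MD preparation proper (solvation, ions, equilibration) is the simulation
engine's job: the hand-off is the window coordinate files plus the
restraint-center table, whose values are computed directly on the generated
window frames (not post-equilibration averages).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as structio
from .annealing import AnnealSchedule, ReplicateSet, run_replicates
from .cvdesign import PCBasis, project
from .ensembles import (DEFAULT_N_MODELS, CommandBackend, FixBackend,
                        JitterBackend, generate_ensembles, save_ensemble)
from .frames import Selection, StructureFrame, select
from .geometry import apply_transform, rmsd, superpose
from .membrane import EmbedParams, MembraneSystem, clash_count, embed
from .morphing import (DEFAULT_N_WINDOWS, MorphPath, interpolate_ligand,
                       linear_morph)

__all__ = ["RunConfig", "run_pipeline", "compute_restraint_centers",
           "make_backend"]

logger = logging.getLogger("pathmorph")


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run.

    Defaults are the package's standard operating point: 24 windows,
    50 models per intermediate, 12 annealing replicates under the geometric
    temperature schedule T(0)=50 → 0.1 over 10^4 steps, and a 15% membrane
    stretch with 5 × 4% compression cycles when a template is supplied.
    """

    start: str = ""
    end: str = ""
    out_dir: str = "pathmorph_run"
    n_windows: int = DEFAULT_N_WINDOWS
    n_models: int = DEFAULT_N_MODELS
    backend: str = "jitter"
    backend_options: dict = field(default_factory=dict)
    t0: float = 50.0
    s_max: int = 10_000
    t_end: float = 0.1
    n_replicates: int = 12
    seed: int = 0
    superpose_selection: str = "name CA"
    ligand_resname: str | None = None
    membrane: str | None = None
    embed_params: dict = field(default_factory=dict)
    cv_spec: dict = field(default_factory=lambda: {"kind": "rmsd_to_reference"})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def schedule(self) -> AnnealSchedule:
        return AnnealSchedule(T0=self.t0, s_max=self.s_max, T_end=self.t_end)


def make_backend(name: str, options: dict | None = None) -> FixBackend:
    options = dict(options or {})
    if name == "jitter":
        return JitterBackend(**options)
    if name == "command":
        return CommandBackend(**options)
    raise ValueError(f"unknown backend {name!r}; available: jitter, command")


def compute_restraint_centers(frames: Sequence[StructureFrame],
                              cv_spec: dict,
                              basis: PCBasis | None = None) -> pd.DataFrame:
    """One umbrella-restraint center per window, from the window frames.

    ``cv_spec['kind']`` selects the collective variable:

    * ``distance`` — distance between the centers of mass of two selections
      (``sel_a``, ``sel_b``), Å;
    * ``rmsd_to_reference`` — Cα RMSD (or ``selection``) to a reference
      window (``reference`` index, default 0), Å;
    * ``pc_projection`` — projection onto ``component`` of a supplied PC
      basis (dimensionless; requires flattening over ``selection``).
    """
    kind = cv_spec.get("kind")
    values = []
    if kind == "distance":
        sel_a, sel_b = cv_spec["sel_a"], cv_spec["sel_b"]
        for f in frames:
            a = f.center_of_mass(select(f, sel_a))
            b = f.center_of_mass(select(f, sel_b))
            values.append(float(np.linalg.norm(a - b)))
    elif kind == "rmsd_to_reference":
        ref = frames[int(cv_spec.get("reference", 0))]
        sel = cv_spec.get("selection", "name CA")
        fit = bool(cv_spec.get("fit", False))
        values = [rmsd(f, ref, sel, fit=fit) for f in frames]
    elif kind == "pc_projection":
        if basis is None:
            raise ValueError("pc_projection requires a fitted PC basis")
        sel = cv_spec.get("selection", "name CA")
        comp = int(cv_spec.get("component", 0))
        X = np.array([f.coords[select(f, sel).indices].reshape(-1) for f in frames])
        values = list(project(X, basis, comp))
    else:
        raise ValueError(f"unknown cv kind {kind!r}")
    return pd.DataFrame({"window": np.arange(len(frames)), "cv_value": values})


def _write_trace(result: ReplicateSet, schedule: AnnealSchedule,
                 path: Path) -> None:
    temps = schedule.temperatures()
    frames = []
    for rep in result.replicates:
        frames.append(pd.DataFrame({
            "replicate": rep.replicate_id,
            "step": np.arange(len(rep.energy_trace)),
            "temperature": temps[:len(rep.energy_trace)],
            "energy": rep.energy_trace,
        }))
    with open(path, "w") as fh:
        fh.write("# annealing energy traces: replicate, step, temperature "
                 "proxy, path energy (A)\n")
        pd.concat(frames).to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full path-generation pipeline; returns the run directory."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        start = structio.read_structure(config.start)
        end = structio.read_structure(config.end)
        ligand_start = ligand_end = None
        if config.ligand_resname:
            lig_sel = f"resname {config.ligand_resname}"
            prot_sel = f"not resname {config.ligand_resname}"

            def split(frame):
                ls = select(frame, lig_sel)
                ps = select(frame, prot_sel)
                lig = StructureFrame([frame.atoms[i] for i in ls.indices],
                                     frame.coords[ls.indices])
                prot = StructureFrame([frame.atoms[i] for i in ps.indices],
                                      frame.coords[ps.indices])
                return prot, lig

            start, ligand_start = split(start)
            end, ligand_end = split(end)

        stage = "superpose"
        sup = superpose(end, start, config.superpose_selection)
        end = apply_transform(end, sup.rotation, sup.translation)
        logger.info("superposed end state onto start: RMSD %.3f A on %s",
                    sup.rmsd, config.superpose_selection)

        stage = "morph"
        path = linear_morph(start, end, config.n_windows)
        if ligand_start is not None:
            lig_end_moved = apply_transform(ligand_end, sup.rotation, sup.translation)
            path = interpolate_ligand(path, ligand_start, lig_end_moved)

        stage = "ensembles"
        backend = make_backend(config.backend, config.backend_options)
        ensemble = generate_ensembles(path, backend, config.n_models,
                                      seed=config.seed)
        save_ensemble(ensemble, out / "ensembles", backend.name,
                      config.seed, targets=path)
        logger.info("generated %d x %d model ensembles (backend %s)",
                    ensemble.n_windows, config.n_models, backend.name)

        stage = "anneal"
        schedule = config.schedule()
        # annealing seeds live in their own stream, offset from the
        # ensemble seeds by a documented constant
        anneal_base = config.seed + 100_000
        result = run_replicates(ensemble, schedule,
                                n_replicates=config.n_replicates,
                                base_seed=anneal_base)
        chosen = [ensemble.frame(w, m)
                  for w, m in enumerate(result.best_path.p)]
        _write_trace(result, schedule, out / "anneal_trace.tsv")
        logger.info("annealed %d replicates; best energy %.4f A",
                    config.n_replicates, result.energy)

        stage = "embed"
        clash_report = None
        if config.membrane:
            template = MembraneSystem.from_frame(
                structio.read_structure(config.membrane))
            params = EmbedParams(**config.embed_params)
            embedded = []
            clash_rows = []
            for w, frame in enumerate(chosen):
                system, report = embed(frame, template, params)
                embedded.append(system.to_frame())
                clash_rows.append({
                    "window": w,
                    "clashes": clash_count(system, params.clash_cutoff),
                    "lipids": len(system.lipids),
                    "lipids_deleted": report.lipids_deleted,
                })
            chosen = embedded
            clash_report = pd.DataFrame(clash_rows)
            with open(out / "embed_report.tsv", "w") as fh:
                fh.write("# per-window membrane embedding: residual clash "
                         "pairs and lipid counts\n")
                clash_report.to_csv(fh, sep="\t", index=False)

        stage = "write"
        windows_dir = out / "windows"
        windows_dir.mkdir(exist_ok=True)
        window_files = []
        for w, frame in enumerate(chosen):
            p = windows_dir / f"window_{w:03d}.pdb"
            structio.write_structure(frame.renumber_serials(), p)
            window_files.append(p)
        # embedded windows can differ in lipid count, so the multi-model
        # path file is only written when all windows share one topology
        renumbered = [f.renumber_serials() for f in chosen]
        if all(f.same_topology(renumbered[0]) for f in renumbered[1:]):
            structio.write_path(renumbered, out / "path.pdb")

        stage = "restraints"
        centers = compute_restraint_centers(chosen, config.cv_spec)
        with open(out / "restraint_centers.tsv", "w") as fh:
            fh.write("# umbrella restraint centers computed on generated "
                     "window frames (pre-equilibration)\n")
            fh.write(f"# cv: {config.cv_spec}\n")
            centers.to_csv(fh, sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "seeds": {
                "ensemble_base": config.seed,
                "ensemble_per_window": "seed + window_index",
                "anneal_base": anneal_base,
                "anneal_per_replicate": "anneal_base + replicate",
            },
            "result": {
                "best_energy": float(result.energy),
                "best_replicate": int(result.best.replicate_id),
                "chosen_models": [int(i) for i in result.best_path.p],
            },
            "outputs": {
                "windows": [f.name for f in window_files],
                "window_sha256": {f.name: _sha256(f) for f in window_files},
            },
            "elapsed_s": round(time.time() - t_start, 3),
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
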