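"""Collective-variable design from path and trajectory coordinate sets.

For two-dimensional umbrella sampling the biasing coordinates are built from
a principal-component analysis of Cα positions over concatenated path /
trajectory frames, all superposed to one reference.  PC 1 typically tracks
the main transition coordinate; where several independently seeded path
replicates disagree, a second CV is designed as the unit-norm linear
combination of higher PCs (by default PCs 2–16) that best *separates* the
replicates, found by maximising an entropy-like score

    S = sum_n sum_{i<j} ln( |c(n, i) - c(n, j)| + eps )

over windows ``n`` and replicate pairs ``(i, j)``, where ``c(n, i)`` is the
projection of replicate ``i``'s window-``n`` frame onto the candidate
combination.  The log rewards spreading every pair apart while saturating
for already-separated ones; ``eps`` keeps coincident projections finite.
The maximisation uses differential evolution; the score depends only on the
direction of the weight vector, so candidates are normalised before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from sklearn.decomposition import PCA

from .frames import Selection, StructureFrame, select
from .geometry import DegenerateFitError, superpose

__all__ = [
    "TrajectoryMatrix",
    "PCBasis",
    "CVCombination",
    "fit_pca",
    "project",
    "replicate_separation_score",
    "optimize_combination",
    "variance_report",
]

DEFAULT_EPSILON = 1e-8
#: 0-based component indices of the default combination subspace (PCs 2-16,
#: 1-based, i.e. everything after the main transition coordinate up to the
#: point where >75% of variance is typically explained)
DEFAULT_PC_INDICES = tuple(range(1, 16))


@dataclass
class TrajectoryMatrix:
    """F × (3A) coordinate table over a fixed atom selection, superposed.

    Built with :meth:`from_frames`, which superposes every frame onto the
    reference (the first frame by default) on the chosen selection before
    flattening, so rigid-body motion does not leak into the PCA.
    """

    X: np.ndarray
    frame_labels: list[tuple] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("trajectory matrix must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite values in trajectory matrix")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_frames(cls, frames: Sequence[StructureFrame],
                    subset: Selection | str = "name CA",
                    reference: StructureFrame | None = None,
                    labels: Sequence[tuple] | None = None) -> "TrajectoryMatrix":
        if not frames:
            raise ValueError("no frames")
        ref = reference if reference is not None else frames[0]
        ref_sub = ref.coords[select(ref, subset).indices]
        rows = []
        for f in frames:
            sub = f.coords[select(f, subset).indices]
            try:
                sup = superpose(f, ref, subset)
                moved = sub @ sup.rotation.T + sup.translation
            except DegenerateFitError:
                # collinear selection: rotation underdetermined, align centroids
                moved = sub - sub.mean(axis=0) + ref_sub.mean(axis=0)
            rows.append(moved.reshape(-1))
        return cls(np.array(rows), list(labels) if labels is not None else None)


@dataclass
class PCBasis:
    """Mean, orthonormal components (rows) and explained-variance fractions."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class CVCombination:
    """A unit-norm linear combination of principal components and its score."""

    pc_indices: tuple[int, ...]
    weights: np.ndarray
    score: float

    def direction(self, basis: PCBasis) -> np.ndarray:
        """The combined 3A-dimensional unit vector in coordinate space."""
        return self.weights @ basis.components[list(self.pc_indices)]


def fit_pca(traj: TrajectoryMatrix | np.ndarray) -> PCBasis:
    """PCA of the coordinate covariance about the mean.

    Components are ordered by decreasing variance and sign-fixed so the
    largest-magnitude loading of each is positive (stable CV definitions
    across runs).  Rank-deficient data keeps its zero-variance components
    (reported with zero explained variance) rather than dropping them.
    """
    X = traj.X if isinstance(traj, TrajectoryMatrix) else np.asarray(traj, float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for k in range(len(comps)):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    return PCBasis(pca.mean_.copy(), comps,
                   pca.explained_variance_.copy(),
                   pca.explained_variance_ratio_.copy())


def _as_matrix(frames) -> np.ndarray:
    if isinstance(frames, TrajectoryMatrix):
        return frames.X
    X = np.asarray(frames, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def project(frames, basis: PCBasis, component_index: int) -> np.ndarray:
    """Project mean-centered frames onto one principal component."""
    X = _as_matrix(frames)
    if X.shape[1] != basis.components.shape[1]:
        raise ValueError(
            f"frame dimension {X.shape[1]} does not match basis "
            f"{basis.components.shape[1]}")
    return (X - basis.mean) @ basis.components[component_index]


def project_combination(frames, basis: PCBasis, pc_indices: Sequence[int],
                        weights: np.ndarray) -> np.ndarray:
    """Project frames onto a weighted combination of components."""
    X = _as_matrix(frames)
    direction = np.asarray(weights, float) @ basis.components[list(pc_indices)]
    return (X - basis.mean) @ direction


def replicate_separation_score(projections: np.ndarray,
                               epsilon: float = DEFAULT_EPSILON) -> float:
    """Entropy-like separation score over a (windows × replicates) table.

    ``S = sum_n sum_{i<j} ln(|c(n,i) - c(n,j)| + epsilon)``; larger is more
    separated.  Invariant to replicate relabelling and window reordering,
    strictly increasing in every single pair distance.
    """
    C = np.asarray(projections, dtype=float)
    if C.ndim != 2:
        raise ValueError("projections must be (n_windows, n_replicates)")
    if not np.all(np.isfinite(C)):
        raise ValueError("missing or non-finite projection values")
    n_rep = C.shape[1]
    total = 0.0
    for i in range(n_rep):
        for j in range(i + 1, n_rep):
            total += float(np.sum(np.log(np.abs(C[:, i] - C[:, j]) + epsilon)))
    return total


def optimize_combination(basis: PCBasis,
                         replicate_frames: Sequence,
                         pc_indices: Sequence[int] = DEFAULT_PC_INDICES,
                         seed: int = 0,
                         epsilon: float = DEFAULT_EPSILON,
                         maxiter: int = 300,
                         popsize: int = 30) -> CVCombination:
    """Best replicate-separating unit-norm combination of the chosen PCs.

    ``replicate_frames`` holds one (windows × 3A) coordinate matrix (or
    :class:`TrajectoryMatrix`) per path replicate, all with the same window
    count.  Differential evolution searches weight space; every candidate is
    normalised before scoring since the score depends on direction only.
    Reproducible under ``seed``.
    """
    mats = [_as_matrix(m) for m in replicate_frames]
    if len(mats) < 2:
        raise ValueError("need at least 2 replicates to separate")
    n_windows = mats[0].shape[0]
    for m in mats:
        if m.shape[0] != n_windows:
            raise ValueError("replicates must share the window count")
    pc_indices = tuple(int(i) for i in pc_indices)
    if max(pc_indices) >= basis.n_components:
        raise ValueError("pc_indices beyond the retained components")
    comps = basis.components[list(pc_indices)]
    centered = np.stack([(m - basis.mean) @ comps.T for m in mats], axis=2)
    # centered: (windows, len(pc_indices), replicates)

    def negative_score(w: np.ndarray) -> float:
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            return 1e12
        u = w / norm
        C = np.einsum("k,wkr->wr", u, centered)
        return -replicate_separation_score(C, epsilon)

    bounds = [(-1.0, 1.0)] * len(pc_indices)
    result = differential_evolution(negative_score, bounds, seed=seed,
                                    maxiter=maxiter, popsize=popsize,
                                    tol=1e-10, polish=True, init="sobol")
    w = result.x / np.linalg.norm(result.x)
    # canonical sign: largest-magnitude weight positive (score is sign-blind)
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        w = -w
    return CVCombination(pc_indices, w, -float(result.fun))


def variance_report(basis: PCBasis,
                    thresholds: Sequence[float] = (0.5, 0.75, 0.9)) -> pd.DataFrame:
    """Smallest number of leading components reaching each cumulative
    explained-variance threshold."""
    cum = np.cumsum(basis.explained_variance_ratio)
    rows = []
    for t in thresholds:
        reached = np.nonzero(cum >= t - 1e-12)[0]
        rows.append({"threshold": t,
                     "k": int(reached[0]) + 1 if len(reached) else None,
                     "cumulative": float(cum[reached[0]]) if len(reached) else float(cum[-1])})
    return pd.DataFrame(rows)
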