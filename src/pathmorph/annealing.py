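"""Monte Carlo simulated annealing over model ensembles.

With ``N`` windows and ``M`` candidate models per window there are ``M**N``
possible paths — astronomically many for production sizes — so a smooth path
is found stochastically.  A path is a vector ``p`` of one model index per
window; its roughness energy is the root-mean-square of raw heavy-atom RMSDs
between neighbouring chosen frames,

    E(p) = sqrt( (1/(N-1)) * sum_n rmsd(frame(p[n], n), frame(p[n+1], n+1))^2 )

which penalises discontinuities through the quadratic term, like a strain
energy.  Neighbour RMSDs are computed *without* re-superposition: all models
were built against morph targets in one shared laboratory frame, and
re-fitting would hide genuine rigid-body jumps.

A Monte Carlo step swaps the model at one randomly chosen (interior, when
endpoints are pinned) window for a random alternative and applies the
Metropolis criterion under a dimensionless temperature proxy that decays
geometrically from ``T0 = 50`` to ``T_end = 0.1`` over ``s_max = 10**4``
steps.  Twelve independent replicates are run by default and the
minimum-energy path sampled anywhere in the combined runs is returned — the
goal is an appropriately smooth path, not a certified global optimum.

Exact small-instance solvers (:func:`exhaustive_search` and the
dynamic-programming :func:`dp_search`, exact because the energy is a
monotone function of a sum of per-edge costs) are provided as oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ensembles import ModelEnsemble
from .frames import Selection, select

__all__ = [
    "AnnealSchedule",
    "PathState",
    "AnnealResult",
    "ReplicateSet",
    "EdgeCosts",
    "path_energy",
    "temperature",
    "mc_step",
    "StepOutcome",
    "anneal",
    "run_replicates",
    "exhaustive_search",
    "dp_search",
]

DEFAULT_T0 = 50.0
DEFAULT_S_MAX = 10_000
DEFAULT_T_END = 0.1
DEFAULT_N_REPLICATES = 12


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric temperature-proxy schedule ``T(s) = T0 * (T_end/T0)**(s/s_max)``."""

    T0: float = DEFAULT_T0
    s_max: int = DEFAULT_S_MAX
    T_end: float = DEFAULT_T_END
    form: str = "geometric"

    def __post_init__(self):
        if self.T0 <= 0 or self.T_end <= 0:
            raise ValueError("temperatures must be positive")
        if self.T_end >= self.T0:
            raise ValueError("T_end must be below T0 for an annealing schedule")
        if self.s_max < 1:
            raise ValueError("s_max must be >= 1")
        if self.form != "geometric":
            raise ValueError(f"unknown schedule form {self.form!r}")

    def temperatures(self) -> np.ndarray:
        s = np.arange(self.s_max)
        return self.T0 * (self.T_end / self.T0) ** (s / self.s_max)


def temperature(schedule: AnnealSchedule, s: int) -> float:
    """Temperature proxy at step ``s`` (0 ≤ s ≤ s_max)."""
    if not 0 <= s <= schedule.s_max:
        raise ValueError(f"step {s} outside [0, {schedule.s_max}]")
    return float(schedule.T0 * (schedule.T_end / schedule.T0) ** (s / schedule.s_max))


@dataclass(frozen=True)
class PathState:
    """One model index per window."""

    p: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p", np.asarray(self.p, dtype=int))

    def __len__(self) -> int:
        return len(self.p)

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(int(i) for i in self.p)


@dataclass
class AnnealResult:
    """Outcome of one annealing run: best path visited, its energy and the trace."""

    best_path: PathState
    energy: float
    energy_trace: np.ndarray
    seed: int
    replicate_id: int = 0
    accepted_steps: int = 0


@dataclass
class ReplicateSet:
    """All replicate runs plus the overall minimum-energy result."""

    replicates: list[AnnealResult]

    @property
    def best(self) -> AnnealResult:
        return min(self.replicates, key=lambda r: r.energy)

    @property
    def best_path(self) -> PathState:
        return self.best.best_path

    @property
    def energy(self) -> float:
        return self.best.energy


class EdgeCosts:
    """Precomputed squared neighbour RMSDs for every model pair of every edge.

    ``d2[n][i, j]`` is the squared raw RMSD (over the scoring subset, heavy
    atoms by default) between model ``i`` of window ``n`` and model ``j`` of
    window ``n+1``.  The annealer, the exact solvers and ``path_energy`` all
    draw from this table, so they agree to rounding.
    """

    def __init__(self, d2: list[np.ndarray], sizes: list[int],
                 pinned_endpoints: bool):
        self.d2 = d2
        self.sizes = sizes
        self.pinned_endpoints = pinned_endpoints

    @classmethod
    def from_ensemble(cls, ensemble: ModelEnsemble,
                      subset: Selection | str | None = None) -> "EdgeCosts":
        topo = ensemble.topology
        sel = select(topo, "heavy" if subset is None else subset)
        stacks = []
        for models in ensemble.windows:
            X = np.stack([m.coords[sel.indices] for m in models])
            stacks.append(X.reshape(len(models), -1))
        k = stacks[0].shape[1] / 3  # atoms in the scoring subset
        d2 = []
        for A, B in zip(stacks[:-1], stacks[1:]):
            sq = (np.einsum("ik,ik->i", A, A)[:, None]
                  + np.einsum("jk,jk->j", B, B)[None, :]
                  - 2.0 * A @ B.T) / k
            d2.append(np.maximum(sq, 0.0))
        return cls(d2, ensemble.sizes, ensemble.pinned_endpoints)

    @property
    def n_windows(self) -> int:
        return len(self.sizes)

    def validate(self, p: np.ndarray) -> None:
        if len(p) != self.n_windows:
            raise ValueError(f"path length {len(p)} != {self.n_windows} windows")
        for n, (idx, size) in enumerate(zip(p, self.sizes)):
            if not 0 <= idx < size:
                raise IndexError(f"model index {idx} out of range at window {n}")

    def sumsq(self, p: Sequence[int]) -> float:
        return float(sum(self.d2[n][p[n], p[n + 1]] for n in range(self.n_windows - 1)))

    def energy(self, p: Sequence[int]) -> float:
        return math.sqrt(self.sumsq(p) / (self.n_windows - 1))

    def interior_windows(self) -> list[int]:
        if self.pinned_endpoints:
            return list(range(1, self.n_windows - 1))
        return list(range(self.n_windows))


def _as_costs(ensemble_or_costs, subset=None) -> EdgeCosts:
    if isinstance(ensemble_or_costs, EdgeCosts):
        return ensemble_or_costs
    return EdgeCosts.from_ensemble(ensemble_or_costs, subset)


def path_energy(ensemble: ModelEnsemble | EdgeCosts, p: PathState | Sequence[int],
                subset: Selection | str | None = None) -> float:
    """Path-roughness energy: RMS of neighbour heavy-atom raw RMSDs, in Å."""
    costs = _as_costs(ensemble, subset)
    pv = p.p if isinstance(p, PathState) else np.asarray(p, dtype=int)
    costs.validate(pv)
    return costs.energy(pv)


@dataclass
class StepOutcome:
    state: PathState
    accepted: bool
    delta_e: float
    window: int
    proposal: int


def mc_step(ensemble: ModelEnsemble | EdgeCosts, state: PathState, T: float,
            rng: np.random.Generator) -> StepOutcome:
    """One Metropolis step: propose a model swap at one (interior) window.

    Draws exactly three variates — window choice, model choice, acceptance
    uniform — whether or not they are all needed, so chains are reproducible.
    Downhill proposals are always accepted; uphill with probability
    ``exp(-dE/T)``.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    costs = _as_costs(ensemble)
    p = state.p
    costs.validate(p)
    interior = costs.interior_windows()
    uw, um, ua = rng.random(3)
    w = interior[int(uw * len(interior))]
    m = int(um * costs.sizes[w])
    old = int(p[w])
    N = costs.n_windows
    old_sum = new_sum = 0.0
    if w > 0:
        old_sum += costs.d2[w - 1][p[w - 1], old]
        new_sum += costs.d2[w - 1][p[w - 1], m]
    if w < N - 1:
        old_sum += costs.d2[w][old, p[w + 1]]
        new_sum += costs.d2[w][m, p[w + 1]]
    base = costs.sumsq(p)
    e_old = math.sqrt(base / (N - 1))
    e_new = math.sqrt(max(base - old_sum + new_sum, 0.0) / (N - 1))
    d_e = e_new - e_old
    accept = d_e <= 0 or ua < math.exp(-d_e / T)
    if accept:
        q = p.copy()
        q[w] = m
        return StepOutcome(PathState(q), True, d_e, w, m)
    return StepOutcome(state, False, d_e, w, m)


def anneal(ensemble: ModelEnsemble | EdgeCosts,
           schedule: AnnealSchedule | None = None,
           seed: int = 0, replicate_id: int = 0) -> AnnealResult:
    """One annealing run: ``s_max`` Metropolis steps under the cooling schedule.

    The path is initialised with uniformly random model indices, and the
    *minimum-energy state visited anywhere in the run* is returned — not the
    final state.  Identical (ensemble, schedule, seed) give bitwise-identical
    results.
    """
    schedule = schedule or AnnealSchedule()
    costs = _as_costs(ensemble)
    N = costs.n_windows
    rng = np.random.default_rng(seed)
    p = [int(rng.integers(size)) for size in costs.sizes]
    if costs.pinned_endpoints:
        p[0] = 0
        p[-1] = 0
    interior = costs.interior_windows()
    if not interior:
        e = costs.energy(p)
        return AnnealResult(PathState(np.array(p)), e, np.array([e]), seed,
                            replicate_id)
    s_max = schedule.s_max
    temps = schedule.temperatures().tolist()
    # pregenerate the three per-step variates (window, model, acceptance)
    uw = rng.random(s_max).tolist()
    um = rng.random(s_max).tolist()
    ua = rng.random(s_max).tolist()
    d2 = [m.tolist() for m in costs.d2]
    sizes = costs.sizes
    n_int = len(interior)
    inv = 1.0 / (N - 1)
    sumsq = sum(d2[n][p[n]][p[n + 1]] for n in range(N - 1))
    energy = math.sqrt(sumsq * inv)
    best_e = energy
    best_p = list(p)
    trace = []
    accepted = 0
    exp = math.exp
    sqrt = math.sqrt
    for s in range(s_max):
        w = interior[int(uw[s] * n_int)]
        m = int(um[s] * sizes[w])
        old = p[w]
        delta = 0.0
        if w > 0:
            row = d2[w - 1][p[w - 1]]
            delta += row[m] - row[old]
        if w < N - 1:
            nxt = p[w + 1]
            delta += d2[w][m][nxt] - d2[w][old][nxt]
        new_sumsq = sumsq + delta
        if new_sumsq < 0.0:
            new_sumsq = 0.0
        new_e = sqrt(new_sumsq * inv)
        d_e = new_e - energy
        if d_e <= 0.0 or ua[s] < exp(-d_e / temps[s]):
            p[w] = m
            sumsq = new_sumsq
            energy = new_e
            accepted += 1
            if energy < best_e:
                best_e = energy
                best_p = list(p)
        trace.append(energy)
    best = np.array(best_p)
    # recompute exactly from the table so the stored energy matches
    # path_energy to rounding, free of incremental drift
    return AnnealResult(PathState(best), costs.energy(best), np.array(trace),
                        seed, replicate_id, accepted)


def run_replicates(ensemble: ModelEnsemble | EdgeCosts,
                   schedule: AnnealSchedule | None = None,
                   n_replicates: int = DEFAULT_N_REPLICATES,
                   base_seed: int = 0) -> ReplicateSet:
    """Independent annealing replicates (seeds ``base_seed + r``).

    Returns all runs; ``.best`` is the minimum-energy path sampled across
    the combined replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    costs = _as_costs(ensemble)
    results = [anneal(costs, schedule, seed=base_seed + r, replicate_id=r)
               for r in range(n_replicates)]
    return ReplicateSet(results)


_EXHAUSTIVE_GUARD = 10 ** 6


def exhaustive_search(ensemble: ModelEnsemble | EdgeCosts) -> tuple[PathState, float]:
    """Exact global minimum by enumerating every path (small instances only)."""
    costs = _as_costs(ensemble)
    free = costs.interior_windows()
    space = 1
    for w in free:
        space *= costs.sizes[w]
        if space > _EXHAUSTIVE_GUARD:
            raise ValueError(
                f"search space exceeds {_EXHAUSTIVE_GUARD}; use dp_search or anneal")
    p = np.zeros(costs.n_windows, dtype=int)
    best_p, best_sum = None, math.inf
    for combo in itertools.product(*(range(costs.sizes[w]) for w in free)):
        p[free] = combo
        s = costs.sumsq(p)
        if s < best_sum:
            best_sum = s
            best_p = p.copy()
    return PathState(best_p), math.sqrt(best_sum / (costs.n_windows - 1))


def dp_search(ensemble: ModelEnsemble | EdgeCosts) -> tuple[PathState, float]:
    """Exact global minimum by dynamic programming over windows.

    The energy is a monotone function of the sum of per-edge squared RMSDs,
    so a Viterbi pass minimising that sum yields the exact optimum in
    ``O(N * M^2)`` regardless of ensemble size.
    """
    costs = _as_costs(ensemble)
    N = costs.n_windows
    if costs.pinned_endpoints:
        starts = [0]
        ends = [0]
    else:
        starts = list(range(costs.sizes[0]))
        ends = list(range(costs.sizes[-1]))
    INF = math.inf
    cost0 = np.full(costs.sizes[0], INF)
    cost0[starts] = 0.0
    back: list[np.ndarray] = []
    cur = cost0
    for n in range(N - 1):
        total = cur[:, None] + costs.d2[n]
        argmin = np.argmin(total, axis=0)
        back.append(argmin)
        cur = total[argmin, np.arange(costs.sizes[n + 1])]
    mask = np.full(costs.sizes[-1], INF)
    mask[ends] = 0.0
    final = cur + mask
    j = int(np.argmin(final))
    best_sum = float(final[j])
    p = np.zeros(N, dtype=int)
    p[-1] = j
    for n in range(N - 2, -1, -1):
        p[n] = back[n][p[n + 1]]
    return PathState(p), math.sqrt(best_sum / (N - 1))
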