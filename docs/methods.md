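# Methods

This note documents the models and procedures implemented in `pathmorph`,
the parameter choices that matter, what the synthetic fixtures do and do not
emulate, and the numerical decisions a maintainer should know about.

## Coordinate model and correspondence

All coordinates are held in Ångström; GRO files (nm on disk) are converted
on read and write. Atoms correspond between end states by the
(chain, residue number, atom name) triple — serials routinely differ between
deposited structures and are ignored for matching. Duplicated triples
(alternate locations, insertion codes) are rejected at read time rather than
silently disambiguated. Hydrogen detection uses the element column when
present and otherwise a name heuristic (leading digits stripped, `H`-initial
names are hydrogens, with a short list of genuine two-letter elements
checked first).

## Morphing

The morph is the exact convex combination of corresponding coordinates;
window 0 and window N−1 carry the input coordinates bitwise. All atoms are
interpolated, hydrogens included, because the downstream fixing backends
need complete structures even though path scoring later uses heavy atoms
only. End states are superposed on all Cα atoms by default before morphing
(configurable); restricting the fit to a subdomain is a per-system choice
exposed through the same selection language. Consequences tested as
invariants: neighbour raw RMSDs are a constant RMSD(start, end)/(N−1), and
morph(A→B) reversed equals morph(B→A).

Ligands are carried rigidly: the start pose's internal conformation with
the heavy-atom centre of mass translated by the window fraction of the
start→end COM displacement. The alternative mode (plain linear
interpolation of ligand coordinates, `rigid=False`) is implemented but not
recommended without a downstream minimiser, since it does not preserve
ligand geometry.

## Fixing backends

The backend contract is: given a target frame, return `n_models` frames on
the same topology, each within a declared heavy-atom RMSD bound of the
target, deterministically for a given seed. Per-window seeds are
`seed + window_index`, so any window can be regenerated independently.
Endpoints are pinned by default (windows 0 and N−1 keep exactly the end
states); this guarantees the final path terminates at the experimental
structures and can be switched off.

Two backends ship:

* `JitterBackend` — isotropic Gaussian noise of standard deviation `scale`
  per Cartesian component on heavy atoms (expected RMSD `scale·√3`,
  declared bound `3·scale`), optionally followed by a SHAKE-like projection
  of bonded distances back to ideal values. It reproduces the *structure*
  of the production problem (within-window spread, between-window
  discontinuities) without any statistical potential.
* `CommandBackend` — a subprocess adapter around an external template-based
  modelling program (shell template with `{input}`, `{output_dir}`,
  `{n_models}`, `{seed}` placeholders, reading `model_*.pdb` back). Its
  RMSD bound is user-declared because how tightly an external program
  restrains models to its template is program- and option-dependent. It is
  deliberately outside the test matrix.

`regularize_geometry` iterates symmetric two-atom projections of each bond
to its ideal length until the worst residual is below tolerance (default
0.01 Å) or `max_iters` sweeps (default 200) are exhausted, then warns with
the residual. Coincident atoms are split along x as a tie-break.

## Path energy and annealing

The roughness energy is the root-mean-square of neighbour heavy-atom raw
RMSDs. Two decisions here:

* **RMS versus sum of squares.** Minimising the RMS and minimising the sum
  of squared neighbour RMSDs are equivalent at fixed window count (monotone
  transform); the RMS is reported because it reads as an Å-scale mean
  discontinuity. Acceptance probabilities use ΔE of the RMS form, so
  reported temperatures are calibrated against that scale.
* **No re-superposition between neighbours.** All models are built against
  morph targets in one shared laboratory frame; re-fitting frames before
  the neighbour RMSD would hide genuine rigid-body discontinuities that the
  annealer exists to remove. A fitted variant is available through the
  RMSD primitive for diagnostics.

The temperature proxy decays geometrically from T₀ = 50 to T_end = 0.1 over
s_max = 10⁴ steps; T₀ and s_max are the documented operating defaults, and
T_end = 0.1 was chosen so the chain ends effectively quenched (acceptance
of typical ΔE ≈ 0.05 Å falls below 1%) while keeping T(s) > 0 throughout.
A Monte Carlo step proposes a uniformly chosen interior window and a
uniformly chosen replacement model, consuming exactly three random variates
(window, model, acceptance) per step so chains are bitwise reproducible;
the proposal may equal the incumbent, which is counted as an accepted
null move. Twelve replicates run from seeds `base_seed + r`, and the
minimum-energy state *visited* anywhere (not the final state) is returned.
The goal is a suitably smooth path, not a certified optimum.

Implementation: per-edge squared-RMSD matrices are precomputed once per
ensemble (`EdgeCosts`), so annealing steps are table lookups and a 12 ×
10⁴-step run takes well under a second at production sizes. The result's
energy is recomputed exactly from the chosen path at the end, keeping the
stored energy equal to `path_energy` to 1e-10 despite incremental updates
during the chain.

Two exact solvers serve as oracles: full enumeration (guarded at 10⁶
paths) and a dynamic-programming shortest path, exact because the energy is
monotone in the sum of per-edge squared costs.

## Membrane embedding

The template bilayer is re-packed around each new conformation by:
replace protein (superposed onto the template protein on shared atoms) →
stretch lipid COMs and box in-plane by 1 + 0.15 → delete lipids with any
heavy atom within 2.0 Å of a protein heavy atom → 5 cycles of [compress by
1 − 0.04; relax]. Lipids move only as rigid bodies in the plane: COM
affine scaling about the box centre, per-lipid translations during
relaxation; internal geometry and z-coordinates are untouched end to end.

The stretch (15%), cycle count (5) and compression (4%) are the operating
defaults and are customizable per system. The clash criterion
(heavy-atom pairs under 2.0 Å, minimum image, counted with a periodic
KD-tree and verified in tests against brute-force image enumeration) and
the deletion of post-stretch clashing lipids are this package's explicit,
deterministic stand-ins for what is otherwise a manual packing judgement.
The built-in relaxer is a soft-sphere steepest descent on per-lipid
in-plane displacements with interaction range 1.2 × cutoff (so relaxed
systems end with clearance, not grazing contacts); a move is kept only if
the protein–lipid clash count does not increase, and the step is halved
otherwise. A force-field minimiser can be substituted through the same
interface. Boxes are orthorhombic only; hexagonal boxes are a known gap.

## CV design

PCA is fitted on the coordinate covariance of superposed frames over a
fixed selection (Cα by default; frames are aligned to the first frame of
the concatenated set, with a centroid-only fallback when the selection is
collinear). Component signs are fixed (largest-magnitude loading positive)
so CV definitions are stable across runs. Rank-deficient data keeps its
zero-variance components, reported as zeros.

The replicate-separation score is
S = Σₙ Σ_{i<j} ln(|c(n,i) − c(n,j)| + ε) with ε = 1e-8 guarding coincident
projections; it is invariant to replicate relabelling and window
reordering and strictly increasing in every pair distance. Distances are
taken between per-window *projections* of the replicate frames onto the
candidate combination (not full-coordinate distances projected
afterwards). The score depends only on the weight direction, so
differential-evolution candidates are normalised before scoring; the
default subspace is PCs 2–16 (1-based), a configuration value rather than
a constant. Determinism comes from the optimiser seed.

## Synthetic fixtures

* Polyalanine conformers are rebuilt from ideal internal coordinates
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C–O 1.231 Å, CA–CB 1.521 Å;
  standard backbone angles; trans peptide) at canonical α-helical
  (−57°, −47°) and extended (−139°, 135°) dihedrals. They exercise I/O,
  selections and morphing with realistic atom naming.
* Bead chains (Cα-only, 3.8 Å spacing, line/arc/sine shapes) are the
  default annealer fixture: cheap and geometrically unambiguous.
* Planted ensembles hide one exact-morph model per interior window at a
  seed-dependent index among decoys jittered by at least a prescribed
  RMSD; the planted path is verified at generation time to beat every
  single-model swap, making it the known global optimum at the jitter
  levels used in testing.
* Toy membranes are lattices of vertical bead "lipids" with a bead
  cylinder standing in for a membrane protein.

What passing on these fixtures shows: the algebra, bookkeeping, determinism
and optimisation behaviour of every stage. What it does not show: that any
particular modelling backend produces chemically sensible ensembles for
real proteins, that real bilayers re-pack at these parameter values, or
that the designed CVs capture the slow modes of a real transition — those
depend on the external modelling program, force field and system, which are
outside this package's scope.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen to make
every ground truth exactly checkable: 6–8 window ensembles with 3–5 models
(81–15 625 paths, enumerable), 100 random annealer instances, 20 planted
seeds, 10⁵ Metropolis proposals, 36–64-lipid membranes, 50-frame PCA sets,
and one full default-parameter run (24 windows × 50 models × 12
replicates) on the polyalanine pair. Production use scales only the inputs,
not the algorithms.

## Known limitations

* The external modelling backend is untested here by design; its contract
  (topology preservation, RMSD bound, seed determinism) is what the rest of
  the pipeline relies on.
* Rigid-COM ligand carriage assumes the ligand does not change internal
  conformation along the transition; large ligand rearrangements need a
  different treatment.
* The soft-sphere relaxer resolves steric overlap only; it knows nothing of
  lipid thermodynamics (area per lipid, order parameters).
* Orthorhombic boxes only; hexagonal membrane patches are not supported.
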