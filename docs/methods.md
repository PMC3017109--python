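# Methods

## Elastic network model

The protein is reduced to one Cα per residue. Springs join every residue
pair whose reference distance is below the cutoff `R_c` (default 10 Å), at
the reference distance as rest length. Sequential same-chain neighbours
(`|Δresnum| = 1`) are treated as chemically bonded: they always carry a
spring with `k_bonded = 10`, *even beyond the cutoff*, so the backbone can
never be severed by a cutoff or mask choice. All other springs have
`k_nonbonded = 1`. Force-constant units are arbitrary — they set the energy
scale but cancel out of pathways and fractional-progress values, which are
the interpretable outputs. There is no mass weighting (uniform Cα masses).

Normal modes are eigenpairs of the analytic 3N×3N sparse Hessian at the
reference. A dense symmetric solver is used up to 1200 degrees of freedom,
shift-invert Lanczos (`sigma = −1e−6`) above. The six smallest-magnitude
eigenvalues are discarded as rigid translations/rotations; if a seventh
near-zero mode appears (gap ratio below 1e6 and eigenvalue below 1e−8) the
network is reported disconnected, naming the components. Eigenvector signs
are fixed (first component of magnitude > 1e−8 made positive) so runs are
bit-reproducible.

A cutoff scan helper (`scan_cutoff`, default grid 8–16 Å in 1 Å steps)
reports the cumulative overlap of the lowest modes with an observed
conformational change; no particular optimum is asserted.

## Transition pathway

Two wells `E1`, `E2` are anchored at the begin conformation and at the
*alignment-completed end target*: the end structure is rigid-body
superposed onto the begin structure over the aligned residue pairs (uniform
weights), and its mapped coordinates fill the target array in begin
indexing. Residues without an end-state position (unaligned) keep their
begin coordinates in the target, contribute **no non-bonded springs** to
`E2`, and their bonded springs in `E2` take rest lengths from the begin
conformation — the chain stays intact while nothing pretends to know their
open-form position.

The saddle-point curve of any double-well mixture of `E1` and `E2` is swept
by minimizing the linearly interpolated potential
`λ E1 + (1−λ) E2 + E_coll` for λ descending from 1 to 0. Each λ is solved
by Newton iteration warm-started from the previous solution:

* the linearized system uses the exact sparse Hessian plus a diagonal shift
  of `1e−8 ×` its largest diagonal entry, which regularizes the rigid-body
  null space (the operator is exactly singular along rigid motions);
* steps are backtracked (halved, up to 30 times) whenever the gradient
  ∞-norm does not decrease;
* convergence is declared at gradient ∞-norm ≤ 1e−8 (model units/Å), and
  each converged conformation is re-superposed rigidly onto the begin
  structure **over aligned residues only**, so freely relaxing unaligned
  tails cannot drag the frame.

The base λ schedule is 201 uniform steps, with adaptive bisection whenever
consecutive solutions are further apart than twice the sampling increment;
the bisection makes the *sampled* pathway schedule-independent to solver
tolerance (the form-independence property is tested by re-solving with a
quadratically spaced schedule). A denser base schedule therefore only adds
cost. The converged sweep is subsampled so consecutive retained
conformations are ≥ 0.1 Å RMSD apart (begin and end always retained); the
number of intermediates is thus a property of the transition amplitude and
the increment, not of the schedule. The solver contains no randomness.

### Steric collision term

`E_coll = Σ (k_coll/2)(d_ij − d_c)² Θ(d_c − d_ij)` over non-bonded pairs,
with `k_coll = 10` and `d_c` auto-computed as the smallest non-bonded
Cα–Cα distance over both endpoint conformations — so both endpoints are
penalty-free by construction and the term only acts when an intermediate
squeezes residues closer than anything seen in either endpoint. The penalty
is C¹ at `d = d_c`. For transitions without serious steric conflict the
term is diagnostic rather than decisive; its exact algebraic form is a
package design choice satisfying the stated properties (short-range,
repulsive, bonded pairs excluded).

## Motional order

Pathway arc length is the running sum of consecutive all-atom RMSDs;
`f = l/L` is a conformation's fractional position. A residue's crossover is
located as the first sign change of
`g(t) = |x(t)−x_begin| − |x(t)−x_end|` along the path, with linear
interpolation of `f` inside the bracketing segment. Design choices:

* **Displacement floor 0.5 Å** (configurable): residues that barely move
  have no meaningful crossover; they are reported as NaN and excluded from
  motif means. The floor is reported with results.
* **First crossing** when `g` changes sign more than once — the
  conservative "begins moving" reading.
* Distances are measured in the begin frame (each conformation is already
  superposed onto the begin structure during the solve).
* Motif means average the defined values over member residues on **all
  chains in scope**; for an exactly symmetric assembly the chains agree by
  construction and the spread is a consistency diagnostic.

Comparison with experiment uses Pearson correlation of motif-mean `f`
against `1 − Φ` (high Φ = early motion). A motif-level Φ table for the
nAChR α subunit is packaged (`ELIC_PHI`), together with the ELIC motif
residue ranges (`ELIC_MOTIFS`: binding loops A/B/C, interface loops 2/7/9,
helices M1–M4, M2–M3 linker); user TSVs override both.

## Perturbation analysis

A perturbation names two residue selections and a rule (`intra_subunit`,
`inter_subunit`, `any`); the expanded pair set is removed from the
non-bonded springs of **both** wells by default (`mask_wells` can restrict
masking to one well — whether one or both wells should lose the
interactions is genuinely open, and symmetric masking is the neutral
default). Bonded pairs matching a mask are kept and logged: severing the
backbone is physically meaningless at this resolution. Masking is verified
set-exactly (masked model springs = full springs − mask) and idempotent. A
mask that disconnects the network is reported with its components.

## Pore profile

Each Cα is a hard sphere of radius 3 Å (a Cα-only stand-in for an all-atom
pore surface). At each axial sample the pore radius is the largest probe
sphere centered in the perpendicular plane that touches no atom sphere:
`max_c min_i (|c − x_i| − r_atom)`. The in-plane maximization is fully
deterministic: a 1 Å lattice over the allowed offset disk (default 10 Å)
seeds a 5×5 multi-resolution stencil search refined to 0.01 Å, warm-started
additionally from the previous sample's center. The dense stencil matters:
the clearance field is a min of cones and a 4-point compass poll stalls on
its ridges. Fully occluded planes report radius 0 with an `occluded` flag;
unconstrained planes (channel mouth) are capped at 30 Å.

In auto mode the pore axis is anchored at the assembly centroid and
oriented to minimize the *variance* of chain-centroid distances to the
axis — zero for an exactly symmetric ring, hence the symmetry axis — using
Nelder–Mead refinement of the best-fit-plane normal of the chain centroids.
(Minimizing the *sum* of squared distances would not recover a ring's
symmetry axis: an in-plane axis gives a smaller sum.) Orientation follows a
positive-z convention. The minimum pore radius is taken over a configurable
axial window (default: the whole profile; for a membrane channel the
transmembrane span is the natural window).

## Synthetic fixtures — what they do and do not establish

The generators produce idealized Cα helices (rise 1.5 Å, 100° twist, helix
radius 2.3 Å) in three topologies with *constructed* ground truth:

* `c5-barrel` (default 5 × 30 residues, barrel radius 8 Å, radial expansion
  2 Å): exactly five-fold symmetric in both states; exercises symmetry
  preservation, pore profiling, and inter-subunit perturbations. The barrel
  radius is chosen so adjacent helices fall within the 10 Å cutoff —
  a barrel with non-interacting chains would make the expansion invisible
  to both wells and the network floppy.
* `two-phase-chain`: two rigid chains displaced in opposite directions; the
  *constructed* two-phase pathway has closed-form crossovers
  `f_A = 0.5/(1+r)`, `f_B = (1+0.5r)/(1+r)` for late/early displacement
  ratio `r` (0.25/0.75 at the default `r = 1`).
* `hinge-dimer`: static stalk plus an arm rotated 30° about a hinge. In the
  construction frame the stalk is exactly static (crossover undefined);
  on a *solved* pathway the global superposition redistributes ~1 Å onto
  the stalk, which is expected behaviour, so the static-stalk truth is
  asserted on the constructed straight-line path.

Green tests on these fixtures establish the correctness of the machinery —
solver contracts, symmetry and invariance properties, closed-form
recoveries — on assemblies a few hundred residues in size. They do not
establish biological accuracy for real channels: idealized helices have no
sheets, loops, sidechain packing heterogeneity, or alignment gaps beyond
the synthetic deletions, and fixture transitions are rigid-body-composed
rather than crystallographic. Applying the toolchain to a real
closed/open pair additionally requires an externally computed structural
alignment.

## Numerical choices and degenerate inputs

* Kabsch superposition with uniform weights; collinear point sets rejected
  (rank check at 1e−8).
* Altloc resolution: highest occupancy, ties by altloc letter; insertion
  codes: first Cα wins; both logged.
* Identical begin/end states yield a valid 2-conformation, zero-length
  pathway; `f_progress` on it is an error (zero total length).
* Coincident connected atoms are a hard error everywhere (energy, Hessian,
  collision term).
* Non-unit mode vectors passed to the mode-displacement helper are
  renormalized with a warning; the displacement amplitude is
  `target_rmsd · √N`, making the achieved RMSD exact to 1e−10.
* Global arrays are 0-based in memory; residue numbering in all TSV/PDB
  output is the author's 1-based numbering.

## Known limitations

* One-well vs. two-well masking, the exact collision functional form, and
  the axial window of the minimum pore radius are configurable because the
  methodology leaves them open; defaults are stated above.
* The pathway is a minimum-energy saddle curve of a frictionless
  interpolated landscape: no rates, free energies, metastable
  intermediates, or asymmetric (symmetry-broken) excursions.
* Cα resolution cannot resolve sidechain events (e.g. pore hydration).
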