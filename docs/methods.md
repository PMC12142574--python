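# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does
not emulate, and the known limitations.

## System and coordinates

The system is a small-molecule ligand that stacks on an amyloid-fibril
surface. Two *feature groups* per ligand — a head group and a tail group
of atoms, declared in configuration (`structure.head_atoms` /
`structure.tail_atoms`), never guessed from chemistry — define the two
reaction coordinates used throughout: d1, the distance between the head
centroids of two ligands, and d2, the distance between ligand 1's head
centroid and ligand 2's tail centroid. Head-to-head (H_H) and
head-to-tail (H_T) dimer configurations are basins in the (d1, d2)
plane.

All coordinates are Ångström internally. The two formulas that are
conventionally written in nm (the switching function with r0 = 0.45 nm
and the ±0.2 nm native-contact tolerance) convert Å → nm at the formula
boundary; nothing else does unit conversion.

Structures and coordinate trajectories are plain (multi-model) PDB, read
and written through biotite. Multi-ligand models are split per ligand by
chain identifier when the chains match the ligand count, otherwise by
contiguous residue-number blocks of the ligand's atom count — both
dialects occur in practice. Observable-mode trajectories serialize to a
documented CSV (`frame, time_ns, sasa_A2, rmsd_A, state, hbonds`).

## Pose generation

The second-ligand pose library is rejection sampling: rotate a copy of
the reference ligand about its center of mass, translate its center of
mass to a random point of the 10–20 Å spherical shell around the
reference center of mass, and accept the pose if no heavy-atom pair
against the reference ligand or the fibril comes closer than the clash
cutoff.

* **Rotation sampling.** The default `euler` mode draws three z-y-z
  Euler angles independently uniform on their ranges (α, γ ∈ [0, 2π),
  β ∈ [0, π]). This is the conventional naive scheme and is *not*
  uniform on SO(3); a `uniform` mode (Haar-uniform via quaternions) is
  offered for users who want unbiased orientations.
* **Translation density.** "Within a 1–2 nm radius" is read as an
  annulus with direction uniform on the sphere and radius uniform over
  the shell *volume* (inverse-CDF r³ scaling), i.e. spatially uniform
  over the shell.
* **Clash cutoff.** 2.0 Å minimum heavy-atom distance, strict
  less-than (a contact at exactly the cutoff is not a clash). The value
  sits below any realistic nonbonded contact; configurable.
* **Stall watchdog.** If fewer than 10⁻⁴ of the last 50 000 attempts
  were accepted, the geometry admits essentially no placements and the
  generator aborts with diagnostics instead of spinning.

## Configurational clustering

Every configuration is rigidly superposed so its first ligand's heavy
atoms best fit the first configuration's first ligand (Kabsch, proper
rotations only). The pairwise RMSD matrix over all ligand heavy atoms is
then computed **without** per-pair re-superposition: the alignment frame
is fixed, which makes the RMSD a scaled Euclidean metric on flattened
coordinates (RMSD = ‖Δx‖/√N_atoms). Centroid-linkage hierarchical
clustering is therefore well defined; it is computed with the standard
Lance–Williams recurrence on the distance matrix (scipy), not by
averaging coordinates, and flat clusters are cut at the 40 Å distance
criterion. The threshold is large because a configuration spans several
stacked ligands; it is configurable.

Each cluster is represented by its medoid (member minimizing mean RMSD
to the cluster), clusters are ranked by occupancy with ties broken by
first appearance, and `population_table` aggregates everything beyond
the top k into an "other" entry.

## Order metrics

* **Native contacts.** For each atom i, the crystal-reference distance
  between atom i of ligand 1 and atom i of ligand 2 is stored; a contact
  is formed when the current distance is within ±0.2 nm of the reference
  (closed interval), and the count is normalized by the number of pairs.
  The i↔i mapping is deliberate: it measures similarity to the reference
  stacking register, not generic contact.
* **Coordination number.** `Σ_i Σ_j s(r_ij)` over inter-ligand heavy-atom
  pairs with the rational switching function (n = 6, m = 8, r0 = 0.45
  nm). The removable 0/0 singularity at r = r0 is evaluated analytically
  as the limit n/m (returned whenever |x − 1| < 10⁻⁹). Hydrogens are
  excluded by default, the convention for contact collective variables.
  Note the x^(n−m) = x⁻² power-law tail: the function is "near zero"
  only in a relative sense at large separation (s ≈ 2×10⁻³ per pair at
  10 nm).
* **Oligomers.** A size-k frame has k(k−1)/2 ligand pairs but only k−1
  key stacking interactions, so the top k−1 pairwise native-contact
  values are *averaged* (keeping Q ∈ [0, 1] across oligomer sizes) while
  the top k−1 coordination numbers are *summed* (larger aggregates
  legitimately score higher).

## Free-energy landscape

ΔG(d1, d2) = −RT ln(P/P₀) with R = 1.987×10⁻³ kcal/(mol·K), T = 300 K
by default and P₀ the highest observed bin probability, so the modal bin
is exactly 0 and every occupied bin is ≥ 0. Bin width defaults to 0.5 Å
(results are quoted to ±1 bin). Empty bins are marked *unobserved*
(NaN), not +∞: assigning them a number would fabricate barriers at the
data boundary. The minima search runs over occupied bins only and
reports bins strictly below all occupied neighbours within a 1-bin
Chebyshev radius, sorted by ΔG.

## Pathway classification and kinetics

The classification partition is:

| class | rule |
|---|---|
| nonaggregated | no frame with joint ligand-pair SASA < 250 Å² |
| on-pathway | aggregated, and some frame with ligand RMSD ≤ 2.0 Å to the crystal reference |
| off-pathway | aggregated, never crystal-like |

Boundary conventions: SASA exactly at the threshold counts as **not**
aggregated (the aggregation condition is strictly below); RMSD exactly
at the threshold counts as on-pathway (≤). A trajectory truncated to a
time window is classified on its visible frames, which makes the
on-pathway fraction non-decreasing in the window length (a trajectory
that has visited a crystal-like pose by time t has visited it by any
t′ > t) — the kinetic-trapping signature.

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(960 points by default), probe radius 1.4 Å and Bondi vdW radii; the
ligand-pair area is evaluated in the context of all supplied coordinates
so a fibril body occludes. A test point is buried when it lies on or
inside another atom's solvent-extended sphere (closed inequality; the
measure-zero boundary set only matters for exactly degenerate
geometries).

Configurational kinetics are lag-1 conditional transition probabilities
between H_H and H_T, pooled over trajectories: k = (transitions A→B) /
(transitions leaving A), with pairs whose window contains an unassigned
frame skipped and a never-visited source state reported as undefined
rather than 0. These are per-frame probabilities, not rates in ns⁻¹.
State assignment from coordinates takes the nearest basin center within
a 3 Å radius in the (d1, d2) plane (ties to H_H, deterministically);
precomputed state observables pass through.

## Hydrogen bonds

Geometric criterion, donor–acceptor distance ≤ 3.5 Å and D–H···A angle
≥ 135° (both inclusive) — a conventional default, recorded in output
metadata and configurable, since nothing in the analysis depends
delicately on it. Hydrogens are attached to donors by proximity
(≤ 1.25 Å); donors without a hydrogen are skipped with a warning.
Observable-mode trajectories bypass geometry entirely: their per-frame
`hbond_count` passes through, restricted to aggregated frames, so the
per-class distribution statistics (means 2.01 / 0.74, the sharp
two-bond peak) are testable without any protein model.

## Energy decomposition

The bookkeeping is exact arithmetic:
ΔG_binding = n·ΔG_pro–lig + (n−1)·ΔG_lig–lig, with
ΔG_lig–lig = ΔG_pro–lig(dimer) − ΔG_pro–lig(1) − ΔG_pro–lig(2)
(the dimer treated as a single entity). The trimer protocol evaluates,
over the final 20 % of frames, the protein↔ligand energy for each of
three stacked ligands and for the two adjacent dimers (pairs 1–2 and
2–3); the two per-pair ΔG_lig–lig values are averaged and both are
reported, with standard errors over frames.

The interaction-energy evaluator is pluggable. The shipped surrogate is
a pairwise Coulomb (332.06·q_iq_j/r) + 12-6 Lennard-Jones (Lorentz–
Berthelot) sum with no cutoff. Because it is strictly pairwise-additive,
its ΔG_lig–lig is zero to machine precision — a built-in validation of
the subtraction plumbing. A config-enabled many-body evaluator adds
κ·Σ_{i<j} E_i·E_j for composite groups, producing a known nonzero
coupling for recovery tests. Implicit-solvent terms are intentionally
out of scope: per-frame energies from an external end-point method can
be imported instead (`fibtemplate energy --import-energies`).

## Synthetic study conditions

The generator emulates a swarm of 1000 independent 100 ns dimer
trajectories plus the companion oligomer ensembles. Its defaults *are*
the study conditions; they are not tuning knobs.

* **Class mixture** 12.6 % on-pathway / 34.6 % off-pathway / 52.8 %
  nonaggregated, drawn i.i.d. per trajectory.
* **State dynamics** lag-1 two-state Markov chains started from the
  stationary distribution, with transition matrices
  (k_H_H→H_T, k_H_T→H_H) = (0.05, 0.39) for on-pathway and
  (0.28, 0.25) for off-pathway chains. The estimator in the kinetics
  stage uses the same lag, making parameter recovery well-posed.
* **H-bond counts** i.i.d. per aggregated frame from
  {1: 0.08, 2: 0.83, 3: 0.09} (mean 2.01 exactly, >80 % at exactly two
  bonds) for on-pathway and {0: 0.41, 1: 0.45, 2: 0.13, 3: 0.01}
  (mean 0.74 exactly) for off-pathway frames; asserted at import.
* **SASA and RMSD** only the thresholds are physically meaningful; the
  distribution shapes are stand-ins. Free-phase SASA is normal
  (320 ± 30 Å²) truncated above 250 Å², aggregated-phase (200 ± 20 Å²)
  truncated below it; crystal-like RMSD (1.2 ± 0.3 Å) truncated at
  ≤ 2.0 Å, non-native (4.5 ± 1.0 Å) truncated above. Truncation makes
  class membership exact by construction — with untruncated normals a
  ~1 % per-frame crossing probability would misclassify essentially
  every long nonaggregated trajectory and the mixture would not be
  recoverable, so the truncated reading is the only self-consistent one.
* **Aggregation onset** uniform over the first half of each on/off
  trajectory; not otherwise parameterized. This choice makes the
  truncated-window analysis informative (an early 20 ns window sees
  roughly 40 % of the eventual aggregation events).
* **Dimer geometries** two copies of a planar 14-atom two-ring toy
  ligand placed so (d1, d2) equals a basin center — (7, 5) for H_H in
  both environments, (12, 11) for H_T in solution, (9, 14) for H_T on
  the fibril — via exact two-point placement (triangle-inequality
  feasibility checked), plus isotropic per-atom Gaussian noise
  (0.5 Å sd default).
* **Oligomer ensembles** fixed template catalogs per environment and
  size, with occupancy weights whose leading entries are the calibrated
  cluster populations (solution: 21.3/20.3 % dimer, 12.5/12.1/9.9 %
  trimer, 11.7 % tetramer, 6.7 % pentamer; fibril: 41.3 % dimer with
  top three summing to 80.3 %, 96.6 % trimer, 100 % tetramer and
  pentamer) and whose remainder declines below the last calibrated
  value, summing to 100 (asserted at import). Template zones sit on a
  150 Å Fibonacci sphere around the first ligand so inter-template
  all-ligand RMSD (> 70 Å) clears the 40 Å criterion, while the 0.5 Å
  per-atom jitter bound keeps within-template scatter — including the
  lever-arm amplification of first-ligand alignment noise — well under
  it. Each configuration additionally gets a random global rigid
  transform, which the alignment stage must undo.

What the generator does **not** emulate: force-field dynamics, water,
any correlation between SASA/RMSD/H-bond observables beyond the class
structure, realistic intra-basin (d1, d2) anharmonicity, or chemistry in
the oligomer templates (they are geometric stand-ins engineered for
separability). Passing tests therefore demonstrate that the *analysis*
stages are correct and statistically consistent under the declared
conditions — not that those conditions are an accurate physical model of
any real fibril–ligand system.

## Reproducibility and problem sizes

Every generator accepts a numpy `Generator` or integer seed and is
bit-reproducible under a fixed seed. The pipeline expands one global
seed into per-stage streams (`SeedSequence.spawn` in a fixed stage
order) so stages can be rerun in isolation. The default analysis sizes —
1000 trajectories × 1000 frames for classification, 200 chains per class
for kinetics, 10⁵ draws for H-bond statistics, 2000 configurations per
oligomer ensemble for clustering — match the scale of the emulated study
where it is desk-computable and give binomial standard errors an order
of magnitude below the quantities of interest.

## Known limitations

* The feature groups defining (d1, d2) must be supplied; there is no
  chemical perception.
* Centroid linkage on an RMSD matrix is only strictly Euclidean because
  the alignment frame is fixed; feeding externally aligned or per-pair
  superposed matrices can produce linkage inversions.
* The Euler-mode pose sampler is intentionally biased (see above);
  quantitative orientation statistics should use `uniform`.
* The Shrake–Rupley implementation is O(N²) in atoms per frame (with a
  radius prescreen) — adequate for ligand-pair + local-surface systems,
  not for whole-fibril SASA scans.
* The surrogate energy evaluator is a toy potential for exercising the
  decomposition; its absolute energies are not comparable to end-point
  method output.
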