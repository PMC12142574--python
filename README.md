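# fibtemplate

Analysis pipeline for **fibril-templated small-molecule aggregation**:
how an amyloid-fibril surface (e.g. a tau filament) templates the ordered
self-assembly of a bound ligand into the stacked arrays seen by cryo-EM,
while the same ligand forms only disordered clusters in bulk solution.

The package is aimed at computational chemists studying ligand binding to
amyloid surfaces (PET-tracer design, aggregation mechanisms). It provides
the complete post-processing stack for large swarms of short dimer-formation
trajectories, together with a synthetic trajectory generator that emulates
the statistical structure of such a study, so every stage is testable and
reproducible without any molecular-dynamics engine or deposited structure.

## What it computes

* **Pose libraries** — rejection sampling of clash-free random placements
  of a second ligand in a 10–20 Å shell around a reference ligand
  (random rotation → random shell translation → steric-clash filter,
  repeated until *n* = 1000 poses are accepted).
* **Configurational clustering** — configurations aligned on the first
  ligand (Kabsch), all-ligand heavy-atom pairwise RMSD matrix,
  hierarchical centroid-linkage clustering cut at a 40 Å distance
  criterion; cluster occupancies and medoid representatives
  (`ConfigurationClusterer`).
* **Order metrics** — native-contact fraction *Q* (equivalent inter-ligand
  atom pairs within ±0.2 nm of the crystal reference distance, normalized
  to 1) and the smooth coordination number
  `C = Σ_i Σ_j s(r_ij)`, `s(r) = (1 − x^n)/(1 − x^m)`, `x = (r − d0)/r0`
  with n = 6, m = 8, d0 = 0, r0 = 0.45 nm. For oligomers of size *k* only
  the strongest *k* − 1 pairwise interactions enter (mean for *Q*, sum
  for *C*).
* **Free-energy landscapes** — 2-D histogram of the inter-ligand feature
  distances (d1: head–head, d2: head–tail) Boltzmann-inverted as
  ΔG = −RT ln(P/P₀) at 300 K, with P₀ the modal bin; minima located on
  occupied bins (`FreeEnergyLandscape`).
* **Pathway classification & kinetics** — trajectories partitioned into
  *nonaggregated* (SASA > 250 Å² in every frame), *on-pathway*
  (aggregated and visiting a crystal-like pose, ligand RMSD ≤ 2.0 Å) and
  *off-pathway* (aggregated, never crystal-like); pooled lag-1 H_H↔H_T
  transition probabilities (`PathwayClassifier`, `TransitionEstimator`);
  built-in Shrake–Rupley SASA.
* **Hydrogen-bond statistics** — geometric detection (D–A ≤ 3.5 Å,
  D–H···A ≥ 135°), per-class count histograms and means.
* **Binding-energy decomposition** —
  ΔG_binding = n·ΔG_pro–lig + (n−1)·ΔG_lig–lig with the ligand–ligand
  coupling from the dimer-as-single-entity subtraction
  ΔG_lig–lig = ΔG_pro–lig(dimer) − ΔG_pro–lig(1) − ΔG_pro–lig(2),
  over a pluggable per-frame interaction-energy evaluator (a pairwise
  Coulomb + Lennard-Jones surrogate ships with the package; external
  end-point energies can be imported).

## Worked example

```python
import numpy as np
from fibtemplate import (SyntheticParams, generate_ensemble, classify_ensemble,
                         transition_probabilities, generate_coordinate_dimer,
                         generate_toy_ligand, FreeEnergyLandscape)
from fibtemplate.landscape import trajectory_feature_distances

params = SyntheticParams()                      # default study conditions

# 500 observable-mode dimer trajectories, classified by the SASA/RMSD rules
ensemble = generate_ensemble(n_traj=500, n_frames=500, params=params, rng=0)
trajs = [t for t, _ in ensemble]
fractions = classify_ensemble(trajs)
print({k: round(100 * v, 1) for k, v in fractions.items()})
# {'on': 11.2, 'off': 30.0, 'non': 58.8}

# lag-1 transition probabilities pooled over the on-pathway chains
on_states = [t.observable_series("state") for t, label in ensemble if label == "on"]
stats = transition_probabilities(on_states, lag=1)
print(round(stats.k_hh_to_ht, 3), round(stats.k_ht_to_hh, 3))
# 0.048 0.388

# free-energy surface of a 70/30 head-to-head / head-to-tail dimer mixture
ligand = generate_toy_ligand()
hh = generate_coordinate_dimer("H_H", "solution", 7000, params, 1, ligand)
ht = generate_coordinate_dimer("H_T", "solution", 3000, params, 2, ligand)
samples = np.vstack([trajectory_feature_distances(hh, ligand),
                     trajectory_feature_distances(ht, ligand)])
fes = FreeEnergyLandscape(bin_width=0.5, temperature=300.0).fit(samples)
for d1, d2, dg in fes.minima_[:2]:
    print(f"minimum at d1={d1:.2f} A, d2={d2:.2f} A, dG={dg:.3f} kcal/mol")
# minimum at d1=7.25 A, d2=5.25 A, dG=0.000 kcal/mol
# minimum at d1=12.25 A, d2=11.25 A, dG=0.400 kcal/mol
```

The class fractions recover the generator's 12.6 / 34.6 / 52.8 % mixture
to binomial accuracy; the transition probabilities recover the on-pathway
chain's asymmetric matrix (0.05 forward, 0.39 back — the kinetic-trapping
signature of the crystal-like state); and the landscape's two minima sit
at the head-to-head (7, 5) Å and head-to-tail (12, 11) Å basin centers,
with the majority basin at ΔG = 0.

A `fibtemplate` console script exposes the same stages
(`simulate`, `poses`, `cluster`, `metrics`, `fes`, `classify`, `kinetics`,
`hbonds`, `energy`, `run`); `fibtemplate run --out report.json` executes
the full pipeline and writes a provenance report.

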