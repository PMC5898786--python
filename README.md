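# camstates

Conformational-state analysis for two-lobed calcium-sensor proteins such
as calmodulin (CaM): decompose an ensemble into quasi-rigid domains,
cluster each domain's conformations into discrete states, characterize
the states, and score how well each state's solvent-exposure pattern
matches the contact footprints of protein–peptide complex structures —
a quantitative test of conformational-selection binding.

## Who this is for

Structural bioinformaticians and molecular-simulation groups who have an
ensemble of a flexible multi-domain protein (multi-model PDB, or any
trajectory convertible to one) plus complex structures of the same
protein bound to targets, and who want to know *which unbound
conformational states look pre-organized for which binding modes*.

## The method

1. **Quasi-rigid domains.** The standard deviation over frames of every
   inter-residue distance forms a fluctuation matrix `f`. Residues that
   move together have small mutual fluctuation; the similarity
   `exp(−f²/2σ_f²)` is clustered spectrally and the eigengap selects the
   number of domains (two lobes for CaM).
2. **States by spectral clustering.** Each frame is featurized as a
   contact map of inverse inter-atomic distances (iiad-cmap); frame
   dissimilarity `d_ij` is the Euclidean distance between feature
   vectors. The Gaussian kernel

       A_ij = exp(−d_ij² / 2σ²),   σ = mean nearest-neighbour distance,

   and the normalized matrix `L = D^(−1/2) A D^(−1/2)` (D the degree
   matrix) yield eigenvalues whose maximum eigengap sets the state count
   k; rows of the top-k eigenvectors are normalized onto the unit sphere
   and clustered with spherical k-means. Each state is summarized by the
   frame with smallest mean RMSD to the other members.
3. **State features.** Interhelical angles from `u·v = |u||v| cos α`
   with helix vectors taken as the principal eigenvector of the heavy
   backbone atoms (oriented by sequence); per-residue helix/strand/coil
   frequencies (simplified Kabsch–Sander assigner, MDTraj DSSP
   pluggable); solvent exposure as the number of water oxygens within
   4.5 Å of any heavy atom of a residue, and relative exposure
   `s_j^(i)` = state-i exposure of residue j over its across-state mean.
4. **Kinetics.** Mean first-passage times between states from the frame
   label sequence; rates are their inverses.
5. **Binding-mode classes.** Complex k gives a binary contact vector
   `m^(k)` (CaM heavy atom within 4.5 Å of any target atom; ≥70 % of
   models for NMR-style ensembles). The matching score

       S_i(k) = Σ_j s_j^(i) m_j^(k)

   is normalized over states into a per-complex distribution;
   distributions are clustered (same spectral engine) into binding-mode
   classes with per-class mean ± std and apolar/polar/charged contact
   composition.

Because public μs-scale CaM trajectories are not available, the package
ships a first-class synthetic-data module: a two-lobe, eight-helix
protein with a flexible linker, planted discrete states that differ in
interhelical angles, a water shell with controllable per-residue (and
per-state) burial, and toy complexes with planted contact sets — every
stage is validated against exact ground truth.

## Worked example

```python
import numpy as np
import camstates as cs

# a complete synthetic study: 300 frames, 4 planted states, water shell,
# 6 toy complexes in 2 planted binding classes
config = cs.make_demo(seed=1, outdir="demo")
results = cs.run_pipeline(config, base_dir="demo")

import json
states = json.load(open("demo/results/states.json"))
print(states["domain_0"]["k"], states["domain_0"]["state_sizes"])
```

prints

```
4 [69, 77, 78, 76]
```

four states in the first lobe, with the listed frame counts — matching
the four planted conformations. `demo/results/` also holds
`domains.json` (2 domains, lobe assignment per residue), `angles.csv`
(per-frame interhelical angles tagged by state), `ss_freq.csv`,
`exposure.csv` (per-state absolute and relative exposure),
`kinetics.csv` (mean transition times and rates) and `classes.json`,
where the six complexes split into the two planted binding classes:

```python
classes = json.load(open("demo/results/classes.json"))
print(classes["domain_0"]["labels"])
```

```
{'complex_0': 1, 'complex_1': 0, 'complex_2': 1, 'complex_3': 0, 'complex_4': 1, 'complex_5': 0}
```

(complexes 0, 2, 4 contact the residue set exposed by one planted state,
complexes 1, 3, 5 the other; the recovered state labels match the
planted four states with adjusted Rand index 1.0 in both lobes).

The same workflow runs from the shell:

```bash
camstates demo --seed 1 --outdir demo
camstates run --config demo/config.yaml
camstates domains --trajectory demo/ensemble.pdb --out domains.json
```

For a real protein, point the config at your multi-model PDB, a helix
table (the canonical CaM helices A–H are built in:
`cs.cam_helices(holo=True)`), and your complex structures with chain ids
and residue maps.

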