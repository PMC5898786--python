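# Methods

This note documents the models, estimators, numerical choices and known
limitations of `camstates`. Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is asserted from
external data.

## Spectral engine

One spectral-clustering engine serves three stages (frame states,
residue domains, binding-mode classes). Given a symmetric dissimilarity
matrix `d`:

- **Kernel.** `A_ij = exp(−d_ij²/2σ²)` with `A_ii = 1` (the kernel is
  applied literally at `d_ii = 0`); no k-NN sparsification — the dense
  kernel is the default and only mode used by the shipped analyses.
- **σ heuristic.** σ is the mean over items of the distance to the
  nearest other item. If duplicates force σ to 0, zero-distance groups
  are collapsed to unique representatives, the engine runs on those, and
  labels are broadcast back; this is the only deduplication performed.
- **Normalization.** `L = D^(−1/2) A D^(−1/2)` with `D_ii = Σ_j A_ij`,
  symmetrized before `eigh`; eigenvalues sorted descending, all in
  [−1, 1], with λ₁ = 1 for a connected graph (checked to 1e−9 in tests).
- **Model selection.** k maximizes `λ_k − λ_{k+1}` (1-based) within the
  search range — default (2, 10) for states, (2, 6) for domains. Ties go
  to the smallest k. A spectrum whose gaps beyond the leading eigenvalue
  are exactly flat carries no cluster structure; the engine returns one
  cluster and warns. k is always available as a user override — model
  counts chosen by eigengap on few, nearly duplicated observations
  (e.g. a handful of complexes) are fragile, and an analysis that knows
  its design (as the demo does) should say so in its config.
- **Embedding.** Rows of the top-k eigenvectors are scaled to unit norm
  (points on the k-sphere). Eigenvector signs are canonicalized (largest
  magnitude entry made positive) so the arbitrary sign returned by the
  eigensolver cannot change labels.
- **Spherical k-means.** Centers are renormalized to the sphere after
  every update; best of `n_init = 10` k-means++-style seeded restarts by
  within-cluster cosine dispersion; assignment-stable convergence.
  Initialization operates on a lexicographically sorted copy of the
  points, so permuting the input permutes the labels identically under
  the same seed.

The engine is verified against a brute-force dense implementation
(distances, kernel, normalized matrix, spectrum) to 1e−10 on 20-frame
instances, and σ against hand enumeration (pairwise distances {1, 2, 3}
give σ = 4/3).

## Frame featurization (iiad-cmap)

Frames are represented by inverse inter-atomic distances 1/r (Å⁻¹) over
the canonical i<j pair list of a chosen atom selection; distant pairs
contribute little without a hard cutoff, and no structural alignment is
needed (the features are internal coordinates — the whole pipeline is
invariant to per-frame rigid motion, tested to 1e−9). Frame
dissimilarity is the Euclidean (Frobenius) norm between feature vectors;
the norm choice is a documented interpretation, as is `pair_stride`
(deterministic subsampling of the pair list) and the CA-only mode.

**Atom-selection guidance.** All-heavy-atom pairs are the default
selection. With the synthetic generator's i.i.d. per-atom coordinate
noise, however, bonded pairs (r ≈ 1.2–1.5 Å) turn that noise into the
dominant feature variance (δ(1/r) ≈ δr/r²), swamping genuine
conformational separation: measured on the default conditions, planted
state separation is 0.76 while noise-only spread is 1.28 in heavy-atom
feature distance, versus 0.43 against 0.16 in CA-only mode. Real
thermal fluctuations do not stretch bonds, so close-pair 1/r terms carry
no conformational signal in any case; the shipped analyses therefore use
CA-only features, and the demo config records that choice.

## Quasi-rigid domains

The fluctuation matrix holds the population (1/n) standard deviation
over frames of each inter-residue distance, computed two-pass (a naive
`E[x²]−E[x]²` loses ~6 digits at 40 Å mean distances and fails the
rigid-translation-gives-zero contract). Representation: CA positions by
default, heavy-atom centroids as the alternative. Similarity
`exp(−f²/2σ_f²)` with `σ_f` the mean positive fluctuation entry feeds
the spectral engine over residues. This implements the principle of
fluctuation-based quasi-rigid decomposition — residues that move
together — not any particular program's bootstrap scoring. Linker
residues are assigned wherever the clustering puts them; no post-hoc
smoothing.

## State features

- **Helix vectors.** Principal eigenvector of the covariance of the
  helix's heavy backbone atoms (N, CA, C, O), sign fixed by positive dot
  product with (last-CA − first-CA). Angles are
  `arccos` of the clamped dot product, in [0, 180]°. The canonical CaM
  helix table (A 6–18, B 29–38, C 45–54, D 65–74, E 83–91, F 102–111,
  G 118–127, H 139–145) is built in; the calcium-loaded form truncates
  helix A to 13–18 via `cam_helices(holo=True)`. "Within-lobe" pairing
  produces the 6 pairs among A–D and the 6 among E–H.
- **Secondary structure.** Default assigner: simplified Kabsch–Sander.
  Amide hydrogens are constructed from the preceding carbonyl
  (H = N + unit(C_prev − O_prev)); the H-bond energy is
  `0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, bond when
  E < −0.5; n-turns (n = 3, 4, 5) with two consecutive turns give
  G/H/I helices, Kabsch–Sander parallel/antiparallel bridge patterns
  give strands; 8 classes reduce to helix = {H, G, I},
  strand = {E, B} (isolated bridges count as strand), coil = rest.
  Chain breaks (C–N > 2.5 Å) start new segments. The assigner is
  pluggable; an MDTraj DSSP adapter is provided and the two agree
  exactly on ideal helix and extended-chain fixtures in the tests.
  Residues with missing backbone atoms are assigned coil with a warning.
- **Solvent exposure.** Count of distinct water oxygens strictly within
  4.5 Å of ≥1 heavy atom of the residue, per frame; profiles average
  per-frame counts (identical to pooling for counts). Strict `<` is
  chosen at the cutoff; equality has measure zero. Relative exposure
  divides each state's profile by the across-state mean per residue;
  residues unexposed in every state get 0 with a warning. The
  across-state mean of `s_j` is 1 to 1e−9 for exposed residues.

## Kinetics

"Average time to transition a→b" is estimated as the mean first-passage
time averaged over all source frames: for every frame labelled a, the
time to the next frame labelled b, scaled by the frame interval; the
rate is its inverse. Source frames whose passage never completes before
the trajectory ends are excluded from the mean and reported as a
censoring count — including them as zeros or dropping them silently
would bias rates of rarely connected pairs. Only contiguous MD label
sequences are valid; sequences flagged as replica exchange are rejected
(exchanges break the dynamics). The estimator equals an enumeration
oracle exactly on short sequences and recovers the switch rate of a
planted two-state Markov chain within 2 % at 10⁵ frames (20 % is the
guaranteed bound).

## Binding analysis

Contact rule: CaM-side heavy atoms against *any* target-chain atom,
strictly within 4.5 Å; for multi-model structures a residue is a contact
when the rule holds in ≥ 70 % of models. An explicit residue map
translates complex numbering to the reference numbering of the exposure
profiles. Matching scores `S_i(k) = Σ_j s_j^(i) m_j^(k)` are normalized
to sum to 1 over states (the distribution interpretation of
normalization). Classes come from the spectral engine on Euclidean
distances between normalized distributions; per class the mean ± std
distribution and mean ± std residue-type fractions are reported. The
default type table: apolar = {ALA VAL LEU ILE PRO PHE MET TRP GLY},
polar = {SER THR CYS TYR ASN GLN HIS}, charged = {ASP GLU LYS ARG};
it is overridable, and GLY/HIS/TRP placements are conventions, not
facts. Depth labels (deep/intermediate/shallow) are user-supplied
annotations attached to classes, never inferred.

## Synthetic data: what it emulates, and what it does not

The generator builds a two-lobe, eight-helix poly-alanine-like protein
(N, CA, C, O plus a pseudo-CB side-chain atom per residue; 88 residues
by default) with NeRF internal-coordinate geometry: ideal α-helices at
(φ, ψ) = (−57°, −47°), extended linker segments at (−120°, 120°). Each
helix template is pre-rotated so its backbone principal axis is exactly
+z; planting a state means rigidly rotating whole helices so target
pair angles are realized *exactly* (cone/cone-intersection solving, at
most two constraints per helix), which is why zero-noise angle recovery
is exact to 1e−6 degrees. The default state plan steps two pair angles
per lobe by 25° between adjacent states — a lobe's open↔closed
transition re-packs several helices, not one.

Per frame: a state is drawn (i.i.d. weights or Markov chain), each lobe
receives an independent random rotation (axis uniform, angle
N(0, 90°) by default — broad lobe tumbling about a flexible linker, as
solution experiments show for calmodulin), the two linker halves travel
rigidly with their lobes (break at the midpoint), and isotropic Gaussian
coordinate noise (0.15 Å default) is added. With one state, zero noise
and zero wobble, all frames are byte-identical.

Water is oxygen-only on a jittered grid (spacing 2.8 Å) kept within
2.6–6.0 Å of the nearest protein heavy atom; a water whose nearest
residue is r survives with probability `burial_mask[r]` (vector, or per
state a mapping state → vector). The ensemble keeps a fixed atom count:
unoccupied water slots are parked >400 Å away, outside every cutoff.

Toy complexes place one peptide heavy atom 3.95 Å from the most exposed
heavy atom of each designated residue (in `ceil(fraction·n_models)`
models; 9 Å in the rest) along a clearance-maximizing direction (quasi-
uniform sphere scan plus seeded hill climb); non-designated residues
stay >6 Å from every peptide atom in every model. The construction
raises for sterically enclosed residues (mid-helix positions) —
`feasible_contact_residues` reports which residues admit a planted
contact for a given geometry.

**What passing tests do and do not show.** The generator produces
exactly the statistical structure the analysis assumes: discrete,
well-separated states; rigid lobes; uncorrelated Gaussian noise;
water whose burial tracks the planted state. Real trajectories have
continuous state overlap, correlated thermal motion, side-chain
rotamers, ions, and exchange-broadened linkers; recovery rates measured
here (ARI 1.0, exact contact recovery) are upper bounds, not forecasts,
for real data. Conversely the oracle-equivalence tests (spectral math,
kinetics enumeration, exposure counting) are exact statements about the
implementation that carry over unchanged.

## Problem sizes and determinism

The shipped study conditions are 300 frames, 88 residues, 4 planted
states, ~1500 shell waters per frame, 6 complexes; the full demo
(generate + analyze) completes in well under ten minutes on one CPU, and
unit tests use 40–90-frame reductions of the same conditions. All
randomness flows through `numpy.random.default_rng` seeds recorded in
configs and outputs; rerunning a pipeline with the same config and seed
reproduces every output byte-for-byte (timestamps are never written).

## Known limitations

- The eigengap criterion over-fragments when clusters are few and
  tight relative to the nearest-neighbour σ (e.g. < 10 complexes);
  supply k explicitly in that regime.
- The simplified Kabsch–Sander assigner implements helices and bridge
  strands but not the full DSSP turn/bend taxonomy; for publication-
  grade secondary structure, plug in the MDTraj assigner.
- `transition_kinetics` assumes the label sequence is one contiguous MD
  segment; concatenated segments must be analyzed separately.
- Binary trajectory formats (XTC/DCD) are not read directly; convert to
  multi-model PDB (e.g. with MDTraj) or build an `Ensemble` in memory.
- Insertion codes and altloc codes beyond 'A' are rejected/dropped by
  design.
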