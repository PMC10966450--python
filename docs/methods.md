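# Methods

## Problem and pipeline

Structure predictors for protein complexes will happily fold *any* two
chains into a complex, whether or not the proteins interact in nature.
`voxelppi` classifies predicted two-chain complexes as interacting or
non-interacting from the geometry of the predicted interface.  The pipeline
is:

1. **Parse** a PDB file carrying per-residue pLDDT confidence in the
   B-factor column.  Only the four heavy elements of the protein main
   structure (C, N, O, S) are kept; hydrogens and HETATM records are
   dropped.
2. **Prune** long low-confidence strands.  pLDDT below 50 marks predicted
   intrinsic disorder: such regions are rendered as extended ribbons that
   frequently entangle the partner chain and fake contact regions, so
   contiguous runs of at least `min_strand_len` residues (default 10)
   with pLDDT < 50 are deleted.  Note that the deletion criterion is
   *low* confidence; a published description of this procedure prints the
   inequality the other way round, which contradicts its own rationale
   (pLDDT < 50 = disorder) and is treated here as a typo.
3. **Locate the interface** on the inter-chain alpha-carbon distance
   matrix with a 12 Å threshold — deliberately wider than the common 8 Å
   contact criterion, because predicted models carry small coordinate
   displacements.  If no residue pair qualifies, the threshold grows in
   1 Å steps until both chains contribute at least one residue, so the
   spatially closest region is always selected.  The tensor center is the
   unweighted mean of the selected CA coordinates (the distance matrix is
   CA-based, so the center is CA-based too).
4. **Tensorize** into a `(64, 64, 64, 8)` grid of 1 Å cells centered on
   the interface; channels are element x chain
   (`C_A, N_A, O_A, S_A, C_B, N_B, O_B, S_B`).
5. **Classify** with a compact 3D DenseNet or ResNet under cube-rotation
   and displacement augmentation, evaluated by cluster-coherent 5-fold
   cross-validation.

## Encodings

*One-hot* marks the cell containing each atom's coordinates with 1
(collisions saturate at 1).  Cell `(i, j, k)` covers the half-open box
`[origin + i, origin + i + 1)` per axis with `origin = center − 32 Å`, so
"rounding to an integer" is `floor(atom − origin)` and exactly reversible.

*Volume* stores, per cell and channel, the intersection volume between the
cell cube and the atom's van der Waals sphere.  Radii are half the
tabulated atomic diameters: C 0.70, N 0.65, O 0.60, S 1.00 Å (hydrogen is
excluded throughout).  Overlaps of same-channel atoms sum, which preserves
per-atom volume conservation at the cost of possible double counting where
bonded spheres overlap.  Two evaluators are provided:

- the **exact integral**: the sphere–cell overlap is computed as the exact
  circle–rectangle cross-section area (closed form via quadrant
  inclusion–exclusion) integrated along z with 64-node Gauss–Legendre
  quadrature under the substitution `z = R sin θ`, which removes the
  square-root edge singularity at the sphere surface.  Summed over all
  cells touched by an atom it reproduces `4/3 π R³` to ~1e-9 Å³.  A
  published formulation of this integral contains a lower bound
  `max(z_k, z_a − a)` where the geometry requires the sphere's lower
  surface; the implementation uses the correctly formed overlap.
- the **Monte-Carlo estimator** (10⁶ uniform points per cell by default,
  counter-seeded and reproducible).  Its agreement with the integral,
  measured as `100·(1 − Σ|MC − exact| / Σ exact)` over random atom/cell
  configurations, is ≈ 99.9%.  The aggregate (volume-weighted) form is
  used deliberately: a per-cell relative difference is ill-conditioned for
  sliver intersections whose exact volume approaches zero, where the MC
  absolute error is tiny but the ratio is unbounded.

Full renders default to the exact integral (it is both faster and exact);
the MC path exists because cell-wise random simulation is the cheaper
method when no closed-form/area machinery is available, and it is
validated against the integral in the test suite.

*Distance* stores, per cell and channel, the Euclidean distance from the
cell center to the nearest atom of that channel, capped at 12 Å (cells
farther than the cap from every atom of a channel stay 0).  Different
channels are filled independently; within a channel the nearest atom wins.
Stored distances are clamped to ≥ 1e-3 Å so that "occupied, distance ≈ 0"
remains distinguishable from "empty" — a collision the raw definition does
not address.  The distance is measured from the cell *center*; measuring
from the cell corner would satisfy the same definition, and the choice
only shifts values by sub-cell offsets.

Fill rates (fraction of cells with any non-zero channel, central 32³
subcube) on realistic synthetic complexes order one-hot < volume <
distance, with distance ≈ 99%; the "central area" is defined here as the
centered half-side subcube, since the interface occupies the box center by
construction.

## Augmentation

The 24 proper rotational symmetries of the cube (axis permutations with
sign flips of determinant +1) permute grid cells exactly; mirror
reflections are excluded because they invert protein chirality.  The group
structure (closure, inverses, unique identity — S₄) is verified by brute
force in the tests, as is encoder equivariance: `encode(rotate(s)) =
rotate(encode(s))` exactly for one-hot and to 1e-6 for distance encoding.

Displacement augmentation draws independent uniform shifts in ±6 Å per
axis.  The reference scheme applies the shift to the render center and
re-renders (no boundary artifacts); the trainer's cached-tensor path
approximates this with integer-cell shifts and zero fill, documented as an
approximation.  Displacements are sampled per example per epoch (the
alternative — fixed per epoch — is not stated anywhere; per-example gives
strictly more variation).  Augmentation is train-time only; evaluation
uses the canonical orientation and zero shift.

## Networks

Both backbones use four blocks of four 3×3×3 convolutions, each
convolution followed by dropout 0.2; the block output passes batch
normalization then ReLU; blocks 2–4 receive the previous block's output
downsampled by 2×2×2 average pooling; the head is a global 3D max pool
into a dense layer with 2-way softmax.  ResNet blocks add the block input
to the block output through a shortcut (1×1×1 projection when channel
counts differ); DenseNet blocks concatenate the block input and all
earlier layer outputs into each later layer.

The layers, backpropagation and the AdamW optimizer are implemented
directly on NumPy (convolutions via sliding-window views and `einsum`);
gradients were verified against central differences to ~1e-10 relative
error in float64.  Choices the architecture description leaves open, fixed
here: kernel 3×3×3, ReLU activations, DenseNet growth rate = ResNet block
width = `base_filters` (default 16), adaptive-moment optimizer with
*decoupled* weight decay (so "weight decay 1e-4" acts as true decay rather
than L2 loss), He initialization.  Because the filter counts are free
parameters, the total parameter count depends on `base_filters`; the
builder logs the count of every network it constructs rather than
asserting a fixed number.  Labels: index 1 = interaction, positives
one-hot as [0, 1].

Training defaults (learning rate 1e-5, weight decay 1e-4, 40 epochs,
batch 32, per-epoch shuffling, categorical cross-entropy) follow the
reference recipe.  The learning-sanity checks in the tests use reduced
problem sizes chosen for a single CPU — 16³ grids, growth 8, learning rate
1e-3 — because the check is a capacity/plumbing property (can the network
fit a separable set; does the CV loop respect its constraints), not a
reproduction of benchmark accuracy, which would require thousands of
predicted complexes and GPU training.

## Dataset handling

Curation of generic pair tables applies, in order: conflict resolution
(pairs attested in both tables leave the negative side), duplicate
collapse (unordered pair keys; evidence counts sum), self-interaction
removal, redundancy pruning, and a balance warning for proteins lacking
at least one positive and one negative pair.  Redundancy: among same-label
pairs whose chains match with identity ≥ 40% (configurable; the threshold
is an analogy to a published leakage filter, not a stated curation value),
only the pair whose proteins have the most recorded interactions is kept.
Curation is idempotent.

Fold planning unions protein clusters linked by pairs and deals the
resulting indivisible groups largest-first onto the smallest fold with a
seeded tie-break; a group holding > 40% of pairs is an error (re-cluster
at a stricter threshold).  Clustering itself is delegated: the module
consumes an external cluster table (easy-cluster dialect) and offers a
greedy single-linkage fallback on a user-supplied identity function.  All
five predicted models of a pair share its fold; training expands to every
available model, testing uses model 1 only.

## Synthetic fixtures

`generate_fixture_complex` emulates what the pipeline actually consumes:
two chains of 4-heavy-atom residues (C/N/O/S mix, one alpha carbon per
residue) at ~0.07 heavy atoms/Å³ inside a spherical envelope — the packing
density of globular proteins — separated by a configurable closest-approach
gap (bisected to 1e-3 Å), with optional extended low-pLDDT tail strands
and constant per-residue pLDDT profiles.  CA positions are Poisson-disk
samples (min separation 2.8 Å) ordered into a chain-like path by greedy
nearest neighbour.  Deterministic: a spec (including its seed) yields
byte-identical PDB text.

The generator reproduces packing density, interface geometry, disorder
profiles and element/channel statistics.  It does **not** model backbone
torsions, secondary structure, side-chain chemistry, or the correlated
errors of real structure predictors — so tests passing on fixtures
demonstrate the geometric and statistical correctness of the pipeline, not
classification accuracy on real proteomes.

## Numerical choices and degenerate inputs

- Adaptive interface threshold: step 1 Å ("gradually increased" is
  otherwise unquantified); the loop is capped only by the complex
  diameter.
- Pruning that would empty a chain retains the single highest-pLDDT
  residue with a warning rather than failing.
- pLDDT exactly at the cutoff counts as ordered (strict `<`).
- Score binarization at 0.5 with the ≥ convention.
- Precision with zero predicted positives is reported as NaN, not 0.
- Per-fold accuracy spread: mean absolute deviation and population
  standard deviation of fold accuracies; pooled metrics are computed on
  the union of fold predictions, not averaged.
- Acceptance-script fixture seeds are derived from the command-line seed
  via `SeedSequence` (kept below 2³¹).

## Known limitations

- No mmCIF input; no multi-model NMR PDB files; exactly two chains.
- The NumPy network trains small problems on CPU; it is not a route to
  benchmark-scale training.
- Sequence-identity computation is pluggable, not included (supply a
  similarity callable or an external cluster table).
- Non-standard residues (e.g. selenomethionine) are handled by the
  element filter (unknown elements are dropped with a warning); upstream
  predictors do not emit them.
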