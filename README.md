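# voxelppi

Protein–protein interaction (PPI) classification from *predicted* complex
structures.

Structure predictors such as AlphaFold Multimer fold any two input chains
into a complex — including pairs that never interact in nature.  The
geometry of the predicted interface still carries the signal: `voxelppi`
turns a predicted two-chain complex (a PDB file with per-residue pLDDT
confidence in the B-factor column) into an interface-centered 3D voxel
tensor and classifies it as interacting / non-interacting with a compact
3D convolutional network.  It is aimed at structural bioinformaticians who
already run complex prediction at scale and want a downstream interaction
screen, and at anyone studying voxel representations of molecular
structure.

## Method

For a complex with chains A and B:

1. **Disorder pruning** — contiguous runs of ≥ 10 residues with
   pLDDT < 50 (predicted intrinsic disorder, rendered as entangling
   ribbon strands) are removed.
2. **Interface detection** — residue pairs with inter-chain
   Cα–Cα distance ≤ 12 Å; the threshold grows by 1 Å until both chains
   contribute, and the tensor is centered on the geometric center of the
   selected Cα atoms.
3. **Tensorization** into `(64, 64, 64, 8)` — a 64 Å cube of 1 Å cells,
   channels `[C_A, N_A, O_A, S_A, C_B, N_B, O_B, S_B]`, under one of
   three encodings:
   - *one-hot*: the cell containing each atom is set to 1;
   - *volume*: each cell stores the sphere–cell intersection volume
     (radii C 0.70 / N 0.65 / O 0.60 / S 1.00 Å), computed by an exact
     integral or a seeded 10⁶-point Monte-Carlo estimator;
   - *distance*: each cell stores the distance to the nearest atom of the
     channel, capped at 12 Å — a dense representation
     (`d(i,j,k) = min_a ‖x_cell − x_a‖`).
4. **Classification** by a 3D DenseNet or ResNet (4 blocks × 4 conv
   layers, dropout 0.2, block-level batch-norm + ReLU, average-pooling
   transitions, global max-pool head, 2-way softmax), trained with
   cross-entropy under cube-rotation (the 24 proper rotations) and ±6 Å
   displacement augmentation, evaluated by cluster-coherent 5-fold
   cross-validation (all 5 predicted models of a pair train; model 1
   tests).

The networks are implemented directly on NumPy (verified backprop); a
synthetic-complex generator replaces structure-predictor output for
testing.  See `docs/methods.md` for assumptions, parameter rationale and
limitations.

## Worked example

```python
from voxelppi import (FixtureSpec, generate_fixture_complex, parse_structure,
                      remove_disordered, compute_interface, EncodingConfig,
                      render, fill_rate)

pdb_text = generate_fixture_complex(
    FixtureSpec(n_res_a=150, n_res_b=150, gap=5.0,
                disordered_tail_len=20, seed=1))
s = parse_structure(pdb_text)
s, report = remove_disordered(s)
print(f"pruned {len(report.removed_segments)} strand(s), "
      f"{report.atoms_removed} atoms")
iface = compute_interface(s)
print(f"interface: {len(iface.residues_a)}+{len(iface.residues_b)} residues "
      f"at threshold {iface.threshold_used:.0f} A")
for encoding in ("one_hot", "volume", "distance"):
    grid = render(s, EncodingConfig(encoding=encoding), center=iface.center)
    print(f"{encoding:>8s}: central fill rate "
          f"{100 * fill_rate(grid, 'central'):.1f}%")
```

prints

```
pruned 1 strand(s), 80 atoms
interface: 20+16 residues at threshold 12 A
 one_hot: central fill rate 2.0%
  volume: central fill rate 14.6%
distance: central fill rate 99.3%
```

The synthetic complex carries a 20-residue low-confidence tail (80 atoms)
that the pruning step removes exactly; the interface is found at the
initial 12 Å threshold; and the central fill rates show why distance
encoding helps a convolutional network — it fills ~99% of the central
region, against 2% (one-hot) and 15% (volume), so far more units receive
gradient per example.

The same steps drive the CLI:

```sh
voxelppi fixtures spec.yaml --out-dir pdbs/
voxelppi render pdbs/*.pdb --encoding distance --out-dir grids/
voxelppi train --pairs pairs.tsv --grids-dir grids/ --out model.npz
voxelppi crossval --pairs pairs.tsv --clusters clusters.tsv \
    --grids-dir grids/ --out-dir reports/
```

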