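# pocketdiff

Joint diffusion of **flexible protein pockets** and ligand structures.

Most pocket-conditioned molecule generators hold the receptor rigid, which
cannot express the induced-fit rearrangements (side-chain rotations, broken
salt bridges) that real binding events cause. `pocketdiff` instead treats the
pocket and the ligand as one full-atom system and generates **both** with a
dual diffusion process:

- **Coordinates** follow a variance-preserving Gaussian diffusion
  `x_t = α_t x_0 + σ_t ε`, `ε ~ N(0, I)`, with `α_t² + σ_t² = 1` on a cosine
  schedule of `N_s = 100` steps. The denoiser predicts the noise `ε̂` and
  sampling runs the ancestral (DDPM-posterior) reverse chain.
- **Ligand atom types** follow a discrete denoising diffusion (D3PM) over a
  categorical vocabulary with uniform transition kernels
  `Q_t = (1−β_t) I + (β_t/K) 𝟙𝟙ᵀ`. The denoiser predicts logits for the clean
  types and the reverse step samples the exact posterior
  `q(s_{t−1} | s_t, ŝ_0)`. Pocket atom types are fixed conditioning.

Both processes share one denoising network: an Evoformer-style stack
(single-sequence attention with pair bias, outer-product updates, triangle
attention and triangle multiplication, transitions) topped by an
**E(3)-equivariant coordinate head** that aggregates weighted unit direction
vectors `Δx_i = Σ_j w(z_ij)·(x_j−x_i)/‖x_j−x_i‖`. Rotating the input rotates
the predicted displacements exactly; atom-type logits are rotation-invariant.
The network and training loop run on a small NumPy reverse-mode autodiff core
(`pocketdiff.nn`) — no deep-learning framework is required.

Around the generator the package provides the full working pipeline:
PDB/SDF I/O, 6 Å pocket extraction, distance-based (1.9 Å) bond perception
and valence-based bond-order assignment, a synthetic complex generator for
desk-scale experiments, molecule quality metrics (validity, connectivity,
large rings, QED, Lipinski RO5, synthetic accessibility, SMARTS
functional-group census, fingerprint Tanimoto), pocket RMSD, residue–ligand
distances, leakage-controlled dataset splitting, and denoising-trajectory
analytics (atom-type transition matrices, RMSD-to-final, bond dynamics).

## Worked example

Overfit the tiny default network on one synthetic pocket+ligand complex and
regenerate the ligand from pure noise, conditioned on the same pocket:

```python
from pocketdiff.benchmarks import parameter_recovery_experiment

result = parameter_recovery_experiment(seed=1, n_train_steps=6000, n_draws=10)
print(f"best ligand RMSD   {result.best_rmsd:.2f} Å")
print(f"type accuracy      {result.best_type_accuracy:.0%}")
print(f"successful draws   {result.n_successful_draws}/10")
```

prints (a few minutes on one CPU core):

```
best ligand RMSD   0.65 Å
type accuracy      100%
successful draws   6/10
```

meaning that six of ten denoising draws reproduced the training ligand to
sub-ångström heavy-atom RMSD with at least 8 of 10 atom types correct, and
the best draw got every atom type right —
the generative chain, the equivariant denoiser and the bond reconstruction
all round-trip a known ground truth. Draw-level numbers vary with the seed;
the comparison uses the RMSD-optimal rotation and atom assignment because
the sampler is permutation- and rotation-equivariant (atoms come back in no
particular order or frame).

The same machinery is exposed on the command line:

```bash
pocketdiff train  --fixture-seed 3 --checkpoint model.npz --steps 4000
pocketdiff sample --fixture-seed 3 --checkpoint model.npz \
                  --ligand-size 10 --n 10 --seed 1 --out generated --save-traj
pocketdiff evaluate --sdf-dir generated --out report.csv
pocketdiff analyze  --traj generated/sample_000_traj --out analysis
pocketdiff split    --similarity sims.csv --ratio 0.8 --out split.json
```

`pocketdiff sample` also accepts `--receptor X.pdb --ligand ref.sdf` to
condition on a real pocket (the reference ligand defines the 6 Å pocket and
is then discarded).

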