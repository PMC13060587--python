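# Methods

## Problem and model

`pocketdiff` generates small-molecule ligands jointly with the conformation
of the protein pocket that binds them. The system is a flat set of heavy
atoms — pocket atoms first, ligand atoms last, hydrogens excluded
throughout — with two coupled state variables per atom: a 3D coordinate and
a categorical atom type. Treating the pocket's coordinates as part of the
generated state (rather than frozen conditioning) is the point of the model:
side chains can rearrange while the ligand forms.

### Atom vocabulary

Types live in a single categorical vocabulary of `K = 19` tokens:
nine ligand elements (C, N, O, S, P, F, Cl, Br, I), eight protein tokens
(backbone `BB_N`, `BB_CA`, `BB_C`, `BB_O` from PDB atom names, plus
per-element side-chain tokens `SC_C/N/O/S`), a `RING_CENTER` token for a
virtual pseudo-atom placed at the centroid of each aromatic residue ring
(His/Phe/Tyr/Trp), and `UNK` for anything else. Only **ligand** atom types
are diffused; pocket and virtual atom types are fixed conditioning at every
step of the chain.

### Features

Each atom is a token. Sequence features are the one-hot type (K dims) plus a
one-hot role (backbone / sidechain / ligand / virtual). Pair features are a
same-residue indicator, the raw Euclidean distance, and a 16-bin Gaussian
radial basis encoding of that distance (centers evenly spaced on [0, 20] Å,
width equal to the 4/3 Å spacing, `exp(−½((d−c)/w)²)`). There are no
positional encodings — atoms are an unordered set — and no learned residue
identities. Pair distances are recomputed from the *current noisy*
coordinates at every diffusion step, so the network always sees the geometry
it must denoise. All features are invariant under rigid motions.

### Denoising network

An Evoformer-style two-track stack (default tiny config: 2 blocks,
`d_seq = 32`, `d_pair = 16`, 4 heads, transition width 64). Per block, in
order: gated multi-head sequence attention with an additive per-head bias
projected from the pair embedding; a position-wise transition MLP; a
sequence outer-product update into the pair track; triangle multiplication
(outgoing, then incoming); triangle attention (starting, then ending node);
and a pair transition. Triangle updates follow the AlphaFold formulations
(gated, residual); every residual-branch output projection is
zero-initialised so each block starts as the identity, which keeps early
training stable. The ending-node triangle attention is implemented as the
starting-node operation on the transposed pair tensor.

Two heads sit on the stack:

- **Coordinate head.** `Δx_i = Σ_{j≠i} w(z_ij) · (x_j − x_i)/(‖x_j − x_i‖ + δ)`
  with `δ = 10⁻⁶ Å` guarding coincident atoms and `w` a scalar projection of
  the layer-normalised pair embedding. Directions depend only on relative
  positions, so the output is exactly translation-invariant and transforms
  with any orthogonal map applied to the inputs. This is the noise
  prediction `ε̂`.
- **Type head.** A linear map on the layer-normalised sequence embedding
  produces K logits per atom — rotation-invariant by construction.

The diffusion timestep enters as a 16-dim sinusoidal embedding of `t/N_s`
concatenated to the sequence features. Coordinates are updated only by the
final head (one refinement per reverse step), not inside each block.

The stack runs on a purpose-built NumPy reverse-mode autodiff core
(`pocketdiff/nn.py`): a define-by-run tape over dense arrays with the ~15
primitives the network needs (broadcast arithmetic, two-operand einsum,
linear, softmax/log-softmax, layer-norm building blocks, sigmoid/ReLU) plus
Adam with global-norm clipping. Every primitive's gradient is verified
against central finite differences in the test suite. At the problem sizes
this package targets (≤ 400 atoms, embedding dims in the tens) dense NumPy
is entirely adequate on one CPU core.

## Diffusion processes

### Coordinates (variance-preserving, cosine)

`x_t = α_t x_0 + σ_t ε` with `α_t = cos θ_t`, `σ_t = sin θ_t`, `θ_t` linear
from 0 to `π/2 − 0.01` over `N_s = 100` steps. Hence `α_0 = 1, σ_0 = 0`
exactly (the chain ends on the data) and `α_N ≈ 0.016` (the start is
essentially pure noise) while `α_t² + σ_t² = 1` holds to machine precision
and `α_t` never vanishes, keeping the `x̂_0 = (x_t − σ_t ε̂)/α_t` inversion
finite. Reverse sampling uses the exact Gaussian posterior
`q(x_{t−1} | x_t, x̂_0)`; its variance is `σ²_{t−1} s²_t / σ²_t` (with `s_t`
the per-step noise), which is zero at `t = 1`, so the final step is
deterministic. With the oracle noise the reverse chain reproduces `x_0`
exactly — a property the tests assert to 10⁻⁶ Å.

All coordinates (pocket *and* ligand) diffuse by default; a flag freezes the
pocket for rigid-receptor ablations. Complexes are centred on the pocket
centroid before modelling, and every noise draw used in training and
sampling is projected onto the zero-centre-of-mass subspace of the diffused
atoms. This matters because the denoiser is translation-invariant: it cannot
see (or predict) a global translation component, and without the projection
the `1/α_t` inversion amplifies centre-of-mass drift early in sampling.
`forward_diffuse_coords` itself is kept pure (it applies whatever noise it is
given), so its marginal statistics match the closed form exactly.

### Atom types (D3PM, uniform kernel)

Single-step kernels `Q_t = (1−β_t) I + (β_t/K) 𝟙𝟙ᵀ` with `β_t` linear from
0.001 to 0.1 across the chain; cumulative products `Q̄_t` are cached. The
forward process draws each ligand atom's type from its `Q̄_t` row; the
reverse step combines the network's clean-type distribution
`ŝ_0 = softmax(logits)` with Bayes' rule,
`p(j) ∝ Q_t[j, s_t] · Σ_{s₀} ŝ_0[s₀] Q̄_{t−1}[s₀, j]/Q̄_t[s₀, s_t]`,
renormalised per atom (uniform fallback with a warning if a row degenerates).
Because `β_t` is small at small `t`, type identity locks in late in
denoising — after the geometry has largely converged — which is also the
behaviour one wants: types should be decided by local structure.

A note on convergence rates: the uniform kernel's non-unit eigenvalue is
`(1−β)`, so a constant-β chain approaches the uniform distribution with
residual `(1−1/K)(1−β)^t` — about 5.6×10⁻³ after 100 steps at β = 0.05.
The tests pin this closed form against a matrix-power oracle.

### Losses and training

`L = L_coords + λ·L_types` with `λ = 1`. `L_coords` is the mean over
diffused atoms of `‖ε̂ − ε‖²` (masked); `L_types` is the cross-entropy of
the type logits against the *clean* ligand types (x₀-parameterisation).
Each training step draws a complex, a uniform `t ∈ [1, N_s]` and one noise
realisation, and takes one Adam step. Defaults for the desk-scale recovery
benchmark: 6000 steps, learning rate 3×10⁻³ decaying by 0.9994 per step,
gradient-norm clip 10. Per-step losses stream to CSV
when a log path is given.

## Sampling and reconstruction

Sampling conditions on a pocket template (its ligand, if any, is discarded).
Coordinates initialise from `N(0, prior_scale²)` around the pocket centroid
(`prior_scale = 1 Å`, matching the unit-variance VP prior), ligand types
initialise uniformly over the vocabulary, and the reverse chain runs all
`N_s` steps, recording every intermediate state in a `Trajectory`
(steps strictly decreasing `N_s → 0`, so `N_s + 1` states). Ligand bonds of
the final structure are perceived as all pairs strictly closer than 1.9 Å;
bond orders are then assigned greedily — all bonds single, then the shortest
bonds upgraded to double while both partners have spare valence
(C ≤ 4, N ≤ 3, O ≤ 2, S ≤ 2, P ≤ 5, halogens ≤ 1). The ligand is exported as
SDF, the pocket as PDB; trajectories are stored as a JSON manifest plus one
`token,x,y,z` CSV per step (intermediate states contain non-element tokens,
which SDF cannot carry).

## Synthetic complexes

`make_fixture_complex(seed, n_residues, n_ligand_atoms)` emulates the
geometry of a small binding site: a self-avoiding chain ligand with bond
lengths uniform in [1.3, 1.6] Å and all non-bonded pairs ≥ 2.05 Å (so 1.9 Å
perception recovers exactly the generated, connected chain), elements drawn
C/N/O with weights 0.7/0.15/0.15, surrounded by five-atom backbone-like
residues (N, CA, C, O, CB at standard covalent distances) packed 3.6–5 Å
from the ligand surface — every residue passes the 6 Å pocket rule by
construction. Generation is deterministic given the seed (bounded retries
with a seeded restart counter). What the generator does **not** emulate:
torsional preferences, aromaticity, residue identity, protonation,
crystallographic context. Tests passing on these fixtures therefore
demonstrate the correctness of the machinery (equivariance, the diffusion
algebra, the pipeline) and the model's capacity to memorise and regenerate a
complex — not chemical realism of generated molecules on real proteins.

## The recovery benchmark and its metrics

The end-to-end benchmark trains the tiny network on ONE fixture complex
(10 ligand atoms, 2 residues, ≈ 20 atoms) and then samples 10 ligands from
noise with the training pocket. A draw succeeds if it matches the training
ligand to < 1.0 Å heavy-atom RMSD with ≥ 80 % correct atom types. Because
the sampler is permutation-equivariant and O(3)-equivariant and starts from
i.i.d. noise, generated atoms carry no index correspondence and no frame
(and arrive in either chirality); the comparison therefore uses the
RMSD-optimal rigid superposition *and* atom assignment, computed by
alternating Kabsch superposition with Hungarian matching from 24 random
initial rotations. This is the only well-defined comparison for an
equivariant generator; a per-index, fixed-frame comparison would fail for
any correct implementation.

## Evaluation metrics

Validity = RDKit sanitization plus an explicit valence audit against the
periodic table's allowed valences. Connectivity = a single bonded component.
Large ring = any SSSR ring with more than six atoms. QED is the Bickerton
composite; RO5 "pass" means at most one violation of {MW ≤ 500, logP ≤ 5,
HBD ≤ 5, HBA ≤ 10} (the conventional reading); SAS is the Ertl–Schuffenhauer
score via the scorer shipped with RDKit. Metrics that require a sanitized
molecule are reported only for valid AND connected molecules, null
otherwise. The functional-group census reports, per SMARTS pattern, the
fraction of molecules containing at least one match (an occurrence-count
mode exists too); the library ships curated patterns for the usual organic
classes — e.g. carboxylic acids `C(=O)[OH]` and primary/secondary amines
`[NX3;H2,H1;!$(NC=O)]`, which deliberately excludes amide nitrogens — and is
extensible from a TSV. Tanimoto similarity uses RDKit topological
(Daylight-like) fingerprints. Pocket RMSD superposes with Kabsch by default
(`align=False` gives the raw fixed-frame value, since it is not obvious
which convention a given study used — both are one flag apart).
Trajectory RMSD-to-final is deliberately raw: the whole trajectory lives in
one frame and superposition would hide the convergence being measured.

## Dataset splitting

Complexes are linked when sequence identity > 30 %, pocket RMSD < 2 Å, or
ligand Tanimoto > 0.85; connected components of that graph are indivisible
groups, assigned greedily in seed-shuffled order to fill the 20 % test side,
remainder train. Similarity matrices are *inputs* (alignment and structural
similarity come from external tools in production); a naive
Needleman–Wunsch identity is included for exercising the logic on synthetic
data. A warning is raised when one group exceeds 80 % of the data, making
the requested ratio unsatisfiable. The audit property — no train/test pair
crossing any threshold — is asserted exhaustively in the tests.

## Numerical choices and degenerate inputs

- Bond perception uses strict `<` at the cutoff (an exact-cutoff pair is
  not a bond); pocket-residue retention uses inclusive `≤` at 6 Å.
- `δ = 10⁻⁶ Å` in the coordinate head; layer-norm `ε = 10⁻⁵`.
- Degenerate masks (nothing to diffuse) give zero losses with a warning;
  degenerate D3PM posterior rows fall back to uniform with a warning.
- Single-atom systems: empty bond sets, zero displacement from the head.
- Checkpoints embed the config and RNG seed; loading reproduces outputs
  bit-for-bit.

## Problem sizes

Tests and the acceptance script run everything at desk scale: ~20-atom
complexes, the 2-block network, 100 diffusion steps, 6000 training steps,
10 sampling draws, 10⁵-draw Monte-Carlo checks. Training on a corpus of real
complexes is supported by the same `Trainer` (it accepts a list of
complexes) but is outside the scope of the shipped experiments.

## Known limitations

- Chirality: the network is equivariant under the full orthogonal group, so
  mirror-image solutions are equally likely; the recovery metric's Kabsch
  step uses proper rotations only, and enantiomeric draws simply score
  worse.
- The uniform D3PM kernel ignores element priors; an absorbing-state kernel
  may be a better fit for sparse vocabularies.
- Bond-order assignment is a geometric heuristic; it does not attempt
  aromatic perception beyond what RDKit sanitization infers afterwards.
- No protonation, tautomers, metals, waters, altlocs, or covalent ligands.
- Generation quality on real pockets depends entirely on training breadth;
  the shipped defaults are sized for single-complex memorisation tests.
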