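# Methods

## Problem and model

`tridta` predicts the binding affinity of a drug–target pair from the
drug's SMILES string and the protein's amino-acid sequence. The label is
a continuous affinity: pKd = −log10(Kd/10⁹) for dissociation constants
measured in nM (so Kd = 10,000 nM maps to the weak-binder boundary 5.0),
or a KIBA-style composite score. The model is a three-branch graph
neural network:

1. **Drug atom graph** — heavy atoms as nodes (78-dim features: one-hot
   element over a 44-symbol vocabulary with an unknown slot, one-hot
   degree/total-H/implicit-valence each over 11 bins, and an aromatic
   flag), bonds as edges.
2. **Drug motif graph** — a coarsening whose nodes are SSSR rings and
   non-ring bonds together with their two atoms (92-dim features:
   multi-hot symbols, one-hot atom count and inter-motif degree over 11
   bins, one-hot total H and summed implicit valence over 12 bins, and
   simple-ring / bond-unit flags). Two motifs are adjacent when they
   share an atom or a bond connects their atom sets.
3. **Weighted protein graph** — residues as nodes (33-dim features:
   one-hot type over the 25-letter alphabet, five class flags, and three
   rescaled physicochemical scalars), with an edge wherever the
   predicted residue–residue contact probability is ≥ 0.5, weighted by
   that probability.

Each branch runs three graph-convolution layers (GCN with symmetric
normalization over the self-looped, optionally weighted adjacency, or
single-head GAT with self-inclusive softmax attention) sized
N → 4N → 4N → 4N. Layers two and three are fused with their input by a
gated skip-connection z = σ(H_new U1ᵀ + H_old U2ᵀ + b),
H ← z⊙H_new + (1−z)⊙H_old — an elementwise convex combination that
preserves multi-scale features as depth grows. Max (default) or mean
pooling and two FC+dropout stages (4N → 1024 → 128) yield a 128-dim
embedding per branch. A shared scorer wᵢ = W2·tanh(W1·Zᵢ) and a
three-way softmax produce attention weights α, the weighted embeddings
are concatenated (384-dim) and a 384 → 1024 → 512 → 1 ReLU head
regresses the affinity. Training minimizes MSE with Adam.

## Contact maps for long sequences

Contact prediction is a pluggable callable (sequence → symmetric L×L
probability matrix); transformer contact predictors have a ~1024-token
context, so sequences longer than 1000 residues are assembled from
sliding windows of width 2×windowsize (default 1000) advanced by
windowsize along the diagonal. Cells covered by several windows hold
the mean of the window predictions; pairs separated by more than the
window width lie outside every window and stay 0 — an inherent blind
spot of the scheme. When the last regular window stops short of the
sequence end, one extra window anchored at L − 2×windowsize is added so
the whole band is covered; tests assert full band coverage for lengths
up to 4000. The retained-edge comparison is ≥ 0.5 (ties kept); both the
threshold and the window size are configurable.

The real pretrained contact model is deliberately out of scope: the
package ships three deterministic stubs (constant, distance-banded,
and a content/position-dependent pseudo-random one whose overlapping
windows disagree, making the averaging path observable). An adapter for
a real predictor only needs to satisfy the same callable contract.

## Design choices where the design was open

- **Atom vocabulary.** The 44-slot symbol list is the common
  organic-plus-metals convention used by graph DTA models, with the last
  slot for unknown symbols; it is serialized (and hashed) with every
  checkpoint.
- **Fused rings.** Ring perception is SSSR, one motif per ring;
  edge-fused systems (naphthalene) give one motif per SSSR ring joined
  by an edge, and their rings are not flagged "simple". Bond membership
  is a partition: a bond shared by two SSSR rings is assigned to the
  first ring in perception order.
- **Out-of-range counts clamp** to the final one-hot bin rather than
  erroring, so featurization is total on valid molecules.
- **Layer widths.** "N, 4N, 4N" is read as layer input widths with all
  outputs 4N; the gate needs equal widths, so it applies to layers two
  and three only.
- **Gates** U1, U2 are square trainable matrices and the gate is
  elementwise per node and feature — the most expressive reading of a
  learned proportion coefficient.
- **GAT** uses one attention head, LeakyReLU slope 0.2 in the logits,
  ReLU as the outer nonlinearity (matching the GCN), self-inclusive
  neighborhoods (no empty softmax on isolated residues), and ignores
  protein edge weights (attention replaces them); GCN consumes them.
- **Projection depth.** "Several" FC+dropout stages down to 128 is
  implemented as two.
- **Head activations** are ReLU with a linear output; dropout 0.2 after
  both hidden stages.
- **rm².** The published formula is typographically garbled; the
  canonical rm² = r²(1 − √(r² − r₀²)) is used, with r₀² from the
  through-origin least-squares fit of y on p (the convention of the
  standard DTA benchmark code). A slightly negative radicand is clamped
  to zero with a warning.
- **Concordance index.** Pairs tied in the true affinity contribute to
  neither numerator nor normalizer; all-tied inputs raise an explicit
  error.
- **Splits.** The 6-part split with one held-out part is the default;
  any part count is supported. Within the training folds one fold is
  held out for best-validation checkpoint selection (the benchmark
  protocol does not specify one; final-epoch weights are also saved
  implicitly in the history).

## Numerical backend

No GPU tensor framework is assumed: the encoders, fusion head and Adam
are built on a small reverse-mode autodiff engine over float64 NumPy
arrays (`tridta/_autodiff.py`), with sparse-matrix message passing
(scipy CSR) and sort+reduceat segment reductions. Eval-mode forward
passes are bit-deterministic; node relabeling changes results only at
float-summation-order level (~1e-15), and the permutation-invariance
tests use `atol=1e-8`.

## Synthetic benchmark: what it emulates and what it does not

The generator emulates the *shape* of a DTA benchmark, not its
chemistry: fragment-assembled SMILES (guaranteed parseable, both ring
and acyclic motifs present), random sequences over the 20 standard
residues with lengths straddling the 1000-residue window limit, stub
contact maps, and labels with a known linear dependence on features
each branch can see —

    raw = a·(ring count) + b·(length/max length) + c·(shared-letter
    fraction),

rescaled affinely into the Davis-like span [5.0, 10.8], plus Gaussian
noise (default σ = 0.1 in label units). Coefficients (a = b = c = 1),
the affine scale, and noiseless values are recorded in a manifest.
Default sizes: 16 drugs × 8 proteins, 64 measured pairs, sequence
lengths 60–1100.

Passing the end-to-end checks therefore shows that the architecture can
extract and fuse signal present in its three graph views and that the
pipeline is wired correctly end to end; it says nothing about accuracy
on real binding data, where labels are not a linear function of cheap
topological statistics and contact maps come from a real structure
predictor.

Desk-scale training conditions ("smoke" profile): 200 epochs, batch 16,
learning rate 2e-3, GCN convolutions, max pooling, with the head's
output bias initialized at the mean training label. The higher learning
rate (vs the benchmark profile's 5e-4) is the standard choice for short
small-batch runs. The benchmark ("paper") profile keeps 2000 epochs,
batch 512, lr 5e-4, GAT. The label-shuffled control reported next to
the held-out concordance index is the mean CI over 100 label
permutations — a single permutation of ~11 test labels has a standard
deviation of ~0.1, so averaging is what makes "≈0.5" checkable.

## Known limitations

- Stereochemistry and 3D geometry are ignored: optical isomers receive
  identical graphs.
- Contacts beyond the window width are structurally zero for long
  sequences.
- The residue feature table's composition (25+5+3) is a documented
  package choice; other splits of the 33 dimensions are possible.
- Single-head GAT only by default (head count is a config knob, not
  exercised by the benchmark profile).
- Training is CPU-only and single-process; the benchmark-scale profile
  (2000 epochs × batch 512 on ~30k pairs) is far beyond desk scale.
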