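# Methods

## Overview

`gppi` predicts whether two proteins physically interact from their 3D
structures alone. Each protein is reduced to its Cα trace and represented as
a **residue contact graph**: nodes are residues carrying a 5-dimensional
physicochemical feature vector, and an undirected edge connects residues
whose Cα–Cα Euclidean distance is strictly below 9.5 Å. A shared-weight
(Siamese) graph-attention encoder maps each graph to a fixed-size embedding;
a symmetric head converts a pair of embeddings into an interaction
probability. Predicted interactions are explained by gradient saliency:
residues whose input features most influence the probability are reported as
candidate interface hotspots.

## Residue features

The five properties are hydrophobicity, van der Waals volume,
polarizability, isoelectric point (pI) and dissociation constant (pKa), each
min-max normalized to [0, 1] over the 20 standard residues, so 1.0 always
denotes the residue expressing that property most strongly. The shipped
default table (`gppi/data/aa_properties.tsv`, versioned and hash-stamped
into every model checkpoint) is assembled from published scales:

| column | raw source | units |
|---|---|---|
| hydrophobicity | Kyte–Doolittle hydropathy index | dimensionless |
| volume | van der Waals residue volume (Darby & Creighton) | Å³ |
| polarizability | Charton–Charton polarizability parameter | dimensionless |
| pI | computed as (pKa₁ + pKa₂)/2 — see below | pH units |
| pKa | side-chain pKa where ionizable, α-carboxyl pKa otherwise | pH units |

pI is the mean of the two pKa values flanking the neutral species: for
residues with an acidic side chain (D, E, C) the α-carboxyl and side-chain
values, for basic side chains (H, K, R) the α-amino and side-chain values,
and the two backbone values otherwise. Residues without an ionizable side
chain have no natural entry for the pKa column; we use the α-carboxyl pKa,
which groups them tightly and far from the strongly ionizable residues.
Both the raw table and the normalized table are plain-text files, so any
alternative scale can be substituted via `build_property_table`.

## Contact graphs

Edges use the strict rule d < 9.5 Å between Cα atoms; each edge stores its
exact Euclidean distance. Consecutive residues of a polypeptide (Cα spacing
≈ 3.8 Å) are therefore always connected, so a single chain yields a
connected graph. For structures above 500 residues a k-d tree prunes the
candidate pairs, but the retained edge set is decided by the same distance
expression as the brute-force scan, so both search paths are exactly
equivalent (this equivalence is a standing test). Multi-chain structures
form one graph; inter-chain edges are allowed because the rule is purely
geometric. No self-loops are added — the encoder keeps a residual path
around each attention layer instead.

## Model

The encoder is a GATv2 stack: attention logits are computed by applying the
scoring vector **after** the LeakyReLU (slope 0.2) of the combined
source + target transform, which makes the attention strictly more
expressive than the original formulation. Details:

* input projection 5 → `hidden_dim`, ELU;
* `n_layers` attention rounds (default 8; the learnability experiments use
  2). Multi-head outputs are concatenated in intermediate layers and
  averaged in the final layer; each round sits inside a residual connection
  with layer normalization, followed by ELU and (during training) dropout;
* when `use_edge_distance` is on (default), the dimensionless edge length
  distance/cutoff ∈ (0, 1) is appended to the neighbor-pair representation
  before scoring, letting attention discount distant contacts;
* graph embedding = mean over node states, projected to `embedding_dim`
  (mean pooling keeps the embedding size-invariant);
* pair head: the two embeddings h_a, h_b enter only through the symmetric
  combination [cos(h_a, h_b), |h_a − h_b|, h_a ⊙ h_b], followed by a small
  feed-forward layer and a sigmoid. Swapping the inputs is a bitwise no-op,
  so p(a, b) = p(b, a) exactly. A pure-cosine variant
  (sigmoid(w·cos + b)) is available via `pair_mode="cosine"`; the learned
  head is the default because training uses binary cross-entropy on a
  probability output, and the cosine similarity alone cannot express the
  "both carry an interface-like surface" conjunction.

Defaults (4 heads, hidden 64, embedding 128, dropout 0.1, head width 32)
are artifact choices exposed in `EncoderConfig`, not claims about the
published production model, whose width and head count are not public.

The whole model runs on a small reverse-mode autodiff core written for this
package (`gppi.autograd`), so the identical forward pass serves prediction,
training and input-gradient saliency. The attention block is implemented as
one fused operation with a hand-derived adjoint for speed; its correctness
is pinned by central-finite-difference checks run in the test suite.

## Training

`split_leakage_free` partitions proteins — not pairs — between training and
validation: connected components of the pair graph are assigned whole to one
side, so the protein sets touched by the two sides are provably disjoint and
no pair can span them (the drop counter required by the contract is
therefore structurally zero, and is still reported). Dense pair sets that
form a single component admit no such split and raise an error; in that
regime a pair-level holdout is the only option, and that is what the
synthetic learnability experiment uses.

Optimization: binary cross-entropy, adaptive-moment (Adam) optimizer at
lr 10⁻³, gradient-norm clipping at 1.0, shuffled batches of 128 pairs,
20 epochs, no scheduler and no class weighting (the datasets this mirrors
are near-balanced). After each epoch the MCC is computed on a balanced
held-out subset at threshold 0.5. The final-epoch model is returned; the
best-eval-MCC epoch can additionally be checkpointed. All randomness
(shuffling, dropout, initialization) flows from explicit integer seeds, and
identical (seed, data, config) reproduce the loss series to float precision
on a fixed thread count.

## Evaluation

A pair is predicted positive iff its score is **≥** the threshold; the
boundary case is deliberately positive. MCC uses the four-cell formula with
the zero-denominator → 0 convention. AUC is the trapezoidal ROC integral,
identical to the Mann–Whitney probability that a random positive outscores
a random negative with ties counted ½ (asserted against a pairwise-count
oracle). At thresholds where nothing is predicted positive, precision is
reported as 1.0 with an explicit `undefined` flag so threshold scans are
not poisoned by 0/0. `optimal_threshold` maximizes precision over all
candidate thresholds (unique score values plus 0) subject to a sensitivity
floor (default 0.96, the operating rule of the released predictor), ties
resolved toward the largest threshold. Because threshold 0 predicts
everything positive, any floor ≤ 1 is achievable; the infeasibility error
can only fire for an invalid floor.

## Saliency and hotspots

The gradient of the interaction probability with respect to every node
feature of both proteins is obtained by backpropagation through the scalar
output; a residue's saliency is the L2 norm of its 5 feature gradients
(sum of absolute values available as an option). The gradient target is the
probability, matching the released behaviour; a logit-target option avoids
vanishing gradients under sigmoid saturation and leaves the within-pair
residue ranking unchanged, since the sigmoid derivative scales every
gradient of the pair by the same factor. Saliency statistics are computed
per protein. Hotspots are residues scoring strictly above
mean + 2·SD of their own protein's profile, capped at the top 10 and
ordered by descending score; the rule is configurable because no canonical
cutoff exists. A flat profile yields no hotspots by construction. Hotspots
are reported only for predicted binders — an "interface" of a predicted
non-interaction is not meaningful.

Finite-difference validation caveat: central differences mis-estimate the
derivative when the ±h interval crosses a LeakyReLU kink. The gradient
check therefore records the sign pattern of every LeakyReLU input at both
evaluation points and resamples positions where they differ; away from
kinks, analytic and numeric gradients agree to ~10⁻⁷ in double precision.

## Synthetic data

The generator produces everything the pipeline needs offline, with known
ground truth:

* **Backbones**: persistent self-avoiding random walks with consecutive Cα
  spacing exactly 3.8 Å and ≥ 4.0 Å clearance between non-consecutive
  residues. These are geometrically plausible Cα traces with realistic
  local contact density — not folded proteins: they have no secondary
  structure, no hydrophobic core, no recurring topology.
* **Planted interaction rule**: half the proteins (configurable) carry a
  "sticky patch" — a contiguous run of 8 residues rewritten to the
  maximum-hydrophobicity residue (isoleucine under the default table),
  while the background sequence is drawn only from residues with normalized
  hydrophobicity ≤ 0.9. A pair interacts iff both proteins carry a patch.
  Planting at the residue-identity level (rather than mutating feature
  matrices) keeps the world consistent under PDB export/re-parsing while
  being equivalent from the model's perspective, which only sees the
  5-dim features. Pairs are sampled to an exact 50/50 label balance.
* **Separability certificate**: before any learning-based test runs, a
  feature-threshold oracle ("≥ 8 residues with hydrophobicity > 0.9 in both
  proteins") is asserted to reach MCC 1.0 on the generated pairs, so a
  failed learning test indicts the model, never the data.

Default scale: 200 proteins of 30–60 residues and 1,000 pairs — small
single-domain size, chosen once as a desk-scale stand-in for curated
interactome datasets. Because the patch is contiguous in sequence and the
walk is spatially local, recovering patch residues by saliency is a
meaningful test of the explanation machinery.

What passing these tests shows — and does not show: they demonstrate that
the pipeline can learn a feature-localized, exactly separable interaction
rule and attribute it to the correct residues. Real interactomes are noisy,
geometrically mediated and far from separable; published headline metrics
depend on curated datasets and trained weights that are out of scope here,
so no synthetic result should be read as reproducing them.

## Numerical choices

* Float64 throughout by default (`EncoderConfig.dtype`); symmetry holds
  bitwise, and gradient checks run in double precision.
* Strict inequality at the 9.5 Å cutoff; an edge at exactly 9.5 Å does not
  exist (and 9.5² is exactly representable, so the boundary is clean).
* Cosine similarity uses an ε = 10⁻¹² guard inside the norms; the
  self-pair cosine is 1 up to that ε.
* Attention softmax subtracts the per-neighborhood maximum before
  exponentiation; isolated nodes (no in-edges) receive a zero attention
  message and propagate through the residual path.
* Layer-norm ε = 10⁻⁵; Glorot-uniform initialization; attention-distance
  weights start at 0 so the distance term is learned from zero rather than
  injecting noise.
* Ties in hotspot ordering break by residue position; ties in
  `optimal_threshold` break toward the larger threshold.

## Known limitations

* No pretrained weights are shipped; published performance figures are not
  reproducible without the authors' curated data and compute scale.
* Structures lacking Cα atoms, and intrinsically disordered proteins, are
  outside the model's assumptions.
* The property table ships one defensible default per scale; the
  polarizability scale used by the published model is not stated anywhere,
  so no result here should be tied to specific default values (tests only
  rely on normalization invariants).
* Training is single-device and in-memory; it is sized for 10²–10⁴ pairs,
  not 10⁵-pair interactomes.
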