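# Methods

## Problem and model

The toolkit classifies fixed-length DNA windows around putative transcription
start sites. Two encodings of each window feed two branches whose features are
fused for the final decision.

**One-hot (quadrature) encoding.** A sequence B₁…B_L over {A, C, G, T} becomes
a 4 × L indicator matrix with rows ordered (A, C, G, T). No information is
lost; the CNN branch (PSFN) is responsible for discovering positional motifs.

**Structural-profile encoding.** Each of the 16 dinucleotides carries twelve
physicochemical/conformational property values (A-philicity, base stacking,
B-DNA twist, bendability, bending stiffness, DNA denaturation, duplex disrupt
energy, duplex free energy, propeller twist, protein deformation, protein–DNA
twist, Z-DNA propensity). Sliding a 2-bp window with stride 1 gives a
12 × (L−1) matrix per sequence. Each property row is standardized across its
16 dinucleotide values before use:

    std(P, d) = (P(d) − mean_d P) / sd_d P

with the *population* standard deviation (divide by 16): the 16 dinucleotides
are the exhaustive population of the property, not a sample. Standardization
happens once, globally, from the bundled table — not per dataset — so encoded
values are comparable across datasets and species. A zero-variance property
row is rejected as an error.

The bundled table (`hmpi/data/structural_properties.tsv`) is compiled from
the primary literature scales named in its header comments. The values are
best-effort transcriptions; because every row is standardized and the
classifier learns its own weighting, pipeline behaviour depends only on the
relative ordering within rows. Users with a vetted table can pass their own
file (same format) to `load_property_table`.

## The branches

**PSFN.** Three convolution blocks (conv → LeakyReLU(α = 0.2) →
Dropout(0.25)) with 32, 64, 128 feature maps and kernels 3, 4, 5; "same"
padding, stride 1, no pooling, so positional resolution is preserved and the
flattened size is 128·L. A dense layer with ReLU maps the flatten to the
128-dimensional sequence feature; a K-way softmax head sits on top. Training
minimizes CCE plus λ‖x − c_y‖². The class centres c_y form an embedding
(K × 128) trained by gradient together with the network. λ defaults to 0.01
(the centre term is a correction, not the main objective; at feature norms of
order 10 this makes the two terms comparable). The centre embedding has its
own Adam learning rate (default 0.1): with the shared rate of 1e-3 the
centres cannot track the feature-space class means within a run and the
centre term degenerates into uniform feature shrinkage (at larger λ,
feature collapse through the ReLU). With the faster centre rate, the
between-class/within-class separation ratio of the learned features is
consistently higher with λ = 0.01 than with λ = 0 at matched seeds, which is
the measurable form of the centre loss's compactness claim. λ = 0 recovers
the plain-CCE twin (PSFNcce) exactly — same architecture, same seed, same
loss trace.

**DSPN.** The flattened SP matrix (row-major, property-major — the flattening
order is a convention we fix and document) passes through seven blocks of
Dense → LeakyReLU(0.2) → Dropout(0.2) → BatchNorm — batch-norm *after*
dropout — a deliberate, fixed composition order, even though the reverse is
more common in practice. The raw SP input is concatenated into the inputs
of blocks 3 and 6, and the block-2 output additionally into block 6
("linked" is read as concatenation, consistent with how the SP inputs are
attached; an additive reading would force equal widths, which the block
sizes do not have). Block widths: 250/1000/250/1000/1500/1000/128
(251-bp preset) or 80/500/80/150/500/500/128 (81-bp preset). The block-7
output is the 128-dimensional structural feature; the head is Dense(K) +
softmax trained with plain CCE. LeakyReLU α is shared with the PSFN (stated
only for the sequence branch; assumed common). The skip concatenations give
the input gradient at least two independent routes to the loss, verified by
severing the block-1 path in tests.

**Fusion.** The 128 + 128 concatenated features pass through Dense(64) +
ReLU and a K-way softmax. The default regime is `pretrain_then_head`: each
branch is trained on its own loss, frozen, and the head fitted on the
extracted features — mirroring the way the branches are meaningful models on
their own. An end-to-end `joint` regime (summed losses, including the centre
term) is provided as an option.

**Variants.** `lsr` swaps the head's CCE for label-smoothing CCE with
ε = 0.2 (targets ε/K off-class, 1 − ε + ε/K at the true class); nothing else
changes. `at` targets imbalanced subtype data: after pretraining, ADASYN is
applied in the transferred feature space — the PSFN second-block output,
global-average-pooled over positions to a 64-vector, concatenated with the
128 DSPN features. One-hot inputs themselves are not meaningfully
interpolable, which is why resampling happens in feature space; the pooled
block-2 reading of "second layer" follows the block structure of the CNN and
yields a fixed-length, resampling-friendly vector. Including the DSPN
features keeps the head's input space consistent between variants.

## ADASYN

For minority sample i, difficulty r_i is the fraction of majority points
among its k nearest neighbours (k = 5, Euclidean distance in z-scored
feature space); the synthetic budget G = (n_maj − n_min)·balance_level is
split proportionally to the normalized r̂_i (uniform fallback when all
r_i = 0, i.e. perfectly separated classes), integerized by largest
remainders so the total is exact. Each synthetic row is x_i + u(x_z − x_i),
u ~ U[0,1], x_z a random minority k-neighbour, so synthetic rows are convex
combinations of minority pairs and stay inside the minority bounding box.
Originals are never altered; a minority class with ≤ k members falls back to
duplication (flagged). Multi-class data is balanced one minority at a time
against the union of the other classes, each up to parity with the largest
class (balance_level = 1 by default; not stated in the source protocol,
exposed as a parameter).

## Training defaults

Adam (lr 1e-3, β = 0.9/0.999), batch 64, up to 50 epochs with early stopping
on validation loss (patience 5, best parameters restored). These are standard settings at this
model scale, exposed on every spec dataclass. All randomness — initialization, dropout masks, shuffling, ADASYN
draws — flows from explicit numpy generators seeded by the caller, so runs
are bit-reproducible at a fixed seed and thread count. Probabilities are
floored at 1e-12 before logarithms so losses stay finite; Mcc with a zero
marginal is reported as 0 with a degeneracy flag. Evaluation mode disables
dropout and uses frozen batch-norm running statistics, making inference a
pure function of parameters and input.

Multi-class subtype evaluation reports per-class one-vs-rest confusion
summaries next to the top-level report; both a 6-way multiclass mode and
separate binary tasks are expressible (the choice of per-subtype protocol is left to
the user; neither mode is asserted as canonical).

## Synthetic benchmarks: what they show and what they do not

The generator plants two independent signals: a consensus motif (default
TATAAT, per-position mutation probability 0.1, position jitter ±2 around the
window centre) for the sequence branch, and a first-order Markov composition
tilt (self-transition of a class-specific base and its complement raised by
0.2) for the structural branch, which must recover it through the SP
encoding — SP values are never injected directly. Negatives are i.i.d.
uniform. Mutation probability 1 (mutations drawn uniformly over all four
bases) plus zero tilt gives an exact null: positives and negatives are then
identically distributed, and trained models sit at chance.

The standard binary benchmark uses 2,000 training / 500 test sequences of
81 bp with branch training capped at 12 epochs (patience 4) — validation
loss plateaus by epoch 8–10 at this scale, and the full benchmark stays
within a few CPU-minutes. At these settings the sequence branch exceeds 0.90
test accuracy, the structural branch 0.85, and the hybrid tracks the best
branch.

The imbalance benchmark (two subtypes, 1200:120) deliberately uses a noisier
task — motif mutation 0.3 and composition tilt 0.08 — because with the
binary-benchmark signal strengths the minority class is already learned
nearly perfectly and there is no imbalance pathology for resampling to
correct. In the noisy regime, the ADASYN + transfer variant roughly doubles
minority one-vs-rest Mcc over the plain hybrid at matched seeds.

Passing these benchmarks shows the pipeline is implemented coherently —
encodings are exact, losses and gradients correct, the branches learn the
kind of signal they are built for, and the imbalance machinery helps where
it should. It does **not** show field performance on real promoters: the
generator has uniform backgrounds, a single motif per class, no promoter
grammar (Inr, CAAT, CpG islands), and structural signal far simpler than
real conformational biology. Claims about real EPD/RegulonDB-scale accuracy
require the corresponding datasets.

## Known limitations

* The numpy engine is single-device and eager; it is sized for the window
  lengths above, not genome-scale scanning.
* The bundled property table is a literature compilation, adequate for the
  transformation contracts the tests pin down; biophysical conclusions
  should use a verified table via the override path.
* Exact bit-reproducibility holds per BLAS configuration; across different
  BLAS builds or thread counts, training trajectories may differ in the last
  bits (evaluation-mode forward passes remain deterministic for fixed
  parameters).
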