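# Methods

This note records the modeling choices behind `bcrlm`: what the
synthetic data generator does and does not emulate, the exact loss and
schedule definitions, the numerical decisions, and the limits of what
desk-scale experiments can show.

## Synthetic repertoires

The generator assembles each heavy chain as
`V + junction₁ + D + junction₂ + J` (light chains: `V + junction + J`),
drawing segments from seeded germline pools. Pool sizes default to
75 heavy V / 27 D / 6 J plus 110 light V / 12 light J so that the
combined gene-symbol count is 230 and the full vocabulary reproduces
its 260-token size. Junctional diversity is the minimal mechanism that
produces a realistic CDR3 length spread: 0–6 uniformly random residues
at each join (4–10 for the single light-chain junction). The CDR3 is
defined structurally, as the span from the V-terminal cysteine anchor
to the start of J, and its coordinates are stored explicitly so no
antibody numbering scheme is needed.

Somatic hypermutation is modeled as independent per-residue
substitution to a uniformly random different amino acid, at a
subtype-specific rate (defaults: 0 for immature, 0.005 naive, 0.03–0.08
for memory/plasmablast/plasma, all within [0, 0.25]). Isotype usage is
a per-subtype multinomial over {IgM, IgD, IgG, IgA, IgE}; the defaults
make antigen-inexperienced subtypes IgM/IgD-dominant and class-switched
compartments IgG/IgA-dominant. Phenotype signal is planted as a
subtype-specific 5-mer written into the CDR3 immediately after the
cysteine anchor with probability `motif_strength`; at strength 1 a
trivial motif-presence classifier separates subtypes with >95%
accuracy, which guarantees the contrastive objective has signal to
find. The default six-subtype label set (immature, naive, unswitched
memory, switched memory, plasmablast, plasma) is a configurable
placeholder: real studies use cohort-specific annotations.

Simulated light chains carry their locus constant region (IGK/IGL) in
the isotype field; the tokenizer maps any token outside the five-label
isotype block to `[UNK]`, so the vocabulary's isotype block stays at
five. What the generator does **not** emulate: AID hotspot targeting,
nucleotide-level recombination, clonal lineage structure, paired
chains, or realistic germline sequence families. Tests passing on this
generator therefore demonstrate that the machinery recovers planted
signal under the stated statistical structure — not that it resolves
the weaker, confounded signals of real repertoires.

Paratope sets are random sequences with a contact motif planted at a
random offset; labels mark the motif span plus a configurable number of
random extra contacts. With `extra_contacts = 0` every positive label
is deterministically recoverable from sequence, which is the regime the
fine-tuning learnability checks use; extra random contacts lower the
achievable AUROC ceiling by construction.

## Curation

Identity is defined by exact global alignment with match +1 /
mismatch 0 / linear gap −1, ties broken toward fewer gaps (then
diagonal > up > left), identity = matches / alignment columns. This is
deliberately *not* CD-HIT's word-based heuristic: the 95% contract is
what matters, and an exact, deterministic definition is
oracle-testable. Clustering is greedy and incremental over records
sorted by descending length: a record joins the first representative at
identity ≥ threshold, else founds a cluster. Because a new
representative is only created when *all* existing representatives are
below threshold, representative pairs — and hence any test/train pair
after splitting representatives — are always below 95%. A
residue-multiset upper bound (`Σ_c min(count_a, count_b) / max(len)`)
screens out hopeless pairs before the quadratic alignment; the bound
never underestimates, so the screen is exact. Heavy and light chains
are clustered separately.

QC rejection precedence is fixed (missing CDR3 → incomplete V(D)J
annotation → CDR3 length outside 6–29) so per-rule counts are
unambiguous; light-chain CDR3s are filtered with the same bounds by
default. Splitting shuffles by seed and assigns contiguously by
cumulative ratio with floor-then-distribute rounding; leftover records
go first to still-empty parts with positive ratio, then by largest
fractional remainder, so small inputs never starve the validation set
(3 records at 90:5:5 give 2/1/0, not 3/0/0).

## Tokenization

Layout: `[CLS] residues… [SEP] v (d) j isotype [SEP]`, padded to
`max_len` (148 by default). Metadata order is fixed (V, D, J, isotype)
to make encodings canonical; light chains omit the D slot entirely
rather than emitting `[UNK]`, keeping their lengths honest. Truncation
removes residue tokens from the C-terminal end only, so the V-proximal
framework and the metadata tail always survive. The tokenizer is
chain-agnostic — no token identifies heavy versus light. HCDR3 mode
replaces the residue segment with the CDR3 alone and is otherwise
identical, so an HCDR3-mode encoding equals the full-length encoding of
a record whose sequence *is* the CDR3.

## Encoder

A post-layer-norm BERT encoder (GELU activations, learned positions,
no token-type embeddings, no pooler) implemented as pure functions of a
parameter tree on numpy, differentiated with `autograd`. The MLM head
is dense → GELU → layer norm with output weights tied to the token
embeddings and a free bias; with the 12/12/768/3072 preset, vocabulary
260 and length 148 this gives 85,961,732 trainable parameters
(≈86 M) — the tie and the absence of a pooler are required to land at
that count. Dropout (default 0.1) is applied as precomputed
inverted-dropout masks on the embedding output and the two sublayer
outputs per layer; attention probabilities are not dropped. Attention
masking adds −10⁹ to pad keys before the softmax, so rows normalize
over real tokens and attention to padding is exactly zero. LayerNorm
epsilon is 1e-5 (see the integrated-gradients note below). Weights are
initialized N(0, 0.02²), seeded.

## Training

Masking follows the 15% / 80-10-10 recipe over maskable positions
(real, non-special tokens — residues *and* metadata); random
replacements are drawn from the amino-acid block. The MLM loss
normalizes by batch size only (a per-sequence *sum* over masked
positions), so its uniform-logit value on one masked position is
ln(vocabulary size) and it is linear in the number of masked positions.

The printed form of the contrastive loss leaves the denominator
semantics open; it is implemented as standard supervised InfoNCE: for
anchor *i* with positive set P(i) (same subtype, excluding self), the
loss averages −log softmax over all other batch members, per positive,
then over anchors with at least one positive. Anchors without positives
are skipped. The contrastive pass embeds the *unmasked* encoding (a
second forward pass) so the phenotype geometry is not corrupted by
masking noise. Temperature defaults to τ = 0.07 and the mixing weight
to w_cl = 0.1 (0.5 in the demo configs, where the phenotype signal is
the experiment's point); both are mandatory config fields. At w_cl = 0
the contrastive branch is never executed and the run is bit-for-bit a
pure-MLM run.

Class-balanced sampling draws classes uniformly, then members uniformly
within class, with replacement. The learning-rate schedule warms up
linearly from 0 to the peak (default 1e-4) over the first 5% of steps,
then holds; after three consecutive evaluations without validation-loss
improvement the rate is multiplied by 0.3 and the counter resets
("steps" in the plateau rule are evaluation intervals, not optimizer
steps). The optimizer is Adam with decoupled weight decay 0.01 applied
to matrices only, betas (0.9, 0.999). Desk-scale runs use a higher peak
rate (1e-3): at a few hundred steps the full-scale peak would barely
move a freshly initialized model.

## Evaluation

ARI, NMI (arithmetic-mean normalization), macro precision/recall/F1,
the generalized multiclass MCC, AUROC and average precision are
computed via scikit-learn behind the module surface; silhouette is
implemented in-package because the package fixes the singleton
convention a = 0 (a lone point in its own cluster scores 1 when another
cluster exists at positive distance). Paratope metrics pool residues
across sequences (micro) with an operating threshold of 0.5 for the
thresholded metrics, reported alongside threshold-free AUROC/APR. The
subtype probe is a linear head on [CLS] trained by cross-entropy with
an optional fine-tuned backbone; the paratope head is per-residue
binary with positives up-weighted by the negative:positive ratio, and
fine-tunes the backbone by default since per-token discrimination
benefits from representation adaptation. Loss and evaluation cover
residue positions only.

## Interpretability

Attention scores use the "attention received" direction (column
aggregation over non-pad queries), since contact residues are attended
*to*; aggregation is mean over layers and mean or max over heads, and
"low-attention" is simply the complement of the top set. Enrichment
ranks pooled residue scores and takes the top ⌈frac·N⌉.

Integrated gradients use a midpoint Riemann sum along the straight line
from a zero baseline, in the space of the **embedding layer's output**
(token + position sum followed by the embedding layer norm); the zero
vector there removes both token and position contributions. This space
matters numerically: attributing the pre-norm sum against a zero
baseline breaks the completeness axiom at any practical step count,
because layer norm is scale-invariant away from its epsilon and all
function variation collapses into a thin boundary layer near the
baseline. In the output space, 200 steps reach a completeness gap below
1% of f(input) − f(baseline) on trained desk-scale models (the gap is
reported in every profile's metadata for auditing). Per-dimension
attributions are summed per token position; profiles report residue
positions. The top decile keeps scores at or above the 90th percentile,
ties included, never fewer than ⌈0.1·n⌉ positions.

Saturation mutagenesis substitutes each selected position with all 19
alternative amino acids (never the original), measures the change in
the originally predicted subtype's probability, and compares the top
attributed positions against an equal number of random non-top residue
positions. The fold statistic is the ratio of decrease frequencies at
Δ < −ε with ε = 0.01; a zero-decrease control group is reported as
infinite with a flag rather than raising. The planted-motif recovery
check uses a one-sided permutation test (random position subsets of
matched size as the null).

## Problem sizes

Library-level checks run on tiny encoders (2 layers, 2 heads, hidden
32) over repertoires of a few hundred sequences with HCDR3-mode
encodings of length ≤ 32; pretraining runs are 200–500 steps at batch
24. The efficacy comparison trains matched w_cl = 0.5 and w_cl = 0
models for 500 steps on three-seed replicates of a 450-record,
three-subtype planted-motif repertoire with SHM and isotype
distributions deliberately equalized across subtypes, so the only
phenotype signal is the sequence motif; it reports median ARI and
silhouette of held-out [CLS] embeddings and the held-out accuracy of a
linear probe. The identity-guarantee check runs the full curation
pipeline on 500 sequences with 40 planted 96–100%-identity duplicates.
The 86 M-parameter preset is instantiated for counting only, never
trained at desk scale.

## Known limitations

The encoder runs on CPU numpy; full-scale pretraining (millions of
sequences, hundreds of thousands of steps) is out of reach by design,
so published-scale benchmark numbers are not reproduced — the package
validates mechanisms, constants and ordering relations instead.
Sequences are treated as independent (no clonal lineage context), the
simulator's SHM is uniform rather than hotspot-targeted, and identical
sequences from different subtypes are inherently ambiguous to any
sequence-only model. Checkpoint resume mid-schedule is not implemented;
re-running a stage re-executes it from its inputs.
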