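# Methods

## Problem and model

The package treats splice-site annotation as dense sequence-to-sequence
classification: every nucleotide of a gene's sense-strand pre-mRNA is
assigned a probability of being a splice donor (the exon→intron
boundary, canonically `GT` at the intron start), a splice acceptor (the
intron→exon boundary, canonically `AG` at the intron end), or neither.

The classifier is a dilated residual CNN.  For a configuration with
kernel-size vector `W` and dilation vector `AR` (one entry per residual
unit, two dilated convolutions per unit), the receptive-field half-width
equals `Σ ARᵢ(Wᵢ−1)`, and the network's terminal crop

    CL = 2 Σ ARᵢ (Wᵢ − 1)

removes exactly that much context from the two ends of the output.  The
four standard configurations are chosen so CL equals the flanking size
(80 / 400 / 2000 / 10,000 nt).  Because convolutions use same-length
zero padding and the crop equals the receptive field, scoring a long
sequence in overlapping windows (each window = 5000-nt core plus
flank/2 of real context per side) reproduces the whole-sequence scores
exactly; the chunk-equivalence test asserts this to 1e-4 and it holds to
float32 round-off.

### Inside a residual unit

The unit is pre-activation: BatchNorm → LeakyReLU(0.1) → Conv, twice,
plus the identity shortcut.  Batch normalization uses ε = 1e-5 and
momentum 0.1; inference always uses running statistics, which is what
makes window-based and whole-sequence prediction agree.  Weights are
Kaiming fan-in initialized from a seeded generator, so a (config, seed)
pair reproduces a model bit-for-bit.

### Channel width

The feature width is not fixed by the architecture family; the default
here is 32 channels, small enough that the flank-80 model trains in
minutes on one CPU core while leaving the width configurable for larger
studies.

## Numerical core

The network, manual backpropagation, AdamW (decoupled weight decay
0.01, betas 0.9/0.999), and both loss functions are implemented in
NumPy; convolutions are evaluated as per-tap BLAS matmuls.  Gradients
are verified against central finite differences in the test suite; the
check tolerates isolated failures at LeakyReLU kink crossings, where the
loss is genuinely non-differentiable.

## Labels, losses, schedules

Label channels are (none, acceptor, donor); the all-zero row marks
padding.  The label-position convention — donor on the last exonic base
before the intron, acceptor on the first exonic base after it — is held
in one constant (`dataset.DONOR_ON_LAST_EXONIC_BASE`) and used
consistently by labeling, evaluation, BED output and ISM.

Both losses mask padding rows and reduce by the mean over non-padding
positions.  Cross-entropy is `−Σ I_c log P_c`; focal loss multiplies by
`(1 − P_t)^γ` (default γ = 2) and coincides with cross-entropy at γ = 0.
Both are implemented in their standard non-negative (negative
log-likelihood) form.

Two learning-rate schedules are provided: multistep (0.5 decay at every
epoch from the sixth onward — the repeated-decay reading of "a 0.5 decay
from the sixth epoch") and cosine annealing with warm restarts
(T₀ = 5 epochs, η_min = 1e-5).  Training splits segments 90/10 into
train/validation with a seeded permutation, stops early after
`patience = 2` epochs without validation-loss improvement, and restores
the best-validation checkpoint.

Transfer learning reloads a checkpoint and trains either all layer
groups or only the last k; frozen BatchNorm layers also stop updating
their running statistics, so "nothing unfrozen" is an exact no-op.

## Calibration

Class-wise temperature scaling: calibrated probabilities are
`softmax(z / T)` with one temperature per class, fitted by full-batch
Adam (lr 0.01) on validation NLL with the network frozen, temperatures
clamped to [0.05, 5.0], plateau-driven lr reduction (factor 0.1,
patience 2) and early stopping (min-delta 1e-6).  The fitter keeps the
best iterate, so the fitted NLL never exceeds the T = 1 NLL.  ECE uses
30 uniform confidence bins on the predicted-class probability;
reliability curves are per-class one-vs-rest (via scikit-learn's
`calibration_curve`) with normal-approximation 95% intervals
(`SE = sqrt(p(1−p)/n)`, z = 1.96).  Note that per-class temperatures
can in principle permute a sample's argmax; only scalar (equal per
class) scaling provably preserves ranking, and the argmax-preservation
property test covers the scalar case.

## Variant delta scores

For a variant inside an annotated gene, reference and alternate windows
are built from real genomic context (N-fallback only at chromosome
ends), run through the (ensemble-averaged) model on the gene's sense
strand, and compared over the 2·distance+1 positions around the variant
(default distance 50, hence 101 positions): DS(acceptor gain) =
max(a_alt − a_ref), DS(acceptor loss) = max(a_ref − a_alt), and the
donor pair likewise, each clamped at 0; the delta position is the offset
of the maximum, ties broken toward the smallest absolute offset and then
upstream.  Indels are aligned back to reference coordinates by skipping
inserted positions and letting deleted reference positions read the
score at the deletion junction.  Variants outside genes, within one
flank of a chromosome end, or deleting more than 2·distance bases are
skipped with a reason code.  Eligible VCF records gain a `SpliceDelta`
INFO field `DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL`.

## Evaluation and ISM

Top-k accuracy follows the k·n_true-cutoff definition, pooled over all
scored positions of the evaluated set; positions tied with the cutoff
score are included by default (fraction clipped to 1; a stable-sort
truncation mode is available).  Note the *fraction* is not monotone in k
— only the captured-site count is — because the denominator grows with
k.  Threshold metrics are standard one-vs-rest accuracy / precision /
recall / F1 at 0.5, with AUPRC as step-wise average precision (not
trapezoidal, which is optimistic on PR curves); precision is reported as
missing when nothing is predicted positive.

ISM importance at a position is `S_ref − mean(S_A, S_C, S_G, S_T)`,
where the reference base's own substitution scores `S_ref`; negative
importance (mutations that strengthen the site) is preserved.  ISM uses
ensemble-averaged scores and real flanking sequence, never N-padding.
Batch mutagenesis averages raw score drops per (position, base) across
sites for logo rendering.

## Pipeline conventions

* Coordinates: GFF/GTF 1-based inclusive on input, 0-based half-open
  internally, BED 0-based half-open on output.
* Canonical transcript = maximal spliced (exonic) length — a
  transcript's information content is exonic, not genomic span — with
  ties broken by lexicographically smallest transcript ID.
* Canonical-intron filter: terminal dinucleotides GT–AG, GC–AG, AT–AC.
* Pseudogene removal matches feature type or biotype in {pseudogene,
  transcribed_pseudogene, processed_pseudogene}.
* Human chromosome split: train 2,4,6,8,10–22,X,Y; test 1,3,5,7,9.
  Random split shuffles by seed and accumulates chromosomes into the
  training set until it holds ≥ the requested fraction of total length.
* Paralog filter: test genes aligned against training genes with
  minimap2 (`-c -x asm20`, tolerating ~20% divergence); a test gene is
  dropped when identity (residue matches / alignment length) and query
  coverage both exceed their thresholds strictly (default 0.8 each).
  Coverage is measured on the test (query) sequence.  A 15-mer
  containment fallback (`backend="kmer"`) serves when minimap2 is
  unavailable; it reports the containment fraction as both identity and
  coverage so the same dual-threshold rule applies.
* Segmentation: ceil(L/5000) segments per gene, 5000-nt cores with
  5000-nt context per side, N- and padding-label fill beyond the gene;
  HDF5 files concatenate genes in batches of 100.
* Prediction windows: 5000-nt cores with flank/2 context per side;
  first/last windows N-padded; sequences beyond the split threshold
  (default 1.5 Mb) are chunked with flank/2 overlap purely for memory —
  chunking never changes scores.  Turbo mode streams BED only; standard
  mode (`--predict-all`) additionally stores per-base tracks in HDF5;
  both produce byte-identical BED.

## The synthetic genome

The generator emulates the *inputs* of a splicing study — multi-exon
protein-coding genes on both strands with canonical GT–AG introns plus
configurable GC–AG, AT–AC and non-canonical fractions, donor sites with
a `[C/A]AG|GT[A/G]AGT`-type consensus, acceptors preceded by a
polypyrimidine tract and `YAG`, uniform exon/intron length ranges, and
near-consensus decoy sites whose recorded single-base fix creates a
cryptic splice site.  Defaults: 10 chromosomes × 200 kb, 8 genes each
(80 genes over 2 Mb), 3–6 exons of 100–250 nt, introns 250–900 nt,
tract length 14, intron classes 92% GT–AG / 3% GC–AG / 2% AT–AC / 3%
non-canonical, background GC 0.42.

Motif strengths (probability that a degenerate consensus position takes
a consensus base) default to 0.995: the generator models strong
constitutive splice sites, under which planted-site identity is nearly
unambiguous given the local motif.  At lower strengths a substantial
fraction of planted sites carries degraded consensus and becomes
indistinguishable from near-consensus background — a property of the
simulation, not of the model under test.

What the generator does *not* emulate: splicing-regulatory grammar
(ESE/ESS elements), alternative isoforms, GC-content heterogeneity,
repeats, and realistic intron length tails.  Passing tests on this
genome therefore demonstrate that the pipeline's mechanics (labeling,
segmentation, training, calibration, scoring, variant algebra) are
correct and that the model class can learn strong local splice signals
— not that trained accuracy transfers to real genomes.

All randomness derives from a single seed through spawned Philox
streams, so identical specs produce byte-identical FASTA/GFF/truth
outputs.

## Study problem sizes

The end-to-end check trains three flank-80, 32-channel models (seeds
10–12) for 10 epochs each with batch size 2 and the cosine schedule on
the 2 Mb default genome and averages their predictions — the
multi-model-per-flank ensemble protocol at reduced count (large studies
use five).  This reaches top-1 ≈ 0.93 (acceptor) / 0.95 (donor) on
held-out chromosomes in a few CPU-minutes; single models land around
0.82–0.92.  Calibration recovery uses N = 10,000 scored positions;
chunk equivalence uses 20 sequences of 1–30 kb.

## Known limitations

* Per-class temperatures may alter argmax decisions; the package
  asserts ranking preservation only for scalar scaling.
* Top-k ties are included with the fraction clipped at 1, which can
  mask a tie-inflated numerator; use `ties="truncate"` for strict
  cutoffs.
* The NumPy training loop is single-device and unsuited to genome-scale
  (10⁸-position) training; the 10,000-flank configuration is exercised
  for construction and arithmetic, not trained in the tests.
* GTF support covers the common gene/transcript/exon attribute layouts;
  exotic dialects may need conversion to GFF3.
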