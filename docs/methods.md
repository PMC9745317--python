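# Methods

This note documents the models, procedures and design decisions behind
`drnaprom`, in the order the pipeline runs them.

## Problem setting

Differential RNA sequencing (dRNA-seq) compares two libraries from the same
sample: one treated with a 5'-monophosphate-dependent terminator exonuclease
(TEX), which degrades processed transcripts and thereby enriches primary
transcripts, and an untreated control. Because primary transcripts start at
transcription start sites (TSSs), TEX(+) coverage shows sharp step-ups at
TSS positions that the TEX(-) control lacks, resolving TSSs at 1 bp. The
DNA directly upstream of a TSS is, by definition, promoter sequence; a
classifier trained on promoter versus non-promoter windows can then score
arbitrary sequence, and rejection sampling through that classifier exposes
the motif features it learned (in cyanobacteria and most other bacteria,
dominated by the AT-rich -10 element, consensus TATAAT).

## TSS calling

Per strand, the coverage-change factor at position *i* is

    delta_i = (x_{i+1} + c) / (x_i + c)

with x the per-base TEX(+) depth and c = 0.01 a calibration constant that
keeps the ratio finite at zero coverage. On the minus strand the scan runs
toward decreasing coordinates so that "next base" is transcript-downstream.
A position p (the base *after* the jump, i.e. the first transcribed base)
is a candidate TSS when three filters pass:

* change factor at p >= `min_change_factor` (default 3.0),
* TEX(+) depth at p >= `min_tex_plus_depth` (default 10),
* calibrated enrichment (TEX+ + c)/(TEX- + c) at p >= `min_enrichment_ratio`
  (default 2.0).

The enrichment test is defined as a calibrated depth ratio at the candidate
base: it is the simplest statistic that captures "present in TEX(+),
absent in TEX(-)", reuses the same calibration constant, and is monotone in
the quantity of interest. Runs of candidates with successive gaps <=
`cluster_window` (default 5 bp) collapse to the candidate with maximal
change factor, ties breaking toward the transcript's 5'-most position, so
each pile-up yields a single 1-bp call. Replicates are summed before calling
by default (appropriate for paired runs of one library); an `intersect` mode
calls replicates separately and keeps positions reproduced within the
cluster window in all of them. All cutoffs are deliberately exposed:
dRNA-seq library quality varies and stringency is a dataset-level decision.

## Dataset construction

Promoters are the L bases directly upstream of each called TSS (default
L = 50; the window ends at p-1, excluding the TSS base itself — users who
prefer to include it can shift coordinates by one). Minus-strand windows
are reverse complemented. Non-promoters are sampled from between
neighbouring same-strand TSSs whose gap exceeds 2L: within the region from
L bases downstream of the upstream TSS to L bases short of the downstream
promoter window, disjoint L-windows are sampled uniformly without
replacement, and any window touching a promoter window on either strand is
discarded. A fraction (default 10%) of i.i.d. random sequences — counted
against the genomic non-promoter total, and generated at the genome's GC
content so GC alone cannot separate the classes — is added as label noise
against overfitting. The pool is then shuffled, truncated to a 1:1
promoter:non-promoter ratio and split 0.8/0.1/0.1 stratified by label.
Exact duplicate strings are collapsed within a class and dropped from both
classes when shared, so no sequence appears in more than one split.

## Tokenization and classifier

Byte-level BPE trained at a merge length of one nucleotide provably
degenerates to single characters, so the tokenizer is shipped as its closed
form: the fixed vocabulary `<pad> <s> </s> <unk> <mask> A C G T N`, with
`<s>`/`</s>` wrapping each sequence and `<pad>` filling to a fixed length.
A length-L input always occupies exactly L+2 tokens, which is what makes
base-level attribution meaningful.

The classifier is a transformer encoder implemented in numpy with
hand-written backpropagation (float64 throughout; gradients are validated
against central finite differences in the test suite). Architecture:
learned token and position embeddings, pre-LayerNorm blocks of multi-head
self-attention with key padding masks and a ReLU feed-forward, a final
LayerNorm, pooling, and a single-logit head through the sigmoid
S(x) = 1/(1+e^-x). The positive-class probability feeds a binary
cross-entropy loss, -1/N Σ (y_i log p_i + (1-y_i) log(1-p_i)), minimized
with Adam (lr 1e-3, batch 64 by default). Two presets exist: `tiny`
(2 layers x 2 heads, width 64, feed-forward 128) — the tested,
CPU-friendly configuration — and `paper` (12 layers x 12 heads, width 768:
the 144-attention-module BERT-base-scale stack), documented for users with
accelerators but not exercised by the tests. A single-logit sigmoid head
was chosen over a two-way softmax because the task is strictly binary and
the sigmoid formulation makes the probability definition explicit. Pooling
defaults to the `<s>` (first-token) representation, with mean pooling as an
option. Early stopping monitors validation AUROC (or F1) with patience 4
and restores the best checkpoint. Determinism is promised bit-exactly for
single-threaded CPU execution under a fixed seed; dropout noise and batch
order flow from that same seed.

Evaluation reports per-class precision tp/(tp+fp), recall tp/(tp+fn) and
F1 = 2tp/(2tp+fp+fn) (the negative class uses complementary counts), plus
AUROC (the tie-corrected rank statistic) and AUPRC (step-wise average
precision), computed via scikit-learn and checked in the tests against
brute-force pair-enumeration and step-sum oracles.

`scan_region` slides the training-length window over both strands of a
genome at a configurable stride, reverse complementing minus-strand
windows. Scores rank candidate promoter regions; like any local
sequence-only scorer it produces false positives on AT-rich promoter-like
background, so scan output is a screening track, not a call set.

## Monte Carlo motif enrichment

A pseudo-random generator draws i.i.d. fixed-length sequences (default
50 nt, uniform bases; GC-weighting configurable) and keeps those the
trained classifier scores >= 0.99 until 500 are accepted. The accepted set
is summarized as a 4xL position frequency matrix, per-position information
content IC = 2 + Σ_b f_b log2 f_b bits (0 for uniform, 2 for invariant),
and a consensus string (modal base where its frequency >= 0.4, else N).
Reverse enrichment keeps sequences scoring <= 0.01 instead; on a model
driven by a localized motif it accepts near-background sequences and
yields no informative position. A `max_draws` guard (default 10^7) bounds
runtime when the discriminator accepts almost nothing, returning a partial
result with a warning. The draw stream is a pure function of the seed, so
raising the cutoff selects a subset of the lower-cutoff acceptances over
the same draws.

## Interpretability

Interactive attention browsers are replaced by two tabular exports. The
attention export writes the full layers x heads x query x key tensor for
one input (each query row a probability vector) plus a mean-over-heads
summary. The importance track uses in-silico mutagenesis: importance at
position j is the largest drop in promoter probability over the three
alternative bases at j. Mutagenesis was preferred over gradient x input
attribution because it is model-agnostic, exactly deterministic, and
testable without autodiff internals; on planted-motif models the motif
positions dominate the track, the testable core of "the model attends to
the -10 element". Special tokens are not mutable positions.

## Synthetic data generator

The simulator emulates the post-alignment form of a dRNA-seq experiment,
not the reads themselves. A background genome is drawn i.i.d. at a
configurable GC content; `n_tss` TSS positions are placed with a minimum
spacing (default 200 bp, which guarantees qualifying non-promoter
intervals) and an edge margin, strands assigned by coin flip; each TSS
gets the motif consensus (default TATAAT), mutated per base at
`motif_mutation_rate` (default 0.1), written with its start
`motif_offset` = 10 bases upstream, mirrored onto the minus strand where
appropriate.

Coverage uses a read-stacking model. Background read 5' ends are drawn per
base from a gamma-Poisson law and extended by a fixed fragment length
(default 60 nt), giving mean depth `background_depth_mean` (default 20)
and coverage-level variance mean + d·mean² with d = `noise_dispersion`
(default 0.05, typical of deeply sequenced bacterial libraries). Each TSS
emits a bundle of primary-transcript reads starting exactly at the TSS
with geometric lengths of mean `decay_length` (default 100), sized so the
expected step height is background x (`tss_step_multiplier` - 1) (default
multiplier 10); TEX(-) receives the same bundle scaled by
`tex_minus_leakage` (default 0.1 — the paper-scale data gives no
quantitative TEX(-) background shape, so leakage is a free parameter).
Minus-strand reads extend toward decreasing coordinates, fixing the strand
convention the caller must honour.

Read stacking, rather than independent per-base noise, is a deliberate
choice: neighbouring bases share the reads that span them, so upward
coverage jumps occur only where reads start — exactly the dependence
structure real alignments have and the property the change-factor filter
exploits. Independent per-base noise would scatter spurious >= 3-fold
jumps across a 100 kb genome at rates that no cutoff tuning can separate
from true TSSs, which misrepresents the data the method was designed for.
The expected per-base profile (background mean, step height, geometric
decay, NB-like marginal dispersion) is unchanged by this choice.

What the simulator does *not* model: rRNA contamination, read-level
artifacts (adapters, soft-clipping, mapping ambiguity), operon structure,
condition-dependent expression, sigma-factor motif classes beyond the
single planted consensus, and genome topology. Passing tests on simulated
data therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not end-to-end performance on real libraries.

`simulate_labelled_sequences` produces desk-scale classifier data directly:
positives are background with the (mutated) motif planted at the position
it would occupy in a promoter window (start at L - offset from the 5' end),
negatives pure background, classes exactly balanced.

## Problem sizes and numerical choices

The tested configuration uses a 100 kb genome with 200 TSSs for calling, a
2000-sequence planted-motif dataset (1600 train / 400 held out) for the
classifier, and 500 accepted sequences for enrichment; the end-to-end
pipeline test runs a 40 kb genome with 120 TSSs and 8 training epochs.
These sizes were chosen so the full suite runs comfortably on a single CPU
while leaving the statistical margins of every check wide.

Numerical details: BCE probabilities are clipped to [1e-7, 1-1e-7] for
loss reporting (the gradient uses the exact sigmoid-BCE form, which needs
no clipping); attention masking uses an additive -1e9 on padded keys;
LayerNorm epsilon is 1e-5; Adam uses (0.9, 0.999, 1e-8). Coverage values
are accepted as reals so normalized tracks work; whether a track is raw or
normalized is recorded in run manifests, not inferred. Cluster tie-breaks
and the TSS-at-p (base after the jump) convention are fixed as described
so that calls are reproducible to the base.

## Known limitations

* The caller reports a flat list of 1-bp TSSs; it does not classify them
  into primary/secondary/internal/antisense categories or compare
  conditions.
* The classifier is single-strand: the reverse complement of a promoter is
  scored as an unrelated sequence.
* Regional scanning inherits the false-positive behaviour of any local
  sequence-only model on AT-rich genomes.
* The `paper`-scale preset is provided but untested here; training it in
  numpy on a CPU is impractical.
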