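# drnaprom

Promoter discovery from bacterial dRNA-seq, end to end: transcription
start site (TSS) calling from TEX(+)/TEX(−) strand-specific coverage, 
balanced promoter/non-promoter dataset construction, a single-nucleotide
transformer promoter classifier, and Monte Carlo motif enrichment — plus a
synthetic dRNA-seq simulator so the whole pipeline runs and is tested
without any downloads.

**Who it is for.** Researchers working on bacteria (the defaults are tuned
for cyanobacteria-style genomes) who have differential RNA-seq coverage
tracks and want (1) single-base TSS calls, (2) a trained promoter
classifier for their strain, and (3) an interpretable readout of the
sequence features — typically the −10 element, consensus `TATAAT` — that
the classifier relies on.

## The method

**TSS calling.** dRNA-seq enriches primary transcripts with a
5′-monophosphate-dependent exonuclease (TEX), so TSSs appear as sharp
step-ups in TEX(+) coverage absent from the TEX(−) control. Per strand, the
coverage-change factor at position *i* is

    Δxᵢ = (xᵢ₊₁ + c) / (xᵢ + c),   c = 0.01

scanned in transcript orientation. The base after the jump is called a TSS
when Δ ≥ 3, TEX(+) depth ≥ 10, and the calibrated enrichment ratio
(TEX⁺+c)/(TEX⁻+c) ≥ 2 (all cutoffs user-tunable); nearby candidates
collapse to the strongest position.

**Classifier.** Promoters are the 50 bases directly upstream of each TSS;
non-promoters come from wide inter-TSS intervals plus 10% random
sequences, balanced 1:1. Each sequence is tokenized one nucleotide per
token (`<s> … </s>` wrapped) and fed to a transformer encoder with a
single-logit sigmoid head S(x) = 1/(1+e⁻ˣ), trained with binary
cross-entropy, −1/N Σ(yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)), and reported with
per-class precision/recall/F1, AUROC and AUPRC. The encoder is pure numpy
with hand-written backprop (gradient-checked); the tested `tiny` preset is
2 layers × 2 heads, width 64, and a `paper` preset mirrors a 12 × 12
BERT-base-scale stack for accelerator users.

**Motif enrichment.** A Monte Carlo generator draws random 50-mers and
keeps those the classifier scores ≥ 0.99 until 500 are accepted; the
accepted set is summarized as a position frequency matrix, per-position
information content (2 + Σ f log₂ f bits), and a consensus string.
Reverse enrichment (score ≤ 0.01) yields no informative positions when the
model has learned a localized motif. Attention tensors and in-silico
mutagenesis importance tracks provide base-level interpretability as TSV.

See `docs/methods.md` for assumptions, parameter meanings, and the
simulator's generative model.

## Worked example

Simulate a 50 kb genome with 100 planted TSSs, call TSSs, and build a
dataset:

```bash
drnaprom simulate --out demo/sim --seed 42 --genome-length 50000 --n-tss 100
drnaprom call-tss --fasta demo/sim/genome.fasta \
    --tex-plus-fwd  demo/sim/TEX_plus_fwd.bedgraph \
    --tex-plus-rev  demo/sim/TEX_plus_rev.bedgraph \
    --tex-minus-fwd demo/sim/TEX_minus_fwd.bedgraph \
    --tex-minus-rev demo/sim/TEX_minus_rev.bedgraph \
    --out demo/tss.tsv
```

which prints `called 100 TSSs -> demo/tss.tsv`; the table starts

```
replicon  position_1based  strand  depth       change_factor  enrichment_ratio
sim_chr   331              +       207.000000  14.775874      5.047793
sim_chr   588              +       203.000000  4.950256       4.950256
```

— each row one TSS at 1 bp resolution with its TEX(+) depth, coverage-change
factor and TEX(+)/TEX(−) enrichment. Train and interrogate a classifier on
planted-motif sequences (2000 sequences, 10% per-base motif mutation):

```bash
drnaprom simulate-seqs --out demo/seqs.csv --n-per-class 1000 --seed 42
# split demo/seqs.csv into train/val/test however you like, then:
drnaprom train --train demo/seq_train.csv --val demo/seq_val.csv \
    --epochs 12 --seed 42 --out demo/seq_model
drnaprom evaluate --model demo/seq_model --data demo/seq_test.csv \
    --out demo/metrics.json
drnaprom enrich-motif --model demo/seq_model --target 500 --cutoff 0.99 \
    --seed 42 --out demo/motif
```

Output of this run: training reports `val AUROC 0.9933`; evaluation prints
held-out `"auroc": 0.9965` with promoter-class
`"precision": 0.9725, "recall": 0.9636, "f1": 0.9680` — the classifier has
recovered the planted signal almost perfectly. Enrichment prints

```
{
  "n_drawn": 300876,
  "n_accepted": 500,
  "acceptance_rate": 0.0016618141692923331,
  "reached_target": true,
  "consensus": "NNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNNTATAATNNNN"
}
```

i.e. of ~301 k random 50-mers, the 500 scoring ≥ 0.99 are exactly those
carrying `TATAAT` at positions 41–46 — the planted −10 element at its
planted offset, read straight back out of the model.

The whole chain also runs from one YAML config
(`drnaprom run --config pipeline.yaml`), with one manifest (parameters,
seeds, input/output digests) written per stage.

## Using real data

The package starts from per-strand bedGraph coverage (0-based half-open).
A typical upstream recipe: align TEX(+) and TEX(−) reads with a
soft-clipping aligner (e.g. HISAT2), split by strand, and export per-base
depth with `samtools depth` / `bedtools genomecov -bga`; then `call-tss`
as above with one `--tex-*` flag per replicate.

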