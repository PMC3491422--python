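# markdiv

Chromatin-mark-stratified divergence analysis of whole-genome-duplication
(WGD) paralog pairs.

After a WGD every gene is duplicated, and the retained paralog pairs
diverge in coding sequence, expression pattern and regulatory sequence.
`markdiv` asks how a binary, gene-specific chromatin mark — the motivating
case is the repressive histone modification H3K27me3 in *Arabidopsis
thaliana*, where the mark sits on individual genes — stratifies that
divergence.  It is written for computational biologists who have a paralog
pair list, one or more mark target-gene lists, sequence FASTA files and a
normalized expression matrix, and want the full class-contrast analysis
with calibrated nulls; and for anyone who wants the same machinery on
synthetic data.

## What it computes

Pairs are classified by the mark status of their members into

- **both** — both paralogs are mark targets,
- **mixed** — exactly one is,
- **none** — neither is,

where a gene is a target when it appears in at least 2 of 3 independent
surveys (configurable minimum support).  Per class the pipeline reports:

1. **Coding divergence.**  For each pair: global protein alignment
   (BLOSUM62, affine gaps 10.0/0.5, free end gaps), protein-guided
   back-translation to a codon alignment, and the Nei–Gojobori (1986)
   counting estimator.  Synonymous (S) and nonsynonymous (N) sites come
   from per-position mutation fates; differences from equal-weight
   averaging over mutational pathways, excluding those through stop
   codons; distances via Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)p).
   Estimates with dS > 5 or saturated (p ≥ 3/4) are discarded.
2. **Expression divergence.**  Pearson correlation r of the two paralogs'
   profiles; class medians compared by two-sided Kolmogorov–Smirnov tests
   and located against a seeded null of 10,000 randomly combined gene
   pairs.  To control for expression level, pairs are also binned into
   five equal-size classes of joint expression level, and
   ln((1+r)/(1−r)) is regressed on level.
3. **Upstream conservation.**  The shared-motif divergence
   dSM = 1 − (covered_a + covered_b)/(len_a + len_b), where coverage is
   the union of maximal perfect matches of ≥ 18 bp between the two 500-bp
   upstream regions.  A pair is "conserved" when its dSM is below the 5th
   percentile of a 10,000-draw random-pair null; per-class conserved
   fractions are compared with a Yates-corrected two-proportion
   chi-square test, and overlap with external conserved-promoter gene
   sets with an upper-tail hypergeometric test.

A first-class synthetic-data module generates all inputs with planted
class structure (mark-dataset overlap, class-dependent expression
correlation and level, codon pairs evolved to target dN/dS, planted
shared promoter motifs) plus a ground-truth table, so the entire pipeline
runs — and is tested — without any downloads.

## Worked example

```bash
markdiv simulate --out demo_data --seed 17
markdiv run --config run.yaml --out demo_out --seed 17
```

or, from Python (this is `examples/05_full_pipeline.py`; the other
examples walk through each stage on its own):

```text
class sizes: {'both': 280, 'mixed': 309, 'none': 311}
median expression r by class: {'both': 0.61, 'mixed': 0.2, 'none': 0.46}
random-null median r: -0.0
median dN by class: {'both': 0.206, 'mixed': 0.224, 'none': 0.145}
conserved upstream fraction by class: {'both': 0.45, 'mixed': 0.23, 'none': 0.23}
```

Reading the numbers: pairs that kept the mark on both copies remain the
most co-expressed (median r 0.61) and have the most conserved upstream
regions (45%), pairs with a single marked copy diverge the most in both
respects (r 0.2, approaching the random-null 0.0), and the unmarked class
evolves slowest in protein sequence (lowest median dN).  The 280/309/311
class sizes differ from the planted 300/300/300 because each survey drops
10% of true targets, so some pairs are classified from incomplete
evidence — exactly the degradation the 2-of-3 integration is there to
absorb.

`run.yaml` lists the input paths and any parameter overrides; see
`markdiv run --help` and `markdiv/pipeline.py:RunConfig` for the full set.
Each run writes per-stage TSVs, `report.json` and a human-readable
`report.md` into the output directory.

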