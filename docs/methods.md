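# Methods

This note records the models, conventions and parameter choices behind
`markdiv`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Mark integration and pair classification

Mark presence is modeled as a binary gene property: genome-wide surveys of
a gene-specific chromatin mark (the motivating case is H3K27me3 in
*A. thaliana* seedlings) disagree at the margins, so a gene is called a
target when it appears in at least `min_support` of the supplied surveys
(default 2 of 3).  Genes absent from every survey are non-targets with
support 0.  Pair classes follow directly: *both*, *mixed*, *none* by the
number of target members.  Classification is symmetric in the pair, and
the three classes partition any classified pair set.

Gene identifiers are opaque case-sensitive strings; an off-by-default
normalization helper (uppercasing, `.N` version-suffix stripping) exists
for sloppier inputs because AGI locus codes themselves are stable.
Duplicate pairs (order-insensitive) in an input pair list are an error:
each pair is analyzed once, keyed by the sorted id tuple.  Empty surveys
are permitted (they simply contribute no calls); this deliberately relaxes
a strict non-emptiness rule so that degenerate simulation settings (full
dropout) remain representable.

## Coding divergence

The estimator is the Nei–Gojobori (1986) counting method on a
protein-guided codon alignment:

1. **Protein alignment** — global, affine gaps, via Biopython's
   `PairwiseAligner`.  Scoring contract: BLOSUM62; an internal gap of
   length L costs `gap_open + (L−1)·gap_extend` with defaults 10.0 and
   0.5; terminal gaps are free (semi-global, `needle`-style behaviour).
   The gap-length bookkeeping (whether the opening residue also pays the
   extension) differs between aligners; the contract above is this
   package's definition, is configurable, and is what the test-suite DP
   oracle checks.  Among co-optimal alignments the aligner's first
   traceback is reported; the score — the only quantity the downstream
   counting depends on — is tie-invariant.
2. **Back-translation** — each aligned residue expands to its source
   codon, gaps to `---`; a terminal stop codon is trimmed; every codon is
   checked to translate to its aligned residue (X accepts any codon).
   Mismatches raise with the offending gene id rather than silently
   misaligning the reading frame.
3. **NG86 counting** — per sense codon, each position contributes exactly
   one site, split into synonymous/nonsynonymous by the fraction of
   synonymous changes among the possible single-nucleotide changes *not
   creating a stop codon* (stop mutations are excluded from the
   denominator).  Codons with gaps, ambiguity codes or stops in either row
   are dropped pairwise, so N + S = 3 × (compared codons) exactly.
   Multi-difference codons are averaged over all orderings of single
   steps with equal weights, excluding orderings whose intermediates are
   stop codons; if every ordering is blocked (impossible for one or two
   differences between sense codons under the standard code) all
   orderings are used.  Distances are Jukes–Cantor corrected; p ≥ 3/4 is
   flagged `undefined_saturation` rather than raised.
4. **Filtering** — estimates with dS above `ks_max` (default 5.0) are
   discarded as unreliable; saturated/undefined estimates are discarded
   with their own reason code.  Counting methods cannot produce negative
   dS, so the "invalid estimate" discard class here covers saturation;
   reason codes are preserved for audit.

Known convention note: Biopython's experimental `codonalign` NG86 both
averages pathways *through* stop codons and scores mutations-to-stop as
nonsynonymous sites.  This package follows the stop-excluding convention
in both places; the cross-check test against Biopython is therefore
restricted to inputs where the conventions provably coincide, and the
multi-difference convention is covered by an enumeration oracle instead.

The genetic code is the standard nuclear table by default and
configurable by NCBI table id.

## Expression divergence

Intensities are assumed already normalized (e.g. RMA-style output on a
log-like scale); the pipeline performs no re-transformation, and joint
expression levels are plain sums over samples of both profiles, matching
how such levels are reported for paralog data.  Pearson r is computed
across samples; zero-variance profiles are flagged undefined and excluded
from distributions, with the exclusion counted in the report.

The random-pair null draws two distinct genes uniformly per draw, with
replacement across draws (the same pair may recur; over thousands of
genes the distinction from without-replacement sampling is negligible,
but the rule is fixed for reproducibility).  Random pairs may coincide
with true paralog pairs — the probability is negligible and no exclusion
is attempted.  Nulls are seeded and bit-reproducible.

Class distributions are summarized by medians (midpoint convention for
even n) and compared pairwise with the two-sided two-sample
Kolmogorov–Smirnov test.  The p-value is the classical asymptotic
Kolmogorov survival function evaluated at √(n₁n₂/(n₁+n₂))·D, clamped into
(0, 1]; SciPy's small-sample "asymp" variant can return exactly 0 at
D = 1, which would violate the p ∈ (0, 1] contract.  The asymptotic
approximation is only trustworthy for moderately large samples — the test
suite's permutation comparison is run at n = 200 for this reason.  KS
p-values are reported raw, without multiple-testing correction, and the
report says so implicitly by listing every comparison.

Level stratification assigns pairs to `n_quantiles` (default 5) equal-size
(±1) bins by rank of joint level, ties broken by stable input order.  The
level–correlation relation is assessed by OLS of ln((1+r)/(1−r)) on joint
level; the transform is deliberately the printed form without the
conventional ½ factor, matching how such regressions are reported for
paralog expression data (it is monotone, so slope signs are unaffected).
|r| = 1 maps to ±∞ and is excluded from the regression.

An optional measurability mask (one gene id per line) stands in for
platform probe coverage: pairs with an unmeasurable member are dropped and
per-class retention percentages are reported as integers.

## Upstream conservation

Shared motifs are maximal perfect matches of ≥ `min_match_length`
(default 18) nucleotides between two upstream regions (default 500 bp),
forward strand only — upstream regions are extracted strand-oriented, so
reverse-complement matching is off by default.  `N` never matches.  The
finder seeds with an exact k-mer index and extends along diagonals, which
is exhaustive (any match of length ≥ l contains an l-mer seed) and is
checked against an all-substrings oracle.

The divergence score is defined by coverage:

    dSM = 1 − (covered_a + covered_b) / (len_a + len_b)

where `covered_x` is the union of positions of x inside any shared motif.
This reproduces the score's defining endpoints — 0 for identical
sequences, 1 for no shared stretch of the minimum length — and is
symmetric and bounded by construction.  Between the endpoints the coverage
definition is this package's own; shared-motif divergence scores produced
by other tools are not numerically interchangeable with it.

The conservation cutoff is the nearest-rank 5th percentile (configurable)
of a seeded random-pair dSM null; "conserved" means strictly below the
cutoff.  For unrelated ~500-bp sequences the chance of any shared 18-mer
is ≈ 483²·4⁻¹⁸ ≈ 3·10⁻⁶ per pair, so on synthetic data the null is
essentially all 1.0 and the cutoff lands at 1.0 — real promoter sets,
with repeats and compositional bias, give informative cutoffs below 1.
The null evaluation short-circuits pairs without any shared k-mer via
cached integer k-mer fingerprints, which keeps 10,000 draws cheap.

Per-class conserved fractions are compared with the pooled two-proportion
chi-square test with Yates continuity correction (identical to R's
`prop.test`, and to the closed form; degenerate tables return statistic 0,
p = 1).  Enrichment of an external gene set among conserved pairs uses the
upper-tail hypergeometric probability P(X ≥ k).  An id-substring exclusion
option exists for reference lists that mix identifier conventions.

`calibrate_parameters` reproduces the calibration logic for the match
length and promoter length: for each candidate pair it counts pairs with
any shared motif among true pairs (signal) versus random pairs
(false-positive proxy) and tabulates the ratio — short minimum lengths
flood the random pairs with hits, which is why 18 bp is the default.
Shorter promoters are truncated to their 3'-most (TSS-proximal) bases.

## Synthetic data

The generator emits every input the pipeline reads, plus a ground-truth
table, all derived from one master seed (per-stage generators are derived
from (seed, stage-label) so stages are independently reproducible).

- **Mark datasets.**  True targets are implied by class (both members of
  *both* pairs, one member of *mixed* pairs, none of *none* pairs) plus a
  20% background-gene fraction, in line with a genome where roughly a
  fifth of genes carry the mark.  Each dataset independently drops each
  true target with probability `dataset_dropout` (default 0.1, under
  which a true target survives 2-of-3 integration with probability
  P(Bin(3, 0.9) ≥ 2) = 0.972).  No false positives are planted; the
  dropout alone already produces realistic class contamination.
- **Expression.**  Pair profiles are bivariate normal across samples:
  common per-pair level drawn around the class level mean (defaults
  place *none* highest at 7.5 and *both* lowest at 6.0 on a log-like
  scale, *mixed* between at 6.3, reflecting the repressive mark), unit
  noise, class correlation ρ (defaults 0.6 / 0.2 / 0.45 for
  both / mixed / none, preserving the observed both > none > mixed
  ordering with realistic spacing).  An optional `level_rho_slope`
  couples correlation to level for testing the level-confound control.
  Deliberate simplifications: no heteroscedastic array noise, no
  tissue structure, no probe effects — so passing tests demonstrate the
  statistical machinery, not robustness to microarray artifacts.
- **Coding sequences.**  Each pair descends from a random sense-codon
  ancestor (ATG-initiated, default 200 codons).  Divergence targets
  (defaults dN 0.20 / 0.22 / 0.14 and dS 0.8 / 0.7 / 0.6 for
  both / mixed / none, the observed ordering) are planted as
  Poisson-distributed observed difference counts with mean p·sites,
  p = (3/4)(1 − e^(−4d/3)) (inverse Jukes–Cantor), at distinct
  nucleotide positions split between the two branches; each change is
  classified against the branch's current codon and never creates a
  stop.  Distinct positions keep observed counts equal to planted ones,
  making the NG86+JC estimate unbiased for the target at these
  divergences, while Poisson counts retain honest sampling noise — the
  recovery tests exploit exactly this.  Substitutions are
  base-uniform (no transition/transversion bias); bias is a config
  extension point, not needed for counting-estimator recovery.
- **Upstream regions.**  I.i.d. random sequences; with class probability
  (defaults 0.40 / 0.20 / 0.25 for both / mixed / none) a shared block of
  `motif_length` (default 25 > 18) is copied between the two members at
  independent offsets.  A planted block slightly shorter than the match
  threshold can still be detected through chance extension into matching
  flanks (probability 1 − (3/4)² ≈ 0.44 for one base short), which is a
  property of exact-match scanning, not a bug.

Desk-scale defaults (300 pairs/class, 4,000 background genes, 100
samples) keep a full generate-and-analyze cycle around a second.

## Problem sizes in the recovery tests

The full-pipeline ordering test runs 20 seeded simulate+analyze cycles at
1,500 pairs/class.  The size is a power choice: the narrowest planted
contrast is the none-vs-mixed conserved-fraction gap (0.25 vs 0.20), and
after accounting for 2-of-3 classification contamination at dropout 0.1
the per-run probability of resolving the strict ordering reaches ~99%
only around n ≈ 1,500; the dN/dS recovery test uses 200 replicates of
300-codon pairs, which puts three standard errors of the replicate mean
near ±0.005 on dS.  The dN/dS recovery targets (dS 0.2, dN 0.1) sit in
the low-divergence regime where the planting scheme is unbiased.

## Pipeline mechanics

Stage seeds derive from `(master_seed, stage_label)` via CRC-mixed
`SeedSequence` spawning, so runs are value-identical under a fixed seed
and stages can be re-run in isolation.  Each stage writes its outputs and
a JSON summary; `resume=True` reuses an existing stage summary instead of
recomputing (no content hashing — deterministic seeding makes stale-cache
bugs visible as value changes).  Exclusion counts (missing sequences,
undefined correlations, discarded estimates, missing regions) reconcile
against the input pair count in the report, and the report renderer
rounds fractions to integer percentages only at presentation time.

## Known limitations

- The dSM formula between its endpoints is this package's coverage-based
  definition; scores from other shared-motif tools are not numerically
  interchangeable.
- The asymptotic KS p-value is inaccurate below a few dozen observations
  per sample; D itself is always exact.
- The codon-evolution planting scheme targets the counting estimator's
  expectations; it is not a substitute for a full phylogenetic simulator
  (no rate heterogeneity, no ts/tv bias, no indels).
- Expression profiles are Gaussian; heavy-tailed intensity distributions
  and platform-specific noise are out of scope, so real-data behaviour of
  the correlation statistics should be validated on real matrices.
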