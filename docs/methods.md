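# Methods

## Scope and data model

cubkit analyses synonymous codon usage in sets of in-frame coding
sequences, one set per species, against a shared backbone of conserved
single-copy genes (an ortholog design). All statistics are defined on the
61 sense codons of the standard nuclear genetic code; codons and all
vectors/matrices are ordered alphabetically (`AAA` … `TTT`). RNA-style
input (U, lowercase) is normalised at parse time. Alternative genetic
codes and ambiguity-code expansion are out of scope; codons containing
non-ACGT characters are skipped at counting time with a tally.

### Counting conventions

* A CDS is valid iff its length is a multiple of three, it contains no
  internal stop codon and at least one sense codon. A terminal stop codon
  is tolerated but never counted: RSCU, ENC and CAI are defined on sense
  codons only, so statistics are computed over the CDS interior.
* Species-level statistics are computed from the **pooled** codon count
  table (summing counts over all of the species' sequences), never by
  averaging per-gene values.
* The ORF length filter is strict (`length_codons > 100`), as is the
  species quality rule: a species passes iff it recovers ≥ 25% of the
  conserved backbone *and* its recovered sequences average > 500 nt.
* GC1/GC2/GC3 are count-weighted G+C fractions over all sense codons,
  including ATG and TGG (the EMBOSS `cusp` convention); GC3 is therefore
  not restricted to degenerate sites, which matters when comparing against
  tools that exclude them.

## Bias metrics

### ENC

For each degenerate amino acid, codon homozygosity is estimated as
`F̂ = (nΣp² − 1)/(n − 1)` (counts mode, small-sample corrected; requires
n ≥ 2 and F̂ > 0) or as the raw `Σp²` (frequencies mode). Class averages
over the 9 two-fold, 1 three-fold, 5 four-fold and 3 six-fold amino acids
compose `ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`.

* Uniform usage gives exactly 61; one codon per amino acid evaluates to
  20 (2 + 9 + 1 + 5 + 3). Survey literature sometimes quotes 21 for this
  lower bound; we report what the composition evaluates to.
* Missing-class policy: if the three-fold class (Ile) has no usable amino
  acid but classes 2 and 4 do, `F̄₃` is imputed as their mean (Wright's
  remedy). Any other missing class drops its term and the composition is
  rescaled by `20 / n_amino_acids_represented`; this only arises on very
  small tables.
* The counts-mode estimator can exceed 61 on near-uniform data, so results
  are capped into [1, 61]. Per-gene and pooled species ENC both use counts
  mode by default; frequencies mode is available as a dialect switch.

### sENC-x

Per degenerate amino acid, the effective codon number `ENC_x = 1/F`
(clipped into [1, k]) is rescaled to `sENC-x = (k − ENC_x)/(k − 1)`:
0 = uniform usage, 1 = a single codon, comparable across degeneracy
classes. The defining rescaling is fixed here explicitly because survey
usage of the quantity states only the [0, 1] range and the direction
(higher = more biased); with this convention the most biased amino acids
(e.g. Arg) take the largest values.

### CAI and TPM

Expression is quantified as TPM (`10⁶ · (c/l) / Σ(c/l)` per library); the
reference set is the 50 conserved genes with the highest unweighted mean
TPM across the provided libraries (ties broken lexicographically by gene
id). Relative adaptiveness is `w = RSCU / max RSCU` within each family on
the pooled reference counts, with a 0.5 pseudocount for zero-count codons
so no weight is 0; amino acids entirely absent from the reference get
weights 1 with a warning. CAI is the geometric mean of `w` over a gene's
codons excluding ATG, TGG and stops. In multi-species runs each species
derives weights from its own orthologs of the reference genes.

## Comparative analyses

* The clustering matrix holds per-species RSCU for the 59 informative
  codons (sense minus ATG and TGG). RSCU of an absent amino acid is
  *undefined*, not 0; such cells are imputed with the codon's column mean
  and masked, and a species missing > 20% of columns is excluded with a
  warning.
* Clustering is agglomerative with Euclidean distance; the default linkage
  is **complete**, with **average** available as a configuration switch —
  the underlying survey methodology is described both ways in different
  places, so the choice is surfaced rather than silently resolved. scipy's
  agglomeration is deterministic for a fixed row order (ties broken by
  lowest pair index). Trees export to Newick; merge heights are cluster
  distances, so tips sit at half the final height in the ultrametric tree.
* Regressions are simple OLS with Pearson r; the reported p-value is the
  regression F-test p, which for one predictor equals the slope t-test p.
  Significance flags use α = 0.05 (the conventional choice; the source
  analyses mark "NS" without stating a threshold). "Overall CUB" is
  implemented literally as −ENC, so a positive per-codon correlation means
  "more frequent in more biased species"; codon frequency there is the
  fraction of all sense codons, not the within-family share (which RSCU
  already captures).
* Gene-level selection signatures correlate −ENC and GC3 against protein
  length and against per-library expression. Expression enters as
  log10(TPM + 1): TPM is log-normally distributed over genes and the raw
  scale would let a handful of extreme transcripts dominate the Pearson
  statistic.

## Synthetic cohorts

The generator emulates the features of the real study design the pipeline
consumes — a conserved-gene backbone shared across species, per-species
CDS FASTA, ortholog inventory with optional dropout, and three-library
RNA-seq-style counts — under a minimal generative model:

* Amino acids i.i.d. from a fixed composition (Swiss-Prot-style averages);
  within each family, codon c of gene g is drawn with weight
  `exp(b_g · m(c))` where `m(c)` indicates a G/C third position. The third
  position is the **only** bias feature, matching the analyses' exclusive
  focus on A/T- vs G/C-ending codons.
* `b_g = β + s·dir_s·z_expr + a·dir_a·z_len`, with z-scores of
  log-expression and log-length standardised within species so the
  selection coefficients s (translational speed) and a (translational
  accuracy) are comparable across parameter sets; dir is +1 toward GC,
  −1 toward AT. β is calibrated by Brent root finding so the no-selection
  expected GC3 equals `gc3_target` exactly (realised cohort GC3 lands
  within ~±0.01 at 2000 genes).
* Defaults describe the exercised study conditions: 2,000 genes per
  species (desk-scale stand-in for a ~2,800-gene backbone), log-normal
  lengths with mean 280 codons (mean recovered length well above the
  500 nt quality bar, floored at 102 codons so the ORF filter keeps
  everything by construction), log-normal expression with SD 1 on the
  log10-TPM scale, 0.25 SD log-normal library noise and Poisson read
  counts at 10⁶ reads per library.
* All randomness flows from one cohort seed; species i uses
  `default_rng([seed, i])`. Same seed ⇒ byte-identical FASTA.

What the generator does **not** emulate: phylogenetic correlation among
species, substitution processes, amino-acid composition differences,
assembly fragmentation or annotation error. Passing the recovery tests
therefore shows the estimators detect the dialled-in forces under clean
conditions, not that real transcriptomes are free of confounders.

## Null behaviour of the estimators

Two gene-level correlations are *not* null even when no bias and no
selection are simulated, and are deliberately excluded from the
null-control check (while still being computed and reported):

* **ENC vs gene length.** Per-gene ENC is an estimator whose sampling
  noise shrinks with gene length; at the uniform-usage boundary the
  [1, 61] cap truncates that noise asymmetrically, so shorter genes
  average lower capped ENC (observed r ≈ +0.2 between ENC and length at
  GC3 = 0.5 with zero selection).
* **ENC vs GC3.** Both are functions of the same codon counts; a gene
  whose GC3 fluctuates away from 0.5 necessarily concentrates its usage,
  lowering ENC (observed r ≈ −0.56 for −ENC vs GC3 with zero selection).

The generatively null analyses — codon usage and GC3 against expression,
and GC3 against length — behave as nulls: ~5% false-positive rate at
α = 0.05 across seeded replicates.

## Numerical conventions

* TSV outputs use 6-significant-digit formatting; reruns with the same
  config and inputs are byte-identical.
* Degenerate regressions (n < 3 or zero variance) raise, or are flagged
  NS with NaN statistics where a table of many regressions is produced.
* Reference-set tie-breaking, clustering tie-breaking and codon ordering
  are all fixed and documented so outputs are reproducible bit-for-bit.

## Known limitations

* CAI values depend mildly on the pseudocount policy; third-decimal
  agreement with other CAI implementations is not guaranteed.
* The missing-class ENC rescaling rule is a pragmatic convention for tiny
  tables; alternative conventions exist.
* sENC-x uses the same homozygosity mode as ENC (counts by default);
  counts-mode values are clipped into [0, 1] because the corrected
  estimator can overshoot the uniform-usage bound on small families.
* tRNA adaptation (tAI), codon-pair bias and effective-population-size
  modelling are out of scope.
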