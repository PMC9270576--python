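# Methods

## Scope and model

The package reimplements, as a tested library plus analysis drivers, a
rare-variant discovery workflow for small case-control sequencing
cohorts, together with the downstream analyses such a study typically
runs: protein-region clustering of the hits, guideline-style risk
tiering, and a knockdown/rescue expression classification. Upstream
read processing (alignment, calling, VQSR) and the annotation engines
themselves (CADD, SIFT, PolyPhen2, population databases) are out of
scope: annotations are inputs.

### Qualifying variants

A genotype call passes QC iff depth ≥ 20, alternate-allele fraction
≥ 0.30 and genotype quality ≥ 20 (exclusions are phrased strictly below
threshold, so boundary values pass; missing fields fail closed). A
variant is a candidate risk allele iff its consequence is non-silent
(missense, nonsense, splice, frameshift, non-frameshift deletion), its
highest population allele frequency is < 0.1% (absence from every
database counts as rare), and the in-silico evidence is strong: CADD
Phred > 20 (strict, "top 1% deleterious") and not tolerated/benign by
*both* SIFT and PolyPhen2. Two deliberate interpretations, both
switchable in `FilterConfig`:

- the SIFT/PolyPhen2 clause excludes a variant only when **both**
  predictors call it benign (`predictor_rule="either"`, the default);
  the stricter both-must-be-damaging reading is available as
  `predictor_rule="both"`. The permissive reading is the one consistent
  with retaining functionally validated alleles whose two predictors
  disagree.
- predicted loss-of-function consequences (nonsense, frameshift,
  splice) pass the in-silico leg regardless of missing missense
  predictor scores, which are routinely unavailable for truncating
  alleles. A missense variant with missing CADD fails closed.

Every excluded call is attributed to exactly one first-failing rule
(depth → VAF → GQ → consequence → frequency → CADD → predictors) in a
filter log, so the cascade is auditable and conservation (retained +
attributed = all calls) is a tested invariant.

### Carrier collapsing and exact inference

Collapsing is dominant/carrier-based: a sample carries a gene iff it has
≥ 1 qualifying call there; each sample counts once per gene however many
qualifying variants it carries. (An allele-count mode exists behind
`AssocConfig(unit="alleles")`; carrier mode is the default because the
reproducing 2×2 for the motivating study's top gene is carrier-based.)

Conditioned on both margins, the case-carrier count follows Fisher's
noncentral hypergeometric distribution. The package computes the
minimum-likelihood two-sided p (probabilities ≤ observed, relative tie
tolerance 1 + 1e-7; tail-doubling available behind a flag), the
conditional-MLE odds ratio (root of `E_ψ[X] = a`), and the exact CI by
tail inversion at α/2 per side. Boundary counts map to estimate 0 /
CI-low 0 (support minimum) and ∞ (support maximum). All tail sums are
log-space over the exact support; nothing is approximated normally.

Root finding comes in two modes. The default bisects on log ψ to a
relative tolerance of 1e-8 inside a bracket derived from the log-weight
span (the tail functions transition on that scale, so the bracket
provably contains the root); the kernel is numba-compiled because the
test suite inverts tails for every 2×2 table with N ≤ 60 (~6·10⁵
tables). The `r-compat` mode instead mirrors R `fisher.test`: Brent
iteration on the odds scale below 1 and on the reciprocal scale above 1,
stopping at `uniroot`'s default tolerance (eps^0.25). The two modes
agree to ~0.1%; `r-compat` exists because printed literature values
carry that solver's trailing digits (e.g. an upper CI bound printed as
1231.61 where the converged root is 1241.21), and reproducing published
tables digit-for-digit is part of this package's purpose.

FDR control is Benjamini–Hochberg (via statsmodels) over exactly the
genes entering the scan — every gene with ≥ 1 qualifying case variant.
The nominal significance call is `p < 0.005`; the FDR-level annotation
is additionally gated on ≥ 3 qualifying case variants, mirroring the
multi-variant condition such scans state for FDR claims. Ranking is
total (p, then OR descending, then gene name) so output is reproducible.

### Region clustering

The N-/C-terminal clustering test forms a 2×2 of variant counts versus
non-variant residue counts per region (variants in region 1, residues
minus variants in region 1; same for region 2) and hands it to the same
exact machinery. Recurrent variants at one residue each count once per
variant — no position deduplication, which is the construction that
reproduces the motivating study's printed counts (16 + 6 = all missense
variants). Note the residues of one protein are not independent trials,
so the p-value is descriptive rather than strictly frequentist; the
printed convention is followed deliberately.

### Risk tiers

Because full guideline-grade evidence (segregation, de novo status, the
original study's supplementary rule table) is unavailable, tiering is a
small monotone rule framework over five boolean evidence flags, with the
rule table as validated config data: established risk requires
functional evidence plus either a truncating consequence or a novel,
damaging, recurrent allele; likely risk requires any two of the four
primary evidence lines; everything else is uncertain. Monotonicity
(adding evidence never demotes) and partition are tested over all 32
profiles. This module is a framework for reproducible tiering, not a
claim to replicate any curation panel's per-variant judgments.

### Expression grid

With one library per condition (CON/KD/RE), counts are normalised to
counts-per-million (per-column totals unless overridden), a pseudocount
of 1 is added, and each gene gets log2(KD/CON) and log2(KD/RE).
Thresholding both axes at ±1.5 partitions genes into a 3×3 grid labelled
A..I (row-major, y = KD/RE from high to low, x = KD/CON from low to
high); G (down on both) is the DOWN group, C (up on both) the UP group.
Values exactly at ±1.5 belong to the outer bins, so the cutoff lines are
selected. CPM-with-pseudocount was chosen because the emulated design
has no replicates, ruling out dispersion-based testing; the external
"CORE" validated-gene list is an input, not re-derived, since its
selection was annotation-driven.

## Synthetic data

`simulate_cohort` draws, per gene and sample, independent Bernoulli
carrier status — separate case/control probabilities for planted genes
(defaults 4/37 and 1/208, the motivating discovery design), one
background probability elsewhere — and gives each carrier exactly one
heterozygous qualifying variant in the gene (dominant model). Annotation
fields of the other variants are drawn from mixtures straddling every
filter threshold, with a configurable fraction placed exactly on the
boundaries (AF = 0.001, CADD = 20); depths are 30 + Poisson(40),
alt-allele counts Binomial(depth, 0.5), GQ uniform 40–99, and a
configured fraction of calls is seeded with one failing DP/VAF/GQ
field. The ground-truth sidecar records the *realized post-QC* carrier
counts (the simulator recounts after seeding failures), so downstream
filter output can be compared to truth exactly rather than
probabilistically.

The background per-gene, per-sample qualifying-carrier probability
defaults to 0.007, calibrated once from the emulated study's own
headline count: ~4k of ~18k genes showing ≥ 1 qualifying case variant
among 37 cases implies `1 − (1 − q)³⁷ ≈ 0.22`, i.e. q ≈ 0.007.

`simulate_rescue_counts` draws log-normal baseline abundances
(log-mean log 100, log-sd 1), shifts planted genes' KD means by
∓effect (default log2 effect 3, 50 down and 50 up genes of 2000), keeps
CON and RE at baseline (the rescue restores expression by construction),
and samples negative-binomial counts (variance m + d·m², default
dispersion d = 0.1, library size 10⁷). Dispersion 0 means deterministic
rounded means — the noiseless limit used by threshold-correctness tests.

What the generators do *not* emulate — linkage disequilibrium,
population structure, batch effects, annotation errors correlated with
frequency, replicate structure in expression — bounds what green tests
show: they validate the statistical machinery and its calibration under
the stated model, not robustness to real-data confounding.

## Numerical choices

- Hypergeometric log-weights via `gammaln`; tails by stable
  shifted-exponential sums; minimum-likelihood p via sorted cumulative
  sums shared between the scalar and batch paths.
- CI/MLE bisection: bracket ±(log-weight span + 40) on log ψ, absolute
  tolerance 1e-10 on log ψ (≈ 1e-10 relative on ψ); MLE bracket grows
  geometrically (factor 4) from the sample OR.
- Ties in ranking broken totally; q-values capped at 1; percentages
  rounded half-up to integers.
- Float INFO fields are normalised to six significant digits on VCF
  read (the precision of VCF's 32-bit floats) and the simulator emits
  six-significant-digit annotation values, making VCF round trips
  lossless; TSV reads use pandas' round-trip float parser.
- Degenerate inputs: empty carrier margins give p = 1; empty cohorts
  yield empty outputs with warnings rather than errors; multi-allelic
  VCF records are rejected naming the site.

## Problem sizes

The shipped suites use the study-scale designs throughout: 37 vs 208
samples and 500–2000 genes for cohort work, 2000 genes for the
expression grid, 200 replicates for parameter recovery, 10⁴ tables for
CI coverage, and the complete enumeration of 2×2 tables with N ≤ 60
(~6.4·10⁵ tables) for the exact-oracle equivalence check.

## Known limitations

- The conditional MLE is undefined (0 or ∞) whenever an informative
  cell is empty, which is common at these sample sizes; the sample OR
  is reported alongside for transparency.
- Carrier-level simulation cannot produce compound heterozygotes or
  multi-variant carriers within a gene, so `n_qualifying_case_variants`
  equals case-carrier count in simulated data (real data need not).
- The expression classifier is descriptive; without replicates no
  significance statement attaches to group membership.
- With a calibrated 0.007 background, a single planted gene at the
  default effect attains the scan's minimum p in only ~70% of
  replicates — small-cohort rankings are genuinely unstable, and the
  parameter-recovery suite measures (rather than hides) that.
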