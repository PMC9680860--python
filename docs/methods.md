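# Methods

## The inference problem

A focal diploid individual is suspected to descend from a cross between
two species, A and B, followed by zero or more backcrosses to a
recurrent parent (A).  Given resequencing panels of a few individuals
per species and the focal sample, all genotyped against one reference,
the pipeline asks three questions: is the focal a hybrid at all, how
many backcross generations separate it from the F1, and how is the
donor (B) ancestry distributed along its chromosomes?

All three are answered from **diagnostic sites**: biallelic SNPs at
which every panel-A sample is homozygous for one allele and every
panel-B sample homozygous for the other.  At such a site the focal
genotype directly reads out its ancestry dosage.

## Site filtering and diagnostic-site ascertainment

Input VCF records are used as called; the only filters are structural:
exactly one alternate allele, all alleles single nucleotides, and no
missing genotype among the samples participating in a given analysis.
Multiallelic records are excluded outright rather than split, and
genotypes are treated as unphased unordered pairs — no stage uses
phase.

Fixation is judged on genotype calls (every sample homozygous), which
is the natural criterion for panels of ~3 individuals; a frequency
threshold mode (`min_freq`) exists for larger panels but is off by
default.  A focal genotype carrying an allele that is neither
panel-specific allele is tallied in a separate `other` bucket and
excluded from the three-class counts, rather than being forced into
them, since silent misclassification would bias the likelihood stage.

## Backcross-generation likelihood

For a BCgF1 pedigree the probability that a diagnostic site is
heterozygous is 2⁻ᵍ (each backcross halves the chance that the hybrid
parent transmits the donor allele); the homozygous-donor class a/a is
impossible.  Observed a/a calls are therefore modelled by a
contamination parameter `p_error` shared by all models:

    q_AA = (1 − p_error)(1 − 2⁻ᵍ),  q_Aa = (1 − p_error)·2⁻ᵍ,  q_aa = p_error.

g = 0 (a plain F1) makes q_AA = 0, so any observed A/A count drives the
F1 model to −∞; this is retained deliberately (the F1 hypothesis is
falsified by a single confident A/A call under this error model).

The log-likelihood of counts (N_AA, N_Aa, N_aa) is the full multinomial
log-pmf.  Factorial terms use log-gamma, never Stirling; the multinomial
coefficient is common to all models and thus irrelevant to ranking, but
reported values include it.  `p_error` defaults to the plug-in estimate
N_aa/N (unrounded); count-level reproductions may fix it (e.g. 0.02)
to match published tables.

Model comparison reports ΔlnL of the best versus runner-up model, the
statistic 2ΔlnL with a chi-square(df = 1) tail probability — labelled
*heuristic*, because the compared models are non-nested point
hypotheses — and, on request, a parametric-bootstrap p-value: simulate
multinomial counts of the observed total under the runner-up model and
report the fraction of replicates whose 2ΔlnL reaches the observed one.
The bootstrap is the recommended inferential statement.

### Linked sites and what ΔlnL means

The multinomial treats every diagnostic site as an independent draw.
In a real genome they are not: ancestry is inherited in chromosome-scale
blocks, so the *effective* number of independent observations is close
to the number of ancestry segments (tens), not the number of sites
(10⁴–10⁶).  Two consequences, both verified by this package's simulator:

- The realized genotype-class fractions of a single backcross genome
  scatter around their expectations with standard deviation ≈ 0.11 for
  a 10-chromosome, 1-Morgan-per-chromosome genome (closed form: the
  ancestry covariance of two loci d Morgans apart is (1/4)e^(−2d) under
  Haldane meiosis; integrating gives a per-chromosome ancestry-fraction
  variance of ≈ 0.142, divided by the number of chromosomes).
- Generation selection from genome-wide counts is therefore imperfect
  even with unlimited sites: across 100 simulated genomes per true
  generation, the true g ∈ {1, 2, 3} is selected in roughly 87/60/73
  of 100 runs respectively, whereas selection from the same number of
  *unlinked* (multinomial) counts is essentially always correct.  No
  realistic map length closes this gap — reaching 99% would need tens
  of Morgans per chromosome.

ΔlnL values computed from linked sites are accordingly overconfident as
evidence measures; the direction of the comparison is robust, its
nominal significance is not.  The per-chromosome segment counts from
the painting stage are the more honest summary of how much independent
evidence a genome carries.

## Ancestry painting and smoothing

The per-site classes along a chromosome (the "graphical genotype") are
smoothed by a centered majority vote over a window of `window` sites
(default 101, odd, clipped at chromosome ends), with ties broken toward
the site's own unsmoothed class — deterministic and conservative.  Runs
of constant smoothed class become segments; segments with fewer than
`min_sites` sites (default 10) are absorbed into the longer neighbour.
Windows are indexed in sites rather than base pairs to be robust to
marker-density variation.  Smoothing a track whose segments all exceed
the window is a no-op.  a/a sites (mostly error under a backcross
model) are smoothed like any other class — the error structure is
exposed, not hidden; callers may drop them beforehand if desired.
Segment boundaries are reported at observed site positions (BED output
is 0-based half-open).

## Diversity and differentiation

θ̂_π is the average pairwise difference among the n = 2 × (panel size)
chromosomes with the small-sample factor n/(n−1), normalized by L̄, the
average number of mapped/callable sites per sample.  For unphased
biallelic genotypes the pairwise sum is computed per site from allele
counts (a site with minor-allele count c contributes c(n−c)), which is
identical to the explicit all-pairs haplotype sum.  L̄ is always an
explicit user input: it derives from upstream coverage data the
pipeline does not see, so it is never guessed or hard-coded.

F_ST per site is (H_T − H_S)/H_T with H_S the unweighted mean of the
two panels' expected heterozygosities 2p(1−p) and H_T computed at the
equal-weight pooled frequency; allele frequencies are plain counts over
2 × panel-size chromosomes with no small-sample correction.  Genome-wide
F_ST is the arithmetic mean of per-site values over sites with
H_T > 0 ("mean of ratios"); a ratio-of-means flag supports sensitivity
analysis.  The choice matters for comparisons against published values
computed with weighted estimators (e.g. Weir–Cockerham), which this
package does not implement.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Sites.**  Each chromosome carries `sites_per_chromosome` SNPs at
  uniform spacing.  Site roles — fixed-opposite between species,
  polymorphic within species A, within species B (alt frequency
  ~ U(0.1, 0.9)), or monomorphic — are assigned in exact rounded
  proportions and shuffled, so the number of true diagnostic sites is
  deterministic.
- **Panels.**  Panel genotypes are drawn per haplotype; sites
  designated within-species polymorphic are resampled until the drawn
  panel actually segregates.  This conditioning is what makes the truth
  record exact: without it, ~8% of polymorphic sites would by chance be
  fixed in a 3-diploid panel and leak into the diagnostic set.  It also
  means the generator's `within_pop_het_fraction` is the fraction of
  sites *observed* polymorphic in the panel, not a population frequency.
- **Pedigree.**  The F1 is formed from a founder of each species (by
  default a species-B mother, so the focal's organelle label is B);
  each backcross mates the current hybrid, as mother, to a freshly
  drawn species-A male.  Meiosis follows the Haldane model: crossover
  count ~ Poisson(map length in Morgans), breakpoints uniform on the
  site-index range, no interference; the gamete alternates between the
  parent's haplotypes from a uniformly chosen start.  Ancestry labels
  travel with alleles, so the truth record contains the exact per-site
  species-A dosage and the exact ancestry-block count over diagnostic
  sites.
- **Error.**  With probability ε per focal site, the genotype is
  replaced by one drawn uniformly from the three biallelic genotypes
  (`uniform` mode; maps ε to the model's p_error as ε/3 — exactly so
  for one backcross, approximately for deeper ones) or set to the
  homozygous-donor genotype (`aa_flip` mode; p_error = ε exactly).
  Defaults: ε = 0.02 in uniform mode.
- **Determinism.**  One seeded generator drives everything; the seed
  and configuration are written into the VCF header, and equal seeds
  yield byte-identical output.

Defaults (10 chromosomes, 4,000 sites of which 2,000 diagnostic per
chromosome, 1 Morgan per chromosome, 3 + 3 panel diploids, ε = 0.02)
mirror the targeted study design at desk scale — a genome of ~20,000
diagnostic markers rather than ~10⁶.  What the simulator deliberately
omits: coalescent within-species structure (panel genotypes are drawn
i.i.d. from site frequencies, so there is no linkage disequilibrium
within species), mutation/drift dynamics, selection,
recombination-rate variation along chromosomes, and sex chromosomes.
Passing tests therefore demonstrate correctness of the estimators and
the pedigree logic, not robustness to population structure or to
reference-alignment artefacts in real data.

## Numerical and degenerate-input conventions

- Likelihoods: 0·ln 0 terms are dropped; a zero-probability class with
  a positive count yields −∞ (a sentinel, never an exception), and a
  comparison in which *all* models are impossible is an error.
- Error-rate estimates ≥ 0.5 trigger a warning (the backcross-direction
  assumption is then probably violated).
- F_ST skips sites with H_T = 0; if none remain the result is an
  explicit undefined-result error, not 0.
- Per-chromosome heterozygosity on a chromosome with no classifiable
  site is NaN, never 0.
- Half-missing VCF calls (e.g. `./1`) are treated as fully missing.
- Smoothing windows must be odd; ties and chromosome-end clipping are
  handled as described above.

## Problem sizes used in the test suite

Simulation-backed tests run at 2–10 chromosomes × 400–4,000 sites with
100 replicate genomes for the recovery studies and 200 chromosomes for
the painting consistency study; these sizes give standard errors well
inside the asserted tolerances while keeping the whole suite around a
minute on a single core.
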