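# Methods

## Study design being modelled

A case/control association study in two stages. In the *pooled* stage,
equimolar 15-sample DNA pools (phenotype-homogeneous) are hybridized to
SNP arrays in three technical replicates; pool allele frequencies are
estimated from the relative allele signal RAS = A/(A+B) and tested for
case/control differences. In the *individual* stage, candidate SNPs
from the pooled screen are genotyped per subject, QC-filtered,
re-tested, replicated in larger cohorts, and summarized across cohorts
by random-effects meta-analysis.

## Synthetic cohorts

The generator is a stated world, not a tuning knob; its defaults match
the modelled design.

**Genotypes.** Controls are drawn under Hardy–Weinberg equilibrium at a
stated minor-allele frequency F₂; cases at the frequency implied by a
stated allelic odds ratio,

    F₁ = OR·F₂ / (1 + F₂·(OR − 1)),

so the population log-odds difference of minor-allele carriage is
ln(OR) by construction. This frequency-shift parameterization (rather
than a liability-threshold model) matches the allelic-test scale on
which results are reported and makes analytic recovery checks exact.

**LD.** SNPs are laid out at fixed spacing (default 25 kb) in
fixed-length blocks (default 4 SNPs). Within a block a latent uniform
is carried from SNP to SNP: kept with probability c, redrawn otherwise,
with the allele being the indicator (latent < frequency). When
consecutive SNPs share a frequency the allele correlation is exactly c,
so r² = c² is controlled by setting c = √r² (default r² = 0.9). To keep
this control exact, *one control MAF is drawn per block and shared by
its SNPs*; per-SNP MAFs would make adjacent-SNP r² depend on the
frequency gap. Blocks are mutually independent. Planted effects are
block-wide, so proxies carry signal and clump selection has true
positives. An LD reference panel (default 200 control subjects) is
simulated alongside, standing in for an external genotyped reference
cohort.

**Intensities.** Channel A has expectation gain·f and channel B
gain·(1−f) (f = pool minor-allele frequency), each multiplied by
independent log-normal noise with unit mean and CV 0.05 by default —
a deliberately minimal one-parameter noise model with no probe
cross-hybridization or batch terms. Aberrant pools are modelled as a
frequency-scale shift (default +0.1, clamped to [0,1]) applied before
intensity generation; the real-world causes (DNA quality, hybridization
artifacts) are not mechanistically modelled. Unequal sample
contributions are available through a finite Dirichlet concentration
(default exactly equimolar, under which the pool frequency equals the
mean of member frequencies exactly).

**Degradation.** Individual genotype tables can be degraded with
per-cell missingness, dosage errors (±1 within {0,1,2}; boundary flips
go inward), and injected HWE violations (heterozygote probability
inflated 1.5-fold, homozygote classes rescaled) so the QC filters have
true positives.

What a green simulation-based test establishes: that each analysis
stage recovers the parameters of *this* generative model at the stated
sizes. It does not establish robustness to probe-level artifacts,
population stratification, batch effects, or differential pooling
error, none of which are generated.

## Pooled association

Mean RAS per (SNP, pool) is the arithmetic mean over non-missing
replicates; cells with fewer than 2 usable replicates are missing.
Entries with A+B ≤ 0 are missing and counted in a QC report.

**Pool QC.** The visual first-two-principal-components outlier check
used in practice is made algorithmic: PCA on the column-centered
pool × SNP matrix (missing cells imputed with the per-SNP mean for the
decomposition only), one pass, excluding any pool whose robust z-score
(median/MAD, MAD × 1.4826) on PC1 or PC2 exceeds 3.5. With fewer than
three pools the filter refuses and passes everything through with a
warning.

**Tests.** Per SNP, an equal-variance two-sample Student's t-test on
pool RAS values (df = n₁+n₂−2; Student rather than Welch by design,
matching the modelled analysis) and a 1-df Pearson χ² on the 2×2 table
of continuous allele counts, mean RAS × 2N, where N counts the subjects
represented by *non-missing* pools at that SNP — missing pools must not
fabricate alleles. Counts are deliberately not rounded: rounding would
make results depend on pool-size parity. No continuity correction.
SNPs with < 2 usable pools in a group are untestable; zero variance in
both groups gives p = 1 when means agree and untestable otherwise.

## Candidate selection (clumping)

Greedy one-assignment clumping: candidate indices are SNPs with both
pooled p-values below 10⁻³ (the conservative intersection reading;
χ²-only indices are available behind a flag), processed in ascending
χ² p (ties: position, then id). A clump is emitted only when at least
one unclaimed same-chromosome SNP within 100 kb has r² > 0.7 (strict)
with the index and proxy χ² p < 10⁻³. Each SNP joins at most one
clump. r² is the squared Pearson correlation of unphased dosages
(composite LD) over pairwise-complete samples — no phasing needed;
monomorphic vectors or < 10 complete pairs give r² = 0. "Within a
100-kb region" is read as index–proxy distance ≤ 100,000 bp.

## Individual-genotype stage

**QC order** (single pass): drop SNPs with missingness ≥ 0.05, then
samples with missingness ≥ 0.05 (on surviving SNPs), then SNPs with
control-group exact HWE p < 10⁻³. Thresholds are exclusive for
keeping, matching the "< 0.05" phrasing of the modelled protocol; the
pass is idempotent. The HWE test is the exact conditional test (sum of
probabilities of heterozygote counts no more probable than observed,
given allele counts), computed by log-space recurrence — stable to
totals of 10⁵.

**Allelic test.** Minor allele fixed in the combined control group and
held consistent across comparisons. OR is the 2×2 allele-count
cross-product (equal to F₁(1−F₂)/(F₂(1−F₁)) when frequencies are exact
count fractions); 95% CI by the log-OR normal method with
SE = √(1/a+1/b+1/c+1/d); Haldane–Anscombe 0.5 added to every cell only
when a zero cell exists; p from the 1-df Pearson χ² on raw counts, no
continuity correction.

**Logistic models.** Additive (dosage 0/1/2), dominant (carrier),
recessive (minor homozygote) codings; maximum-likelihood fit
(statsmodels); complete separation (non-convergence or |β| > 15) is
flagged with no p-value. No covariates by default — the modelled
analysis was unadjusted — with sex/age available as options.
Benjamini–Hochberg is applied within each comparison × model family.

**Concordance.** A pooled candidate is *confirmed* when the individual
allelic test has p < 0.01 and the OR direction matches the pooled OR
(derived from group mean RAS); otherwise *discordant-direction* or
*not-significant*.

**Age at onset.** Case-only logistic regression of young (age at
diagnosis ≤ 65, coded 1) vs old (coded 0) on each SNP under all three
codings, BH across the scan. The ≤ 65 convention is the default and the
cutoff is configurable.

**Tagging substitution.** Among a user-declared LD set, the tagging SNP
is the one with the lowest missingness, ties broken by the largest
control HWE p.

## Meta-analysis

Cochran's Q = Σ wᵢ(θᵢ − θ̄)² with inverse-variance weights;
I² = max(0, (Q − (k−1))/Q) × 100, reported to one decimal, truncated at
0; DerSimonian–Laird τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)); pooled
log OR re-weighted by 1/(se² + τ²) with a two-sided Z test. DL is
chosen as the classical moment estimator (the historical default of the
standard packages); REML is not implemented. When study CIs rather than
SEs are supplied, SE = (ln CI₊ − ln CI₋)/(2·1.96).

## Design power

Two-proportion normal-approximation power at two-sided α:

    power = Φ((Δ − z_{α/2}·SE₀)/SE₁) + Φ((−Δ − z_{α/2}·SE₀)/SE₁)

with Δ = |p₁ − p₀|, SE₀ the pooled null SE and SE₁ the alternative SE.
The second (far) tail is numerically zero at any real effect size but
makes the null case exact (power → α as OR → 1). Default counting
treats the allele frequency as a per-subject proportion
(n = individuals); allele counting (n = chromosomes) is available and
gives uniformly higher power. An optional continuity correction
subtracts (1/n₁ + 1/n₂)/2 from Δ. Note the per-allele χ² actually run
on data is better powered than the per-subject analytic figure; the
Monte-Carlo calibration test verifies the χ² against the
allele-counting variant of the same formula.

## Numerical conventions

* 1-based, fully closed genomic coordinates; strand ignored.
* All tabular outputs TSV, floats at 6 significant digits, p-values in
  scientific notation.
* One global seed fans out deterministically (SeedSequence) to
  per-stage child seeds; identical inputs give identical outputs.
* Dosages are minor-allele counts; channel A carries the minor allele,
  so RAS estimates the minor-allele frequency directly.
* X-chromosome dosage conventions for males are not modelled; all SNPs
  are treated autosomally.

## Known limitations

* The intensity model has no probe-affinity, cross-hybridization or
  array-batch structure; calibration results transfer to real arrays
  only to the extent the one-parameter CV captures their noise.
* The PCA outlier rule is a deterministic stand-in for a visual call;
  its threshold (robust z > 3.5) is a package choice.
* Composite (genotype) r² can differ slightly from haplotype r² under
  Hardy–Weinberg departures.
* No population-stratification correction, genotype imputation, or
  genome-build liftover.
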