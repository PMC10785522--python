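# Methods

This note documents the statistical procedures implemented in
`skintrait-pop`, the assumptions behind them, and the design choices made
where more than one defensible convention exists.

## The analysis problem

The pipeline targets studies that assess a population's genetic
predisposition to common skin-related traits using a curated panel of
trait-associated SNPs (here organised into four categories: pigmentation,
dermatitis, nutrition and aging). Such studies combine four computations:
per-individual genetic scores per trait, a population-level "landscape" of
risk statuses, allele-frequency differentiation (Fst) between the study
population and reference populations, and a correlation screen between the
genetic scores and questionnaire phenotypes.

## Genotype representation and QC

Genotypes are risk-allele dosages (0, 1, 2; NaN for missing) in a samples ×
panel-loci matrix. VCF records are matched to the panel by rsID, with a
(chrom, pos) fallback when the ID column is "."; a record's {REF, first ALT}
pair must equal the panel's {risk, other} pair in either orientation. No
strand flipping is attempted — array-vs-reference strand mismatches
(including the inherently ambiguous A/T and C/G pairs) are resolved by
excluding the record with a warning, because a silent wrong flip corrupts
every downstream dosage whereas a dropped locus only shrinks the panel.

QC applies, in order:

1. **Samples**: removed when call rate < 0.98 or missing fraction ≥ 0.05.
2. **Variants** (on the retained samples): removed at missingness ≥ 0.05,
   Hardy–Weinberg exact p < 10⁻⁶, MAF < 0.01, or imputation R² < 0.3 (when
   an R² INFO field is present; the field name is configurable because
   imputation tools differ in what they call it).

Inequalities are strict as listed; boundary values survive. A variant
failing several checks is reported under its first failing reason
(missingness → HWE → MAF → R²), so the per-reason removal counts partition
the removed variants. Filtering is idempotent. HWE is computed on all
retained samples pooled; with strongly differentiated cohorts pooled
testing loses some power to the Wahlund effect, but at the panel's scale
(tens of loci, hundreds of samples, moderate Fst) the induced heterozygote
deficit is far from the 10⁻⁶ removal threshold.

### Hardy–Weinberg exact test

The test conditions on the sample size N and the minor-allele count n₁ and
enumerates all heterozygote counts h with the parity of n₁. The two-sided
p-value sums the conditional probabilities of every h whose probability does
not exceed that of the observed count. Probabilities are computed from
log-gamma multinomial weights normalised by log-sum-exp; a relative guard of
10⁻¹² on the "≤ observed probability" comparison keeps mathematically tied
heterozygote counts on the same side of the cut despite floating-point
noise. The exact conditional test (rather than a chi-square approximation)
is the appropriate choice at array-QC thresholds because the chi-square
statistic misbehaves at low MAF, exactly where QC decisions matter. The
test suite verifies agreement with a full-enumeration oracle in exact
rational arithmetic for every genotype configuration up to N = 50.

## Trait scoring

**GRS-RAC ("Top SNP")**: per trait, each variant contributes its risk-allele
dosage — homozygous risk (RR) = 2, heterozygous (RN) = 1, no risk allele
(NN) = 0 — and the contributions are summed. On complete data the score is
an integer in [0, 2M] for M panel variants.

**PRS**: the beta-weighted alternative Σ βⱼ·dosageⱼ. Traits with any missing
beta fall back to GRS-RAC with a warning; with all betas equal to 1 the two
scores coincide, which the tests exploit.

**Missing genotypes** contribute the cohort mean dosage of their variant
(standard polygenic-score practice). Zero-filling would systematically push
carriers of missing calls toward the low-score ("better") status; mean
filling is neutral. The fill is logged.

## The three-status landscape

For each trait the observed score range [min, max] of a designated
*reference population* is divided into three equal-width intervals
(w = (max−min)/3, cuts at min+w and min+2w). "Three equal intervals" is read
as equal score width, not as tertiles — tertile boundaries would by
construction flatten every population toward (⅓, ⅓, ⅓) and erase the
cross-population contrasts the landscape exists to show. The same fixed
boundaries are applied to all comparison populations so that proportions are
comparable; scores outside the reference range clamp into the outer
intervals. Intervals are half-open [low, high) with the top interval closed,
so boundary scores deterministically land on the higher-risk side.

Orientation: a higher risk-allele count means a worse status. Traits framed
as protective capacities (e.g. antioxidant response) carry a per-trait
`direction: protective` flag that swaps the outer labels. Trait
directionality is a panel annotation because it is a property of how the
source studies defined each trait, not of the genotype data.

## Weir–Cockerham Fst

Per locus, with r populations, nᵢ non-missing diploid calls, allele
frequency pᵢ and heterozygote proportion hᵢ:

    n̄  = Σnᵢ/r
    n_c = (r·n̄ − Σnᵢ²/(r·n̄)) / (r−1)
    p̄  = Σnᵢpᵢ/(r·n̄)
    s²  = Σnᵢ(pᵢ−p̄)²/((r−1)·n̄)
    h̄  = Σnᵢhᵢ/(r·n̄)

    a = (n̄/n_c)·[ s² − (p̄(1−p̄) − ((r−1)/r)·s² − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1))·[ p̄(1−p̄) − ((r−1)/r)·s² − ((2n̄−1)/(4n̄))·h̄ ]
    c = h̄/2

θ = a/(a+b+c), undefined at monomorphic loci (a+b+c = 0). The multi-locus
estimate is the **ratio of sums** Σa / Σ(a+b+c) — the standard "weighted"
estimator, weighting loci by information content — not the mean of per-locus
ratios; a mean-of-ratios variant is exposed for comparison because the two
differ on heterogeneous loci and the distinction is easy to get silently
wrong. Negative estimates (sampling noise around zero differentiation) are
reported as computed; an optional clipped column exists for presentation
only. Loci with no calls in a population, or monomorphic across the pair,
are dropped from both sums (for ratio-of-sums, including their (0,0,0)
components would be a no-op anyway). The general r-population formula is
implemented; the pairwise matrix uses r = 2 per unordered pair, with
per-pair locus counts reported.

At a fixed-difference locus (p₁=1, p₂=0, h=0, equal n) the components
reduce analytically to a = ½, b = c = 0, θ = 1, which the tests assert
exactly.

## Synthetic data: what it emulates, what it does not

The generator draws ancestral frequencies uniformly on a configured range
(default 0.1–0.9), per-population frequencies from the Balding–Nichols
Beta distribution with variance F·p(1−p), and genotypes as Binomial(2, p_pop)
— HWE within each population. Missing calls are injected uniformly at random.
The emitted VCF places the risk allele in REF or ALT at random per locus, so
reading it back exercises both dosage orientations. Weir–Cockerham θ is a
consistent estimator of the planted F in this model, which the acceptance
tests verify across F ∈ {0.01, 0.05, 0.10, 0.25} (1,000 loci, n = 100 per
population, 20 replicates, mean within 10% relative error).

Questionnaire variables are planted as ρ·z + √(1−ρ²)·ε on the standardised
trait score; binary items threshold that latent at a configured prevalence,
which attenuates the observed point-biserial correlation exactly as real
dichotomised measures would. Unplanted demographics and lifestyle items are
independent of the scores, with prevalences typical of an adult cohort.

The default study conditions: a reference population ("VN", n = 100) and a
comparison population ("JPT", n = 96), both at F = 0.05 from the shared
ancestral pool; 25 traits over 85 panel SNPs (ten traits with four SNPs,
fifteen with three); missingness 0.002; imputation R² drawn from
U(0.85, 1.0); a 96-respondent questionnaire on the reference population with
a ρ = 0.45 continuous correlation planted on the "wrinkles" trait and a
ρ = 0.30 binary one on "vitamin D level". The default missingness is kept
low deliberately: with only 85 loci, a single missing call already puts a
sample at the 98% call-rate boundary, so higher missingness rates are useful
for testing the sample filter but not for a clean default cohort.

What the generator does **not** emulate: linkage disequilibrium between
panel SNPs (the panel is sparse by construction), genotyping batch effects,
relatedness between samples, imputation-quality structure beyond the R²
tag, and population-specific allele ages or selection. Passing tests
therefore demonstrate the estimators' correctness under idealised
independent-locus HWE structure, not robustness to those real-data
complications.

## Correlation screen

All variables enter as numbers via an explicit codebook (binary {yes,no} →
{1,0}, ordinal levels → integer codes, continuous passed through); Pearson
correlation on a 0/1 coding is the point-biserial coefficient, so one method
covers all pairs. Each unordered pair uses its pairwise-complete cases
(listwise deletion would discard most of a ~100-row questionnaire); pairs
need n ≥ 3 and non-constant margins. p-values are two-sided from
t = R·√((n−2)/(1−R²)) on n−2 df. The primary output is unadjusted, with
significance at p < 0.05 and |R| strength bands at 0.1/0.3/0.5
(left-closed); a Benjamini–Hochberg column can be enabled for honest
multiple-testing reporting without changing the primary flags.

## Orchestration and reproducibility

The `skintrait-pop` CLI chains the stages (simulate → qc → score →
landscape → fst → correlate); each stage writes plain TSV/JSON artifacts
plus a run manifest carrying the configuration hash, seed and package
version, and each TSV carries the hash in a header comment. All randomness
flows from the single configured seed, and reruns with identical inputs and
configuration reproduce identical table contents. A downstream stage run
before its upstream artifact exists fails with an error naming the stage to
run first.

## Problem sizes

Test and acceptance computations use: full HWE oracle enumeration to
N = 50; Fst recovery at 1,000 loci × 100 diploids per population × 20
replicates per F; correlation null calibration at 25 variables × n = 96 ×
200 replicates; and the default two-population fixture (196 samples, 85
loci) for end-to-end runs. These sizes give standard errors comfortably
inside the asserted tolerances while keeping the whole suite fast.

## Known limitations

- Pooled-sample HWE filtering can over-remove strongly differentiated loci
  in multi-population matrices at large panel sizes and extreme Fst.
- No LD-aware PRS (clumping/thresholding) — the panel model assumes the
  curation step already selected approximately independent SNPs.
- A/T and C/G panel SNPs whose VCF record disagrees with the panel alleles
  are dropped, never strand-corrected; panels should be curated on the
  target reference strand.
- The landscape's equal-width intervals are sensitive to score-range
  outliers in the reference cohort.
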