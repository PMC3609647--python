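# Methods

## The estimation problem

Mutation-carrier cohorts are assembled through clinical genetics services,
so the probability that a carrier appears in the data depends on her
disease history: affected women, and especially young cases, are heavily
over-represented. For a time-to-onset outcome this breaks prospective
likelihoods — a Cox fit on such a cohort is biased — but it leaves the
conditional law of the *genotype given the phenotype* untouched, provided
selection depends on phenotype alone. `carriermod` therefore works with
the retrospective likelihood

    L_i = p_g · h_g(t_i)^{δ_i} · S_g(t_i) / Σ_{g'} p_{g'} h_{g'}(t_i)^{δ_i} S_{g'}(t_i)

per carrier, where g ∈ {0,1,2} is the SNP dosage, p_g are HWE genotype
probabilities at allele frequency q, t_i is the age at first event
(diagnosis of the modelled disease, a competing diagnosis, prophylactic
surgery, or last observation) and δ_i indicates that the first event was
the modelled disease.

## Incidence-constrained baseline

The per-genotype hazards follow proportional hazards
h_g(t) = h0(t)·exp(β g). The baseline h0 is not a free parameter: carrier
cohorts cannot estimate absolute incidence (they are not population-based),
so h0 is pinned by requiring that the genotype-averaged hazard equals an
externally supplied carrier incidence curve λ̄(t):

    Σ_g p_g h_g(t) S_g(t) / Σ_g p_g S_g(t) = λ̄(t)   at every age t.

This is solved by the fixed-point iteration
h0 ← λ̄·(Σ p_g S_g)/(Σ p_g e^{βg} S_g), recomputing the per-genotype
survivals each pass, to a max-abs change below 1e-8 (converges in a
handful of iterations; 100 iterations raises an error with the iteration
trace). At β = 0 the solution is h0 = λ̄ exactly. The same solver accepts
an arbitrary discrete mixture of log relative risks, which is how
genotype-specific effects, age-varying log-HRs, and multilocus profiles
are handled.

**Age grid.** Hazards are piecewise constant on one-year bins from age 20
to 80 (onset below 20 is negligible for the penetrance curves of
interest); cumulative hazards use left-Riemann sums, and event ages
interpolate linearly within a bin. Follow-up ages outside the grid are
clamped with a warning.

**Discrete-time conservation.** On a one-year grid the hazard-matching
constraint above conserves the *mixture survival* only to second order
(a Jensen gap of order 1e-4 in cumulative risk for wide-risk mixtures).
For per-SNP effect estimation this is immaterial — the same discretisation
is applied at every β, so likelihood differences are unaffected. For
absolute-risk projection the cumulative risk is itself the quantity of
record, so the profile model replaces the hazard fixed point with a
per-bin Newton solve that conserves Σ_G P(G)·S_G(t) = S̄(t) to machine
precision at every grid age.

## Score test with kinship-adjusted variance

Association is screened with the 1-df score test of the retrospective
likelihood at β = 0. Within stratum s, with q̂_s the plain sample allele
frequency (the MLE at the null, where the retrospective genotype law is
just p_g) and residuals r_i = δ_i − Λ̄_s(t_i):

    U_s = Σ_i (g_i − 2 q̂_s) r_i
    V_s = 2 q̂_s (1 − q̂_s) · Σ_i Σ_j 2φ_ij r_i r_j        (2φ_ii = 1)

U = Σ_s U_s is exactly the derivative of the constrained retrospective
log-likelihood at β = 0 — the baseline-derivative terms cancel, an
identity the test suite verifies against numeric differentiation to 1e-6.
φ_ij is the pedigree kinship coefficient (computed by the standard
recursion; founders unrelated), entering because the dosage covariance of
two relatives is 2φ·2q(1−q): on family data the off-diagonal terms are a
genuine part of Var(U), and dropping them (the "unadjusted" variance) is
anti-conservative whenever relatives' residuals are positively correlated
— which they are as soon as any familial risk component exists.

Two calibration caveats, both properties of this standard form rather than
implementation choices: the variance uses raw residuals, so the test is
exactly calibrated when the cohort mean residual is near zero (true under
random sampling by the martingale property, and approximately true in
practice when the affected fraction matches the cohort-average cumulative
hazard); and with family-level selection (keeping only families with an
affected member) the raw-residual variance is inflated and the test
becomes conservative. The calibration suites therefore use randomly
sampled cohorts.

## Maximum-likelihood estimation

Hazard ratios are estimated by maximising the total retrospective
log-likelihood, re-solving the constrained baseline at every trial β.
Analyses are stratified (by country in the motivating application): each
stratum gets its own allele frequency and its own constrained baseline,
and β is shared.

**Allele frequencies are profiled, not plugged in.** Under
outcome-dependent sampling with a non-null effect, the cohort's crude
allele frequency is distorted (affected carriers are enriched for risk
alleles), and plugging it into p_g biases β̂ toward the null — we measured
bias +0.06 on ln HR at a true HR of 0.7 under threefold affected
oversampling, a substantial fraction of the naive Cox bias. Each
stratum's q is therefore profiled out by an inner 1-d maximisation at
every β (the profile MLE is asymptotically equivalent to the joint MLE);
this removes the bias (to −0.005 in the same experiment). At the null the
profiled q̂ coincides with the sample frequency, so the score test is
unchanged.

The per-allele optimiser is bounded 1-d minimisation on β ∈ [−3, 3] with
tolerance 1e-8; an optimum at the bound is flagged and the CI suppressed.
Genotype-specific fits free (β₁, β₂) by Nelder-Mead started from the
log-additive solution. Standard errors come from central second
differences of the profile log-likelihood (step 1e-3); confidence
intervals are Wald on the log scale. The genotype-by-age interaction
models the per-allele log-HR as β0 + β1·(t−50)/10 with a 1-df LRT of
β1 = 0; country heterogeneity is the LRT of common-β against per-stratum
β with (#strata − 1) df. p-values are never genomic-control adjusted.

## Competing risks and tumour subtypes

The competing-risks model gives breast and ovarian cancer cause-specific
hazards h_{B,g} = h0B·e^{β_B g} and h_{O,g} = h0O·e^{β_O g}, each baseline
constrained to its own incidence curve with the averaging weighted by the
joint survival exp(−H_B − H_O); the two baselines are solved by a joint
fixed point and (β_B, β_O) by a 2-d maximisation. With no ovarian events
the ovarian effect is fixed at zero and the fit reduces exactly to the
single-cause model. The subtype model splits the breast hazard into
ER-positive and ER-negative components with an age-constant split
(default 77% ER+, the approximate proportion in BRCA2-carrier tumours)
and separate per-allele effects; unknown-ER cases contribute the sum of
the two cause-specific densities, and subtype heterogeneity is the 1-df
LRT of β₊ = β₋.

## QC filters

SNPs: call rate < 0.95, monomorphic, stratified Hardy-Weinberg p < 1e-7.
The HWE statistic is the 1-df inbreeding-coefficient form
f̂_s = 1 − obs_het/(2q̂_s(1−q̂_s)) combined across strata with sample-size
weights, Z = Σ_s n_s f̂_s / √(Σ_s n_s), so Z² is χ²₁-calibrated for any
number of strata and reduces to the classic n·f̂² with one stratum.
Samples: call rate < 0.95; two-sided heterozygosity outliers at p < 1e-6
against the cohort mean/SD (a cohort-level normal approximation, the
standard array-QC practice); duplicate pairs excluded entirely when
discordant (default tolerance 5% of co-called SNPs), concordant pairs
keep the first-listed sample. Ancestry fractions use simplex-constrained
least squares of dosage fractions on reference population allele
frequencies (non-negative least squares with a sum-to-one penalty row,
renormalised) — a deterministic substitute for an MDS embedding that
targets the same decision, exclusion of samples with > 19% non-reference
ancestry. All thresholds are strict inequalities.

## Genomic control

λ = median(χ²)/median(χ²₁); λ₁₀₀₀ = 1 + (λ−1)·(1/n_aff + 1/n_unaff)/(2/1000).
QQ tables use exact Beta order-statistic medians for the expected
quantiles. λ is a diagnostic only; no correction is applied.

## Risk profiles

A panel of K independent loci with multiplicative per-allele effects
defines ln RR = Σ_k g_k ln HR_k, a discrete distribution computed by
sequential convolution of 3-point HWE distributions. Support points equal
within 1e-10 are merged exactly; because distinct HRs essentially never
collide, the support would otherwise grow as 3^K, so it is capped (default
32,768 atoms) by pooling adjacent atoms on a uniform grid, preserving
total probability and the probability-weighted mean — ln RR resolution
stays below 1e-4, far inside the 0.005 tolerance of the Monte-Carlo
cross-check. The baseline is constrained jointly for the whole panel
(survival-matched form, above), and per-age summaries report the minimum,
requested percentiles, average and maximum cumulative risk; the "lowest
5%" band of carriers spans [minimum, 5th-percentile risk] and the
"highest 5%" band [95th percentile, maximum]. The shipped
`BRCA2_MODIFIER_PANEL` lists the strongest SNP per established modifier
region (MAF and per-allele HR); the shipped incidence curves are
illustrative step curves (~52% breast, ~12% ovarian cumulative risk by
80), since published carrier penetrance tables are not redistributable —
absolute numbers from the defaults are demonstration values, not clinical
estimates.

## Synthetic cohorts

The generator emulates the data-generating process the model assumes plus
the nuisances QC must catch: HWE founder genotypes, Mendelian
transmission to sibships (all-female offspring are the genotyped study
cohort; parents exist as pedigree links), genotype-dependent breast onset
drawn by inverse transform from the constrained baseline (onset placed
uniformly within its year), genotype-independent ovarian onset,
truncated-normal recruitment ages (mean 55, SD 12, range 21-80) that act
as censoring, a small prophylactic-mastectomy rate (2%), country strata
assigned per family, missing calls, and optional duplicate samples.
Ascertainment policies: random; individual-level affected oversampling at
odds ratio r (optionally targeting a cohort size); or affected-proband
family selection. ER status is assigned to cases as 77% positive with 10%
masked unknown; a mutation-class label (e.g. the founder-mutation flag)
is carried but not modelled.

An optional `background` of unobserved modifier loci (maf, hr pairs)
induces the familial phenotype correlation real cohorts show; the
calibration suites use ten loci of MAF 0.3 and HR 1.72 (log-hazard
variance ≈ 1.2, the scale of the established polygenic component for
BRCA2 carriers). With a background present the constraint is applied to
the full profile mixture, so the population-average incidence still
matches λ̄(t) exactly.

What the generator does not emulate: LD between SNPs, genotyping
intensities and calling error, imputation dosages, calendar-period or
birth-cohort incidence variation (a single age-indexed curve is used),
shared non-genetic family environment, and age-varying ER proportions.
Passing tests therefore demonstrate correctness of the estimators under
the model's own assumptions and robustness to outcome-dependent sampling
and relatedness — not robustness to LD structure or incidence-curve
misspecification.

## Validation design and problem sizes

The validation suite runs at sizes chosen to give each check real
statistical teeth while staying desk-scale: score-test calibration pools
2,000 null sib-correlated SNPs over twenty 300-sib-pair cohorts (the
adjusted test must sit inside the exact binomial 99% window at α = 0.05,
and the unadjusted variance must fall measurably short of the
kinship-aware variance); ascertainment robustness uses 200 replicates of
n = 2,000 at true HR 0.7 under threefold oversampling against a lifelines
Cox comparator; parameter recovery uses one cohort of ~8,200 carriers
(~4,300 affected) at MAF 0.35 and HR 0.85; the null pipeline runs 5,000
SNPs through generation, QC and kinship-adjusted score tests and checks
λ ∈ [0.95, 1.05]; the profile projection is cross-checked against 10⁶
Monte-Carlo profile draws. Every stochastic check is seeded.

## Known limitations

- The likelihood is per-individual (composite over relatives), with
  relatedness entering only through the score variance; a full pedigree
  likelihood would be marginally more efficient for estimation.
- The raw-residual score variance is exact under phenotype-independent
  sampling and individual-level oversampling near the
  affected-fraction/incidence balance point, but conservative under
  family-level ascertainment (see above).
- λ's sampling noise with 5,000 SNPs is ≈ 0.03, comparable to the
  [0.95, 1.05] diagnostic band itself.
- Ancestry projection assumes the reference populations span the
  admixture space; it estimates fractions, not cluster membership.
- Competing-risks and subtype baselines assume the supplied incidence
  curves refer to the same carrier population as the cohort.
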