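# carriermod

Genetic modifier analysis for ascertained mutation-carrier cohorts.

Women carrying a high-penetrance mutation (the motivating case is *BRCA2*)
are mostly recruited through genetic-counselling clinics, where testing
targets women already diagnosed with breast or ovarian cancer — sampling is
outcome dependent, and standard survival analysis (Cox partial likelihood)
of such cohorts gives biased estimates of modifier-SNP effects.
`carriermod` implements the survival framework consortia use for modifier
GWAS in this setting, end to end:

- **Retrospective likelihood.** Each carrier contributes the probability of
  her *genotype* given her phenotype,
  `L_i = p_g h_g(t_i)^δ S_g(t_i) / Σ_g' p_g' h_g'(t_i)^δ S_g'(t_i)`,
  which is invariant to phenotype-dependent sampling. Per-genotype hazards
  follow `h_g(t) = h0(t) e^{βg}` with the baseline constrained so the
  genotype-averaged hazard reproduces a supplied carrier incidence curve
  λ̄(t) at every age; follow-up ends at the first of diagnosis, competing
  diagnosis, prophylactic surgery, or last observation.
- **Kinship-adjusted score test.** The 1-df score
  `U = Σ_s Σ_i (g_i − 2q̂_s)(δ_i − Λ̄_s(t_i))` with variance
  `V = Σ_s 2q̂_s(1−q̂_s) Σ_ij 2φ_ij r_i r_j`, where φ is the pedigree kinship
  coefficient — relatives share alleles, and ignoring that inflates test
  statistics on family data.
- **Array QC.** Call-rate, monomorphism and stratified 1-df Hardy-Weinberg
  filters for SNPs; call-rate, heterozygosity, duplicate-concordance and
  ancestry-fraction filters for samples.
- **Genomic control.** Median-based λ and λ₁₀₀₀ (λ standardised to 1000
  affected / 1000 unaffected), plus QQ-plot data.
- **Extensions.** Competing-risks joint fit of breast and ovarian
  cause-specific hazards; ER-subtype-specific effects with a heterogeneity
  LRT; genotype-by-age interaction and between-country heterogeneity tests;
  prevalent-case sensitivity filtering.
- **Absolute-risk profiles.** The combined multilocus risk distribution of a
  SNP panel (exact dynamic-programming convolution under HWE and
  multiplicative effects), with the baseline constrained so the
  profile-averaged incidence matches the carrier incidence curve, projected
  into per-percentile absolute risks by age.
- **Synthetic cohorts.** A pedigree-structured generator (HWE founders,
  Mendelian transmission, genotype-dependent onset matched to the incidence
  constraint, clinic-style oversampling, country strata, missing calls,
  duplicates) so every stage is testable without access to consortium data.

## Worked example

```python
import carriermod as cm

cfg = cm.SyntheticConfig(
    n_families=4000, sibs_per_family=2, maf=0.35, per_allele_hr=0.85,
    ascertainment_policy=("oversample_affected", 3.0, 4000),
    seed=42, n_strata=4,
)
records, genotypes, pedigree = cm.simulate_cohort(cfg)
kinship = cm.compute_kinship(pedigree)

res = cm.fit_per_allele(
    records, genotypes.dosages.iloc[:, 0].to_numpy(),
    cfg.incidence, strata="stratum", kinship=kinship,
)
print(f"per-allele HR = {res.hr:.3f} (95% CI {res.ci_lo:.3f}-{res.ci_hi:.3f})")
print(f"score chi2 = {res.score_chi2:.2f}, p = {res.p:.2e}")
```

prints

```
per-allele HR = 0.805 (95% CI 0.740-0.875)
score chi2 = 20.51, p = 5.93e-06
```

a cohort of 3,979 carriers (1,987 affected, 1,992 unaffected — affected
oversampled threefold) simulated with a true protective per-allele HR of
0.85: the retrospective fit recovers it within sampling error despite the
outcome-dependent sampling, and the score test detects it at p ≈ 6×10⁻⁶.

Projecting the 14-region *BRCA2* modifier panel into absolute risks:

```python
from carriermod.profile_risk import BRCA2_MODIFIER_PANEL
out = cm.absolute_risk_percentiles(BRCA2_MODIFIER_PANEL,
                                   cm.default_breast_incidence())
print(out.round(3).to_string(index=False))
```

```
 age  risk_min  risk_avg  risk_max  risk_p5  risk_p95
  50     0.044     0.189     0.819    0.113     0.292
  80     0.148     0.518     0.998    0.350     0.709
```

With an average carrier risk of ~52% by age 80, carriers in the lowest 5%
of the combined SNP profile face a risk of 15-35% while the highest 5% face
71-100% — the spread that motivates profile-based risk stratification.
(The shipped incidence curves are illustrative; real projections should use
published carrier penetrance tables via `IncidenceCurve.read_csv`.)

A CLI mirrors the library: `carriermod qc`, `carriermod assoc`
(`--competing-risks`, `--subtype er`), `carriermod gc`,
`carriermod profile-risk`, and `carriermod run --config pipeline.yaml`.

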