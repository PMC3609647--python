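"""SNP and sample quality control for array genotype matrices.

Filters mirror standard array-QC practice for consortium genotyping:

* SNPs — call rate < 95%, monomorphic, or stratified Hardy-Weinberg
  disequilibrium at p < 1e-7 (1-df inbreeding-coefficient test combined
  across strata, so population structure between countries does not fake
  a departure).
* samples — call rate < 95%, heterozygosity outliers (two-sided normal
  test of the per-sample heterozygote fraction against the cohort at
  p < 1e-6, catching contamination and genotyping failure), duplicate
  pairs (discordant pairs dropped entirely, concordant pairs keep one),
  and estimated non-European ancestry fraction > 19%.

Thresholds are strict inequalities as printed; every exclusion carries
exactly one primary reason, assigned in the order listed above.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pio import GenotypeMatrix

__all__ = [
    "snp_qc",
    "stratified_hwe_test",
    "sample_qc",
    "ancestry_fractions",
]


def _dosage_array(genotypes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(genotypes, GenotypeMatrix):
        df = genotypes.dosages
    else:
        df = genotypes
    return df.to_numpy(float), df.index.to_numpy(), df.columns.to_numpy()


def stratified_hwe_test(counts_by_stratum) -> tuple[float, float]:
    """Stratified 1-df Hardy-Weinberg test via inbreeding coefficients.

    Each stratum s with genotype counts (n0, n1, n2), n_s = n0+n1+n2 and
    allele frequency q̂_s contributes f̂_s = 1 − obs_het/(2 q̂_s(1−q̂_s)),
    whose null variance is ≈ 1/n_s.  Strata are combined with sample-size
    weights,  Z = Σ_s n_s f̂_s / sqrt(Σ_s n_s),  and χ² = Z² is referred to
    a 1-df chi-square (for a single stratum this is the classic n·f̂²
    statistic).  A fixated stratum (q̂ ∈ {0,1}) carries no information and
    contributes 0 with a warning.
    """
    num = 0.0
    den = 0.0
    for counts in counts_by_stratum:
        n0, n1, n2 = (int(c) for c in counts)
        n = n0 + n1 + n2
        if n < 1:
            raise ValueError("each stratum needs at least one genotyped sample")
        q = (n1 + 2 * n2) / (2 * n)
        if q in (0.0, 1.0):
            warnings.warn("fixated stratum contributes nothing to the HWE test")
            continue
        het = n1 / n
        f_hat = 1.0 - het / (2 * q * (1 - q))
        num += n * f_hat
        den += n
    if den == 0:
        return 0.0, 1.0
    chi2 = num * num / den
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def snp_qc(
    genotypes,
    strata=None,
    call_rate: float = 0.95,
    hwe_p: float = 1e-7,
) -> pd.DataFrame:
    """Per-SNP QC report; one row per SNP with statistics and exclusions.

    ``strata`` is a per-sample label array (single stratum when None).
    Exclusion reasons in priority order: call_rate, monomorphic, hwe.
    An all-missing SNP is excluded for call rate, not an error.
    """
    X, sample_ids, snp_ids = _dosage_array(genotypes)
    n, m = X.shape
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    labels = np.unique(strata)

    valid = np.isfinite(X)
    n_called = valid.sum(axis=0)
    cr = n_called / n
    with np.errstate(invalid="ignore"):
        maf = np.where(n_called > 0, np.nansum(X, axis=0) / (2 * np.maximum(n_called, 1)), np.nan)
    maf = np.where(maf > 0.5, 1 - maf, maf)

    hwe_chi2 = np.full(m, np.nan)
    hwe_pv = np.full(m, np.nan)
    for k in range(m):
        if n_called[k] == 0:
            continue
        counts = []
        for lab in labels:
            xs = X[strata == lab, k]
            xs = xs[np.isfinite(xs)]
            if xs.size == 0:
                continue
            counts.append(((xs == 0).sum(), (xs == 1).sum(), (xs == 2).sum()))
        if counts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hwe_chi2[k], hwe_pv[k] = stratified_hwe_test(counts)

    mono = (maf == 0.0) | (maf == 1.0) | (n_called == 0)
    reason = np.full(m, "", dtype=object)
    reason[np.where((cr < call_rate))[0]] = "call_rate"
    sel = (reason == "") & mono
    reason[sel] = "monomorphic"
    with np.errstate(invalid="ignore"):
        sel = (reason == "") & np.isfinite(hwe_pv) & (hwe_pv < hwe_p)
    reason[sel] = "hwe"

    return pd.DataFrame(
        {
            "snp": snp_ids,
            "call_rate": cr,
            "maf": maf,
            "hwe_chi2": hwe_chi2,
            "hwe_p": hwe_pv,
            "monomorphic": mono,
            "excluded": reason != "",
            "reason": reason,
        }
    )


def sample_qc(
    genotypes,
    duplicates=None,
    call_rate: float = 0.95,
    het_p: float = 1e-6,
    discordance: float = 0.05,
) -> pd.DataFrame:
    """Per-sample QC report.

    ``duplicates`` is an iterable of (id_a, id_b) known duplicate pairs;
    pairs with genotype discordance above ``discordance`` (fraction of
    co-called SNPs) are both excluded, concordant pairs keep the first.
    Exclusion priority: call_rate, heterozygosity, duplicate_discordance,
    duplicate.
    """
    X, sample_ids, snp_ids = _dosage_array(genotypes)
    n, m = X.shape
    valid = np.isfinite(X)
    cr = valid.sum(axis=1) / max(m, 1)
    with np.errstate(invalid="ignore"):
        het = np.where(valid.sum(axis=1) > 0, (X == 1).sum(axis=1) / np.maximum(valid.sum(axis=1), 1), np.nan)
    mu = np.nanmean(het)
    sd = np.nanstd(het, ddof=1)
    if sd > 0:
        z = (het - mu) / sd
        het_pv = 2 * stats.norm.sf(np.abs(z))
    else:
        z = np.zeros(n)
        het_pv = np.ones(n)

    reason = np.full(n, "", dtype=object)
    reason[cr < call_rate] = "call_rate"
    sel = (reason == "") & (het_pv < het_p)
    reason[sel] = "heterozygosity"

    idx_of = {s: i for i, s in enumerate(sample_ids)}
    dup_flag = np.zeros(n, dtype=bool)
    for pair in duplicates or []:
        a, b = pair
        if a not in idx_of or b not in idx_of:
            raise ValueError(f"duplicate pair ({a}, {b}) references unknown sample")
        ia, ib = idx_of[a], idx_of[b]
        both = valid[ia] & valid[ib]
        disc = float(np.mean(X[ia, both] != X[ib, both])) if both.any() else 1.0
        if disc > discordance:
            dup_flag[[ia, ib]] = True
            for i in (ia, ib):
                if reason[i] == "":
                    reason[i] = "duplicate_discordance"
        else:
            if reason[ib] == "":
                reason[ib] = "duplicate"
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "call_rate": cr,
            "het_fraction": het,
            "het_z": z,
            "duplicate_discordant": dup_flag,
            "excluded": reason != "",
            "reason": reason,
        }
    )


def ancestry_fractions(
    genotypes,
    reference_freqs: pd.DataFrame,
    european_label: str = "EUR",
    threshold: float = 0.19,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Admixture fractions by simplex-constrained least squares.

    Each sample's allele-dosage fractions (dosage/2) are projected onto the
    reference populations' allele-frequency vectors, with mixing weights
    constrained to the probability simplex (non-negative least squares
    with a sum-to-one penalty row, then renormalised).  The non-European
    fraction is 1 − w[european_label]; samples with fraction strictly
    above ``threshold`` are flagged for exclusion.

    ``reference_freqs``: DataFrame indexed by SNP id, one column per
    reference population, values = allele frequencies of the counted
    allele.  Requires ≥ 2 populations and ≥ ``min_snps`` SNPs shared with
    the genotype matrix.
    """
    if reference_freqs.shape[1] < 2:
        raise ValueError("need at least two reference populations")
    if european_label not in reference_freqs.columns:
        raise ValueError(f"reference table lacks population {european_label!r}")
    X, sample_ids, snp_ids = _dosage_array(genotypes)
    shared = [i for i, s in enumerate(snp_ids) if s in reference_freqs.index]
    if len(shared) < min_snps:
        raise ValueError(
            f"only {len(shared)} SNPs shared with the reference (need >= {min_snps})"
        )
    F = reference_freqs.loc[[snp_ids[i] for i in shared]].to_numpy(float)
    pops = list(reference_freqs.columns)
    lam = 10.0  # sum-to-one penalty weight
    rows = []
    for i in range(X.shape[0]):
        d = X[i, shared]
        ok = np.isfinite(d)
        if ok.sum() < min_snps:
            raise ValueError(f"sample {sample_ids[i]} has too few called reference SNPs")
        A = np.vstack([F[ok], lam * np.ones((1, F.shape[1]))])
        y = np.concatenate([d[ok] / 2.0, [lam]])
        w, _ = optimize.nnls(A, y)
        total = w.sum()
        w = w / total if total > 0 else np.full_like(w, 1.0 / w.size)
        rows.append(w)
    W = np.asarray(rows)
    out = pd.DataFrame(W, columns=pops)
    out.insert(0, "sample_id", sample_ids)
    out["non_european_fraction"] = 1.0 - out[european_label]
    out["excluded"] = out["non_european_fraction"] > threshold
    return out
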