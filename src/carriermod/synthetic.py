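"""Pedigree-structured synthetic carrier cohorts.

Emulates the data a mutation-carrier consortium assembles: sibships of
female carriers recruited through clinics, genotyped on a SNP panel, with
age at breast/ovarian onset driven by genotype-dependent proportional
hazards whose *population average* reproduces a supplied carrier incidence
curve, plus outcome-dependent sampling, country strata, missing calls and
duplicate samples for QC exercises.

Model per carrier i:  h_i(t) = h0(t) · exp(β·g_i + Σ_k βk·b_ik), where g is
the focal SNP, b_ik an optional unobserved polygenic modifier background
(independent loci, multiplicative), and h0 solved so that the mixture
hazard over the combined profile equals the input incidence at every age.
The background induces the within-family phenotype correlation that real
modifier panels create, which is what the kinship-adjusted score test
exists for.  Ovarian onset is genotype independent.  Follow-up ends at the
first of breast onset, ovarian onset, prophylactic mastectomy, or
recruitment (last observation).

All randomness flows from one ``numpy`` generator seeded by ``seed``; two
runs with the same config are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .incidence import IncidenceCurve, default_breast_incidence, default_ovarian_incidence
from .pio import GenotypeMatrix
from .profile_risk import LocusSpec, profile_distribution
from .retrospective import constrained_baseline

__all__ = ["SyntheticConfig", "simulate_families", "simulate_phenotypes",
           "apply_ascertainment", "simulate_cohort",
           "simulate_null_sibship_genotypes"]


@dataclass
class SyntheticConfig:
    """Generative settings for one synthetic cohort.

    ``sibs_per_family`` is an int or an inclusive (lo, hi) range sampled
    uniformly.  SNP 0 carries the focal effect (``maf``, ``per_allele_hr``);
    the remaining ``n_snps - 1`` SNPs are null with MAFs drawn uniformly on
    (0.1, 0.5).  ``background`` lists unobserved (maf, hr) modifier loci
    shared through the pedigree.  ``ascertainment_policy`` is "random",
    ("oversample_affected", ratio[, target_n]) or "affected_proband".
    """

    n_families: int = 1000
    sibs_per_family: int | tuple = 2
    maf: float = 0.35
    per_allele_hr: float = 1.0
    n_snps: int = 1
    background: list | None = None  # [(maf, hr), ...]
    incidence: IncidenceCurve = field(default_factory=default_breast_incidence)
    ovarian_incidence: IncidenceCurve = field(default_factory=default_ovarian_incidence)
    censor_age_mean: float = 55.0
    censor_age_sd: float = 12.0
    ascertainment_policy: object = "random"
    n_strata: int = 4
    missing_rate: float = 0.0
    n_duplicate_pairs: int = 0
    mastectomy_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.maf < 1.0:
            raise ValueError(f"MAF must lie strictly in (0,1), got {self.maf}")
        if self.per_allele_hr <= 0:
            raise ValueError("per-allele HR must be positive")
        if self.n_families < 1 or self.n_snps < 1 or self.n_strata < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")


def _sib_counts(cfg: SyntheticConfig, rng) -> np.ndarray:
    if isinstance(cfg.sibs_per_family, (tuple, list)):
        lo, hi = cfg.sibs_per_family
        return rng.integers(lo, hi + 1, size=cfg.n_families)
    return np.full(cfg.n_families, int(cfg.sibs_per_family))


def _mendelian(father: np.ndarray, mother: np.ndarray, rng) -> np.ndarray:
    """One offspring dosage per row given parent dosages (vectorised)."""
    return (
        (rng.random(father.shape) < father / 2.0).astype(float)
        + (rng.random(mother.shape) < mother / 2.0)
    )


def simulate_families(config: SyntheticConfig):
    """Draw founder genotypes from HWE and transmit to sibships.

    Returns ``(GenotypeMatrix, pedigree)``.  The matrix covers founders and
    offspring; the observed ``dosages`` have missing calls injected at
    ``missing_rate`` (true dosages are retained separately for phenotype
    simulation).  Optional duplicate samples (copies of random offspring,
    id suffix ``_dup``) are appended for QC exercises.
    """
    rng = np.random.default_rng(config.seed)
    n_fam = config.n_families
    sibs = _sib_counts(config, rng)
    mafs = np.concatenate(
        [[config.maf], rng.uniform(0.1, 0.5, size=config.n_snps - 1)]
    )

    father = rng.binomial(2, mafs[None, :], size=(n_fam, config.n_snps)).astype(float)
    mother = rng.binomial(2, mafs[None, :], size=(n_fam, config.n_snps)).astype(float)
    fam_of_sib = np.repeat(np.arange(n_fam), sibs)
    child = _mendelian(father[fam_of_sib], mother[fam_of_sib], rng)

    strata = rng.integers(config.n_strata, size=n_fam)
    fam_ids = np.array([f"F{i:05d}" for i in range(n_fam)])
    rows = []
    for i in range(n_fam):
        rows.append((fam_ids[i], f"{fam_ids[i]}_P1", "0", "0", 1, 0))
        rows.append((fam_ids[i], f"{fam_ids[i]}_P2", "0", "0", 2, 0))
    sib_index_within = np.concatenate([np.arange(k) for k in sibs]) if sibs.sum() else np.array([], int)
    sib_ids = np.array(
        [f"{fam_ids[f]}_S{j + 1}" for f, j in zip(fam_of_sib, sib_index_within)]
    )
    for sid, f in zip(sib_ids, fam_of_sib):
        rows.append((fam_ids[f], sid, f"{fam_ids[f]}_P1", f"{fam_ids[f]}_P2", 2, 0))
    pedigree = pd.DataFrame(
        rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "affection"],
    )

    ids = []
    dos_rows = []
    for i in range(n_fam):
        ids.extend([f"{fam_ids[i]}_P1", f"{fam_ids[i]}_P2"])
        dos_rows.extend([father[i], mother[i]])
    ids.extend(sib_ids.tolist())
    dos_rows.extend(list(child))
    true = pd.DataFrame(
        np.asarray(dos_rows), index=pd.Index(ids, name="sample_id"),
        columns=[f"snp{k:04d}" for k in range(config.n_snps)],
    )

    observed = true.to_numpy().copy()
    if config.missing_rate > 0:
        mask = rng.random(observed.shape) < config.missing_rate
        observed[mask] = np.nan
    obs = pd.DataFrame(observed, index=true.index, columns=true.columns)

    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "family_id": [i.rsplit("_", 1)[0] for i in ids],
            "role": ["founder" if i.endswith(("_P1", "_P2")) else "sib" for i in ids],
            "sex": [1 if i.endswith("_P1") else 2 for i in ids],
        }
    )
    stratum_of_fam = {fam_ids[i]: f"C{strata[i]}" for i in range(n_fam)}
    samples["stratum"] = samples["family_id"].map(stratum_of_fam)

    if config.n_duplicate_pairs > 0:
        if sib_ids.size == 0:
            raise ValueError("cannot inject duplicates without offspring")
        pick = rng.choice(sib_ids, size=config.n_duplicate_pairs, replace=False)
        dup_obs = obs.loc[pick].copy()
        dup_obs.index = pd.Index([f"{s}_dup" for s in pick], name="sample_id")
        obs = pd.concat([obs, dup_obs])
        dup_samples = samples[samples["sample_id"].isin(pick)].copy()
        dup_samples["sample_id"] = dup_samples["sample_id"] + "_dup"
        dup_samples["role"] = "duplicate"
        samples = pd.concat([samples, dup_samples], ignore_index=True)

    snps = pd.DataFrame({"snp": true.columns, "maf": mafs})
    gm = GenotypeMatrix(obs, snps=snps, samples=samples, true_dosages=true)
    return gm, pedigree


def _background_dosages(config: SyntheticConfig, gm: GenotypeMatrix, rng):
    """Unobserved modifier-locus dosages, transmitted through the pedigree."""
    if not config.background:
        return None
    loci = [LocusSpec(f"bg{k}", m, h) for k, (m, h) in enumerate(config.background)]
    mafs = np.array([l.maf for l in loci])
    samples = gm.samples
    fams = samples["family_id"].unique()
    fam_idx = {f: i for i, f in enumerate(fams)}
    father = rng.binomial(2, mafs[None, :], size=(len(fams), len(loci))).astype(float)
    mother = rng.binomial(2, mafs[None, :], size=(len(fams), len(loci))).astype(float)
    out = np.zeros((len(samples), len(loci)))
    fam_of = samples["family_id"].map(fam_idx).to_numpy()
    is_p1 = samples["sample_id"].str.endswith("_P1").to_numpy()
    is_p2 = samples["sample_id"].str.endswith("_P2").to_numpy()
    is_off = ~(is_p1 | is_p2)
    out[is_p1] = father[fam_of[is_p1]]
    out[is_p2] = mother[fam_of[is_p2]]
    out[is_off] = _mendelian(father[fam_of[is_off]], mother[fam_of[is_off]], rng)
    log_hr = np.log([l.hr for l in loci])
    return loci, out @ log_hr


def _draw_onset(cum_target: np.ndarray, curve: IncidenceCurve, baseline: np.ndarray, rng):
    """Inverse-transform onset ages from a baseline hazard; NaN = never.

    ``cum_target`` is the per-individual required baseline cumulative
    hazard −ln(U)/RR_i.  Onset is located on the one-year grid and placed
    uniformly within the year.
    """
    cum_grid = np.concatenate([[0.0], np.cumsum(baseline)])  # at bin edges
    n = cum_target.size
    bin_idx = np.searchsorted(cum_grid, cum_target, side="left") - 1
    never = bin_idx >= baseline.size
    bin_idx = np.clip(bin_idx, 0, baseline.size - 1)
    ages = curve.ages[bin_idx] + rng.random(n)
    ages[never] = np.nan
    return ages


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SyntheticConfig) -> pd.DataFrame:
    """Simulate carrier phenotype records for the offspring generation.

    Breast onset follows the constrained proportional-hazards model (focal
    SNP plus any polygenic background); ovarian onset follows the ovarian
    incidence independent of genotype; censoring is at the recruitment age
    (truncated-normal draw) or prophylactic mastectomy.  Returns the
    CarrierRecord table for female offspring (the genotyped study cohort;
    parents exist only as pedigree links).
    """
    rng = np.random.default_rng(config.seed + 104729)  # independent stream
    if genotypes.true_dosages is None:
        raise ValueError("phenotype simulation needs the generating dosages")
    samples = genotypes.samples
    sib_mask = (samples["role"] == "sib").to_numpy()
    cohort = samples.loc[sib_mask].reset_index(drop=True)
    n = len(cohort)
    if n == 0:
        raise ValueError("no offspring to phenotype (sibs_per_family = 0)")

    beta = float(np.log(config.per_allele_hr))
    g_causal = genotypes.true_dosages.iloc[:, 0].to_numpy()[sib_mask.nonzero()[0]]
    ln_rr = beta * g_causal

    profile = [LocusSpec("causal", config.maf, config.per_allele_hr)]
    bg = _background_dosages(config, genotypes, rng)
    if bg is not None:
        bg_loci, bg_lnrr = bg
        ln_rr = ln_rr + bg_lnrr[sib_mask.nonzero()[0]]
        profile = profile + bg_loci

    values, probs = profile_distribution(profile)
    model = constrained_baseline(config.incidence, probs, values)
    h0 = model.baseline

    u = rng.random(n)
    breast_onset = _draw_onset(-np.log(u) / np.exp(ln_rr), config.incidence, h0, rng)
    u2 = rng.random(n)
    ovarian_onset = _draw_onset(
        -np.log(u2), config.ovarian_incidence, config.ovarian_incidence.hazard, rng
    )

    recruit = np.clip(
        rng.normal(config.censor_age_mean, config.censor_age_sd, size=n),
        config.incidence.age_start + 1.0,
        config.incidence.age_end,
    )
    mast_age = np.full(n, np.nan)
    has_mast = rng.random(n) < config.mastectomy_rate
    mast_age[has_mast] = rng.uniform(30, 60, size=int(has_mast.sum()))

    ends = np.vstack(
        [
            np.where(np.isnan(breast_onset), np.inf, breast_onset),
            np.where(np.isnan(ovarian_onset), np.inf, ovarian_onset),
            np.where(np.isnan(mast_age), np.inf, mast_age),
            recruit,
        ]
    )
    first = np.argmin(ends, axis=0)
    t = ends[first, np.arange(n)]
    breast_event = (first == 0).astype(int)
    ovarian_event = (first == 1).astype(int)

    # tumour ER status: ~77% of carrier breast tumours ER+, 10% unascertained
    er = np.full(n, "unknown", dtype=object)
    aff = breast_event == 1
    is_pos = rng.random(n) < 0.77
    known = rng.random(n) >= 0.10
    er[aff & known & is_pos] = "pos"
    er[aff & known & ~is_pos] = "neg"

    mut = np.where(
        rng.random(len(samples["family_id"].unique())) < 0.1, "6174delT", "other"
    )
    fam_list = samples["family_id"].unique()
    mut_of = dict(zip(fam_list, mut))

    records = pd.DataFrame(
        {
            "sample_id": cohort["sample_id"],
            "family_id": cohort["family_id"],
            "stratum": cohort["stratum"],
            "censor_age": t,
            "breast_event": breast_event,
            "ovarian_event": ovarian_event,
            "mastectomy_age": np.where(first == 2, t, np.nan),
            "diagnosis_age": np.where(breast_event == 1, t, np.nan),
            "recruitment_age": recruit,
            "er_status": er,
            "mutation_class": cohort["family_id"].map(mut_of),
        }
    )
    return records


def apply_ascertainment(records: pd.DataFrame, policy, seed: int = 0, target_n: int | None = None):
    """Outcome-dependent subsampling of the simulated cohort.

    * ``"random"`` — keep everyone (or a simple random ``target_n``).
    * ``("oversample_affected", r)`` or ``("oversample_affected", r, target_n)``
      — affected retained with probability r·p and unaffected with p, with p
      set to hit ``target_n`` (p = 1/r when no target is given, i.e. all
      affected kept).
    * ``"affected_proband"`` — keep only families with at least one affected
      member; the earliest-diagnosed affected is flagged as proband.
    """
    rng = np.random.default_rng(seed)
    rec = records.reset_index(drop=True)
    if isinstance(policy, str) and policy == "random":
        if target_n is not None and target_n < len(rec):
            keep = rng.choice(len(rec), size=target_n, replace=False)
            rec = rec.iloc[np.sort(keep)]
        out = rec.reset_index(drop=True)
    elif isinstance(policy, (tuple, list)) and policy[0] == "oversample_affected":
        ratio = float(policy[1])
        tn = target_n if target_n is not None else (policy[2] if len(policy) > 2 else None)
        aff = rec["breast_event"].to_numpy() == 1
        n_aff, n_unaff = int(aff.sum()), int((~aff).sum())
        if tn is None:
            p_unaff = 1.0 / ratio
        else:
            p_unaff = tn / (ratio * n_aff + n_unaff)
        p_aff = min(1.0, ratio * p_unaff)
        p_unaff = min(1.0, p_unaff)
        u = rng.random(len(rec))
        keep = np.where(aff, u < p_aff, u < p_unaff)
        out = rec.loc[keep].reset_index(drop=True)
    elif isinstance(policy, str) and policy == "affected_proband":
        aff_fams = set(rec.loc[rec["breast_event"] == 1, "family_id"])
        out = rec[rec["family_id"].isin(aff_fams)].reset_index(drop=True)
        out["proband"] = False
        diag = out["diagnosis_age"].where(out["breast_event"] == 1, np.inf)
        idx = diag.groupby(out["family_id"]).idxmin()
        out.loc[idx, "proband"] = True
    else:
        raise ValueError(f"unknown ascertainment policy {policy!r}")
    if len(out) == 0:
        raise ValueError("ascertainment removed every record")
    return out


def simulate_null_sibship_genotypes(family_labels, n_snps: int, maf: float = 0.3, seed: int = 0):
    """Null-SNP dosage matrix preserving sibship genotype correlation.

    For calibration studies: draws ``n_snps`` independent SNPs for a cohort
    whose rows are grouped into sibships by ``family_labels`` (members of a
    group share two implicit HWE parents; singleton groups are draws from
    HWE directly).  Genotypes are independent of any phenotype — the
    resampling null for a family-structured cohort, where shuffling
    individuals would instead destroy the within-family correlation.

    Returns an (n, n_snps) float array.
    """
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must lie in (0,1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(family_labels)
    fams, fam_idx = np.unique(labels, return_inverse=True)
    father = rng.binomial(2, maf, size=(fams.size, n_snps)).astype(float)
    mother = rng.binomial(2, maf, size=(fams.size, n_snps)).astype(float)
    n = labels.size
    return (
        (rng.random((n, n_snps)) < father[fam_idx] / 2.0).astype(float)
        + (rng.random((n, n_snps)) < mother[fam_idx] / 2.0)
    )


def simulate_cohort(config: SyntheticConfig):
    """Convenience wrapper: families -> phenotypes -> ascertainment.

    Returns (records, GenotypeMatrix, pedigree) with records already
    subsampled by the configured ascertainment policy and the genotype
    matrix restricted to the retained cohort.
    """
    gm, pedigree = simulate_families(config)
    records = simulate_phenotypes(gm, config)
    records = apply_ascertainment(
        records, config.ascertainment_policy, seed=config.seed + 1
    )
    keep = records["sample_id"].tolist()
    gm_cohort = GenotypeMatrix(
        gm.dosages.loc[keep],
        snps=gm.snps,
        samples=gm.samples[gm.samples["sample_id"].isin(set(keep))].reset_index(drop=True),
        true_dosages=gm.true_dosages.loc[keep],
    )
    return records, gm_cohort, pedigree
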