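"""Incidence-constrained retrospective-likelihood survival model.

Carriers of high-penetrance mutations are recruited through clinics, where
testing targets women already diagnosed — sampling is outcome dependent, and
a prospective analysis (e.g. Cox partial likelihood) of such a cohort is
biased.  The retrospective likelihood conditions the other way round: it
models the probability of each carrier's *genotype* given her phenotype,

    L_i = p_g * h_g(t_i)^δ_i * S_g(t_i) / Σ_g' p_g' h_g'(t_i)^δ_i S_g'(t_i),

which is invariant to any sampling scheme that depends on phenotype alone.

The per-genotype hazards follow a proportional-hazards model
h_g(t) = h0(t)·exp(β·g) whose baseline is *not* free: it is constrained so
that the genotype-averaged hazard reproduces a supplied carrier incidence
curve λ̄(t) at every age.  Association is tested with the 1-df score test of
the retrospective likelihood at β=0; because relatives share alleles, the
score variance is corrected with pedigree kinship coefficients.

Follow-up runs to the first of: disease diagnosis, a competing diagnosis,
prophylactic surgery, or last observation; only the modelled disease counts
as an event (δ=1), everything else censors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .incidence import IncidenceCurve

__all__ = [
    "HazardModel",
    "SNPAssociationResult",
    "hwe_probs",
    "constrained_baseline",
    "retrospective_loglik",
    "score_test",
    "score_test_batch",
    "fit_per_allele",
    "fit_genotype_specific",
    "genotype_age_interaction_test",
    "country_heterogeneity_test",
    "exclude_prevalent",
    "wald_ci_from_hr_p",
]

BASELINE_TOL = 1e-8
BASELINE_MAX_ITER = 100
BETA_BOUNDS = (-3.0, 3.0)


def hwe_probs(q: float) -> np.ndarray:
    """Genotype probabilities ((1-q)^2, 2q(1-q), q^2) under HWE."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"allele frequency must lie in (0,1), got {q}")
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


@dataclass
class HazardModel:
    """Constrained proportional-hazards model over discrete risk classes.

    The classes are usually the three genotypes 0/1/2 with log relative
    risks (0, β, 2β), but any discrete mixture works (genotype-specific
    effects, multilocus risk profiles, age-varying log-HR).

    ``log_rr`` has shape (G,) for age-constant effects or (G, n_bins) for
    age-varying ones.  ``baseline`` is the solved h0 per one-year age bin.
    The defining invariant: Σ_g p_g h_g(t) S_g(t) / Σ_g p_g S_g(t) = λ̄(t)
    at every bin start.
    """

    curve: IncidenceCurve
    probs: np.ndarray
    log_rr: np.ndarray
    baseline: np.ndarray
    n_iter: int = 0

    @property
    def multipliers(self) -> np.ndarray:
        """Relative risk per class and age bin, shape (G, n_bins)."""
        lr = np.asarray(self.log_rr, dtype=float)
        if lr.ndim == 1:
            lr = lr[:, None] * np.ones(self.baseline.size)[None, :]
        return np.exp(lr)

    def class_cum_hazard_grid(self) -> np.ndarray:
        """H_g at bin starts, shape (G, n_bins)."""
        per_bin = self.multipliers * self.baseline[None, :]
        cum = np.cumsum(per_bin, axis=1)
        return np.concatenate([np.zeros((cum.shape[0], 1)), cum[:, :-1]], axis=1)

    def class_cum_hazard(self, t) -> np.ndarray:
        """H_g(t_i), shape (G, n)."""
        c = self.curve
        t = np.clip(np.asarray(t, dtype=float), c.age_start, c.age_end)
        idx = np.clip(np.searchsorted(c.ages, t, side="right") - 1, 0, c.ages.size - 1)
        frac = np.clip(t - c.ages[idx], 0.0, 1.0)
        grid = self.class_cum_hazard_grid()
        per_bin = self.multipliers * self.baseline[None, :]
        return grid[:, idx] + frac[None, :] * per_bin[:, idx]

    def class_survival(self, t) -> np.ndarray:
        return np.exp(-self.class_cum_hazard(t))

    def mixture_survival(self, t) -> np.ndarray:
        """Population-average survival Σ_g p_g S_g(t)."""
        return self.probs @ self.class_survival(t)


def constrained_baseline(
    incidence: IncidenceCurve,
    probs,
    log_rr,
    tol: float = BASELINE_TOL,
    max_iter: int = BASELINE_MAX_ITER,
) -> HazardModel:
    """Solve for the baseline hazard h0 matching the incidence constraint.

    Fixed-point iteration:
        h0 <- λ̄(t) · [Σ_g p_g S_g(t)] / [Σ_g p_g m_g(t) S_g(t)]
    with S_g recomputed from the current h0 each pass (survival evaluated at
    bin starts; left-Riemann convention).  With β=0 this returns h0 = λ̄
    exactly in one pass.

    Raises ``RuntimeError`` with the iteration trace on non-convergence.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must be a simplex vector")
    lam = incidence.hazard
    n_bins = lam.size
    lr = np.asarray(log_rr, dtype=float)
    if lr.ndim == 1:
        mult = np.exp(lr)[:, None] * np.ones(n_bins)[None, :]
    else:
        if lr.shape != (probs.size, n_bins):
            raise ValueError("age-varying log_rr must have shape (G, n_bins)")
        mult = np.exp(lr)
    if mult.shape[0] != probs.size:
        raise ValueError("log_rr and probs disagree on the number of classes")

    h0 = lam.copy()
    trace = []
    for it in range(1, max_iter + 1):
        per_bin = mult * h0[None, :]
        cum = np.cumsum(per_bin, axis=1)
        h_grid = np.concatenate([np.zeros((mult.shape[0], 1)), cum[:, :-1]], axis=1)
        s_grid = np.exp(-h_grid)
        num = probs @ s_grid
        den = probs @ (mult * s_grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            h_new = np.where(den > 0, lam * num / den, 0.0)
        delta = float(np.max(np.abs(h_new - h0)))
        trace.append(delta)
        h0 = h_new
        if delta < tol:
            return HazardModel(incidence, probs, np.asarray(log_rr, float), h0, it)
    raise RuntimeError(
        f"constrained baseline did not converge in {max_iter} iterations; "
        f"trace={trace[-5:]}"
    )


def _clamp_ages(t, curve: IncidenceCurve) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out_of_range = (t < curve.age_start) | (t > curve.age_end)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(out_of_range.sum())} follow-up ages outside "
            f"[{curve.age_start:g}, {curve.age_end:g}] clamped to the grid",
            stacklevel=3,
        )
    return np.clip(t, curve.age_start, curve.age_end)


def retrospective_loglik(t, delta, g, model: HazardModel) -> float:
    """Total retrospective log-likelihood of genotypes given phenotypes.

    ``g`` indexes the model's risk classes (0/1/2 genotypes in the usual
    case); missing genotypes (negative or NaN) are dropped.  The baseline
    h0(t)^δ factor is common to the numerator and every denominator term
    and cancels, so only the relative risks enter.
    """
    t = np.asarray(t, dtype=float)
    delta = np.asarray(delta, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = np.isfinite(g) & (g >= 0)
    t, delta, g = t[keep], delta[keep], g[keep].astype(int)
    t = _clamp_ages(t, model.curve)

    c = model.curve
    idx = np.clip(np.searchsorted(c.ages, t, side="right") - 1, 0, c.ages.size - 1)
    mult = model.multipliers  # (G, n_bins)
    h_t = model.class_cum_hazard(t)  # (G, n)
    log_m = np.log(mult[:, idx])  # (G, n)
    # log of per-class unnormalised term, h0^δ dropped
    log_terms = np.log(model.probs)[:, None] + delta[None, :] * log_m - h_t
    m = log_terms.max(axis=0)
    log_den = m + np.log(np.exp(log_terms - m[None, :]).sum(axis=0))
    log_num = log_terms[g, np.arange(g.size)]
    return float(np.sum(log_num - log_den))


# ---------------------------------------------------------------------------
# Score test
# ---------------------------------------------------------------------------


def _resolve_curves(incidence, labels):
    if isinstance(incidence, dict):
        return {lab: incidence[lab] for lab in labels}
    return {lab: incidence for lab in labels}


def score_test(
    records: pd.DataFrame,
    dosages,
    incidence,
    kinship=None,
    strata: str | None = "stratum",
):
    """Kinship-adjusted 1-df score test of the retrospective likelihood.

    Per stratum s with allele frequency q̂_s (plain sample frequency, the
    MLE at the null) and residuals r_i = δ_i − Λ̄_s(t_i):

        U_s = Σ_i (g_i − 2 q̂_s) r_i
        V_s = 2 q̂_s (1 − q̂_s) Σ_i Σ_j 2φ_ij r_i r_j     (2φ_ii = 1)

    U = Σ_s U_s, V = Σ_s V_s, χ² = U²/V with a 1-df chi-square p-value.
    U is the analytic derivative of the constrained retrospective
    log-likelihood at β = 0 — the baseline-derivative terms cancel — which
    the test suite verifies against numeric differentiation.

    ``kinship`` is a :class:`~carriermod.pio.KinshipModel` (or None for an
    unrelated cohort); missing dosages (NaN or negative) drop the carrier
    for this SNP only.
    """
    g = np.asarray(dosages, dtype=float)
    t = records["censor_age"].to_numpy(float)
    delta = records["breast_event"].to_numpy(float)
    sample_ids = records["sample_id"].to_numpy()
    labels = (
        records[strata].to_numpy()
        if strata is not None and strata in records.columns
        else np.zeros(len(records), dtype=int)
    )
    curves = _resolve_curves(incidence, np.unique(labels))

    U = 0.0
    V = 0.0
    for lab in np.unique(labels):
        sel = np.flatnonzero((labels == lab) & np.isfinite(g) & (g >= 0))
        if sel.size == 0:
            continue
        gs = g[sel]
        q = gs.mean() / 2.0
        if not 0.0 < q < 1.0:
            warnings.warn(f"stratum {lab!r} monomorphic; contributes 0 to the score")
            continue
        curve = curves[lab]
        ts = _clamp_ages(t[sel], curve)
        r = delta[sel] - curve.cum_hazard(ts)
        U += float(np.sum((gs - 2 * q) * r))
        quad = float(np.sum(r * r))
        if kinship is not None:
            ii, jj, two_phi = kinship.pairs_for(sample_ids[sel])
            quad += 2.0 * float(np.sum(two_phi * r[ii] * r[jj]))
        V += 2 * q * (1 - q) * quad
    if V <= 0:
        raise ValueError("degenerate cohort: score variance is non-positive")
    chi2 = U * U / V
    p = float(stats.chi2.sf(chi2, df=1))
    return U, V, chi2, p


def score_test_batch(
    records: pd.DataFrame,
    dosage_matrix,
    incidence,
    kinship=None,
    strata: str | None = "stratum",
    chunk: int = 512,
):
    """Vectorised :func:`score_test` over the columns of a dosage matrix.

    Returns a DataFrame with columns U, V, chi2, p (one row per SNP).
    Missing dosages are handled per SNP exactly as in ``score_test``.
    """
    G = np.asarray(dosage_matrix, dtype=float)
    if G.ndim != 2:
        raise ValueError("dosage_matrix must be samples x SNPs")
    n, n_snps = G.shape
    t = records["censor_age"].to_numpy(float)
    delta = records["breast_event"].to_numpy(float)
    sample_ids = records["sample_id"].to_numpy()
    labels = (
        records[strata].to_numpy()
        if strata is not None and strata in records.columns
        else np.zeros(n, dtype=int)
    )
    curves = _resolve_curves(incidence, np.unique(labels))

    U = np.zeros(n_snps)
    V = np.zeros(n_snps)
    for lab in np.unique(labels):
        sel = np.flatnonzero(labels == lab)
        curve = curves[lab]
        ts = np.clip(t[sel], curve.age_start, curve.age_end)
        r_full = delta[sel] - curve.cum_hazard(ts)
        Gs = G[sel, :]
        valid = np.isfinite(Gs) & (Gs >= 0)
        Gz = np.where(valid, Gs, 0.0)
        n_valid = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = Gz.sum(axis=0) / (2.0 * np.maximum(n_valid, 1))
        ok = (q > 0) & (q < 1) & (n_valid > 0)
        R = valid * r_full[:, None]  # residuals, zeroed where missing
        U_lab = (Gz * R).sum(axis=0) - 2 * q * R.sum(axis=0)
        quad = (R * R).sum(axis=0)
        if kinship is not None:
            ii, jj, two_phi = kinship.pairs_for(sample_ids[sel])
            if ii.size:
                for lo in range(0, n_snps, chunk):
                    hi = min(lo + chunk, n_snps)
                    quad[lo:hi] += 2.0 * (
                        two_phi[:, None] * R[ii, lo:hi] * R[jj, lo:hi]
                    ).sum(axis=0)
        U += np.where(ok, U_lab, 0.0)
        V += np.where(ok, 2 * q * (1 - q) * quad, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, U * U / V, np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return pd.DataFrame({"U": U, "V": V, "chi2": chi2, "p": p})


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class SNPAssociationResult:
    """Per-SNP association summary from the retrospective likelihood."""

    snp: str = ""
    n_affected: int = 0
    n_unaffected: int = 0
    maf: float = np.nan
    maf_unaffected: float = np.nan
    beta: float = np.nan
    se: float = np.nan
    hr: float = np.nan
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    score_u: float = np.nan
    score_v: float = np.nan
    score_chi2: float = np.nan
    p: float = np.nan
    loglik: float = np.nan
    at_bound: bool = False
    # genotype-specific (heterozygote / homozygote vs common homozygote)
    beta_het: float = np.nan
    se_het: float = np.nan
    beta_hom: float = np.nan
    se_hom: float = np.nan

    @property
    def hr_het(self) -> float:
        return float(np.exp(self.beta_het))

    @property
    def hr_hom(self) -> float:
        return float(np.exp(self.beta_hom))


def _prepare(records, dosages, strata):
    g = np.asarray(dosages, dtype=float)
    keep = np.isfinite(g) & (g >= 0)
    rec = records.loc[keep].reset_index(drop=True)
    g = g[keep]
    labels = (
        rec[strata].to_numpy()
        if strata is not None and strata in rec.columns
        else np.zeros(len(rec), dtype=int)
    )
    return rec, g, labels


@dataclass
class _StratumData:
    """Precomputed per-stratum arrays for repeated likelihood evaluation."""

    label: object
    curve: IncidenceCurve
    g: np.ndarray  # int genotype classes
    delta: np.ndarray
    bin_idx: np.ndarray
    frac: np.ndarray
    q_naive: float


def _split_strata(rec, g, labels, curves) -> list[_StratumData]:
    out = []
    for lab in np.unique(labels):
        sel = labels == lab
        gs = g[sel]
        q = gs.mean() / 2.0
        if not 0.0 < q < 1.0:
            continue  # monomorphic stratum carries no genotype information
        curve = curves[lab]
        t = _clamp_ages(rec.loc[sel, "censor_age"].to_numpy(float), curve)
        idx = np.clip(
            np.searchsorted(curve.ages, t, side="right") - 1, 0, curve.ages.size - 1
        )
        frac = np.clip(t - curve.ages[idx], 0.0, 1.0)
        out.append(
            _StratumData(
                lab,
                curve,
                gs.astype(int),
                rec.loc[sel, "breast_event"].to_numpy(float),
                idx,
                frac,
                q,
            )
        )
    return out


def _stratum_loglik(sd: _StratumData, log_rr, q: float) -> float:
    """Retrospective loglik of one stratum at class effects log_rr, freq q."""
    model = constrained_baseline(sd.curve, hwe_probs(q), log_rr)
    mult = model.multipliers
    per_bin = mult * model.baseline[None, :]
    cum = np.cumsum(per_bin, axis=1)
    h_grid = np.concatenate([np.zeros((mult.shape[0], 1)), cum[:, :-1]], axis=1)
    H = h_grid[:, sd.bin_idx] + sd.frac[None, :] * per_bin[:, sd.bin_idx]
    log_m = np.log(mult[:, sd.bin_idx])
    log_terms = np.log(model.probs)[:, None] + sd.delta[None, :] * log_m - H
    m = log_terms.max(axis=0)
    log_den = m + np.log(np.exp(log_terms - m[None, :]).sum(axis=0))
    return float(np.sum(log_terms[sd.g, np.arange(sd.g.size)] - log_den))


_Q_BOUNDS = (1e-4, 1 - 1e-4)


def _stratified_loglik(strata_data, log_rr_fn, profile_q: bool = True) -> float:
    """Σ_s retrospective loglik with per-stratum allele frequency.

    ``log_rr_fn(curve)`` returns the (G,) or (G, n_bins) log relative
    risks.  With ``profile_q`` the stratum allele frequency is profiled out
    by an inner 1-d maximisation — under outcome-dependent sampling with a
    non-null effect the cohort allele frequency is phenotype-distorted, so
    plugging in the crude sample frequency would bias the effect estimate.
    With ``profile_q=False`` the naive sample frequency is used (exact at
    the null; this is the likelihood whose β-derivative the score test is).
    """
    total = 0.0
    for sd in strata_data:
        log_rr = log_rr_fn(sd.curve)
        if profile_q:
            opt = optimize.minimize_scalar(
                lambda q: -_stratum_loglik(sd, log_rr, q),
                bounds=_Q_BOUNDS,
                method="bounded",
                options={"xatol": 1e-6},
            )
            total -= float(opt.fun)
        else:
            total += _stratum_loglik(sd, log_rr, sd.q_naive)
    return total


def fit_per_allele(
    records: pd.DataFrame,
    dosages,
    incidence,
    strata: str | None = "stratum",
    kinship=None,
    snp: str = "",
    profile_q: bool = True,
) -> SNPAssociationResult:
    """Per-allele (log-additive) HR by maximising the retrospective likelihood.

    The baseline is re-constrained to the incidence curve at every β, and
    the stratum allele frequencies are profiled out alongside β (the
    ascertained cohort's crude frequency is phenotype-distorted away from
    the null).  SE from the numeric second derivative of the profile
    likelihood at the optimum; 95% CI is Wald on the log scale.  An optimum
    at the search bound (|β̂| = 3) is flagged and the CI suppressed.
    """
    rec, g, labels = _prepare(records, dosages, strata)
    curves = _resolve_curves(incidence, np.unique(labels))
    strata_data = _split_strata(rec, g, labels, curves)

    def nll(beta: float) -> float:
        return -_stratified_loglik(
            strata_data, lambda c: np.array([0.0, beta, 2 * beta]), profile_q=profile_q
        )

    opt = optimize.minimize_scalar(
        nll, bounds=BETA_BOUNDS, method="bounded", options={"xatol": 1e-8}
    )
    beta = float(opt.x)
    at_bound = min(beta - BETA_BOUNDS[0], BETA_BOUNDS[1] - beta) < 1e-4
    h = 1e-3
    d2 = (nll(beta + h) - 2 * opt.fun + nll(beta - h)) / h**2
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan

    res = SNPAssociationResult(
        snp=snp,
        n_affected=int(rec["breast_event"].sum()),
        n_unaffected=int((1 - rec["breast_event"]).sum()),
        maf=float(g.mean() / 2),
        maf_unaffected=float(g[rec["breast_event"].to_numpy() == 0].mean() / 2)
        if (rec["breast_event"] == 0).any()
        else np.nan,
        beta=beta,
        se=se,
        hr=float(np.exp(beta)),
        loglik=-float(opt.fun),
        at_bound=at_bound,
    )
    if not at_bound and np.isfinite(se):
        res.ci_lo = float(np.exp(beta - 1.96 * se))
        res.ci_hi = float(np.exp(beta + 1.96 * se))
    u, v, chi2, p = score_test(rec, g, incidence, kinship=kinship, strata=strata)
    res.score_u, res.score_v, res.score_chi2, res.p = u, v, chi2, p
    return res


def fit_genotype_specific(
    records: pd.DataFrame,
    dosages,
    incidence,
    strata: str | None = "stratum",
    kinship=None,
    snp: str = "",
    profile_q: bool = True,
) -> SNPAssociationResult:
    """Genotype-specific HRs: free (β₁, β₂) for the het and rare-hom classes."""
    rec, g, labels = _prepare(records, dosages, strata)
    curves = _resolve_curves(incidence, np.unique(labels))
    strata_data = _split_strata(rec, g, labels, curves)
    have_hom = bool(np.any(g == 2))

    def nll(b):
        b1, b2 = b
        return -_stratified_loglik(
            strata_data, lambda c: np.array([0.0, b1, b2]), profile_q=profile_q
        )

    start = fit_per_allele(rec, g, incidence, strata=strata, snp=snp, profile_q=profile_q)
    x0 = np.array([start.beta, 2 * start.beta])
    opt = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8})
    b1, b2 = map(float, opt.x)
    h = 1e-3
    f0 = opt.fun

    def d2(i):
        e = np.zeros(2)
        e[i] = h
        return (nll(opt.x + e) - 2 * f0 + nll(opt.x - e)) / h**2

    res = SNPAssociationResult(
        snp=snp,
        n_affected=start.n_affected,
        n_unaffected=start.n_unaffected,
        maf=start.maf,
        maf_unaffected=start.maf_unaffected,
        beta=start.beta,
        se=start.se,
        hr=start.hr,
        ci_lo=start.ci_lo,
        ci_hi=start.ci_hi,
        score_u=start.score_u,
        score_v=start.score_v,
        score_chi2=start.score_chi2,
        p=start.p,
        loglik=-float(f0),
        beta_het=b1,
        se_het=float(1 / np.sqrt(d2(0))) if d2(0) > 0 else np.nan,
    )
    if have_hom:
        res.beta_hom = b2
        v = d2(1)
        res.se_hom = float(1 / np.sqrt(v)) if v > 0 else np.nan
    return res


def genotype_age_interaction_test(
    records: pd.DataFrame,
    dosages,
    incidence,
    strata: str | None = "stratum",
    profile_q: bool = True,
):
    """LRT for a genotype-by-age interaction (proportional-hazards check).

    The log-HR is modelled as β(t) = β0 + β1·(t−50)/10 per allele; the test
    compares the free (β0, β1) fit against β1 = 0 with 1 df.
    Returns (chi2, p, beta0_hat, beta1_hat).
    """
    rec, g, labels = _prepare(records, dosages, strata)
    curves = _resolve_curves(incidence, np.unique(labels))
    strata_data = _split_strata(rec, g, labels, curves)

    def log_rr_fn_factory(b0, b1):
        def f(curve):
            z = (curve.ages + 0.5 - 50.0) / 10.0  # bin midpoints
            beta_t = b0 + b1 * z
            return np.arange(3)[:, None] * beta_t[None, :]

        return f

    def nll(b):
        return -_stratified_loglik(strata_data, log_rr_fn_factory(*b), profile_q=profile_q)

    base = fit_per_allele(rec, g, incidence, strata=strata, profile_q=profile_q)
    opt0_fun = -base.loglik
    opt = optimize.minimize(
        nll,
        np.array([base.beta, 0.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8},
    )
    chi2 = max(0.0, 2.0 * (opt0_fun - float(opt.fun)))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, float(opt.x[0]), float(opt.x[1])


def country_heterogeneity_test(
    records: pd.DataFrame,
    dosages,
    incidence,
    strata: str | None = "stratum",
    profile_q: bool = True,
):
    """LRT of a common per-allele β against stratum-specific β's.

    df = (#strata with genotype variation) − 1; with a single stratum the
    test is vacuous and returns (0, 0, 1).  Returns (chi2, df, p).
    """
    rec, g, labels = _prepare(records, dosages, strata)
    curves = _resolve_curves(incidence, np.unique(labels))
    common = fit_per_allele(rec, g, incidence, strata=strata, profile_q=profile_q)
    ll_het = 0.0
    df = -1
    for lab in np.unique(labels):
        sel = labels == lab
        if not 0.0 < g[sel].mean() / 2 < 1.0:
            continue
        sub = fit_per_allele(
            rec.loc[sel].reset_index(drop=True), g[sel], curves[lab], strata=None,
            profile_q=profile_q,
        )
        ll_het += sub.loglik
        df += 1
    if df <= 0:
        return 0.0, 0, 1.0
    chi2 = max(0.0, 2.0 * (ll_het - common.loglik))
    return chi2, df, float(stats.chi2.sf(chi2, df=df))


def exclude_prevalent(records: pd.DataFrame, window_years: float = 5.0) -> pd.DataFrame:
    """Drop affected carriers diagnosed ≥ ``window_years`` before recruitment.

    Long-prevalent cases must have survived their disease to be recruited, a
    potential survival bias; this sensitivity filter removes them.  Records
    lacking a recruitment age are kept with a warning; unaffected carriers
    are never dropped.
    """
    rec = records.reset_index(drop=True)
    affected = rec["breast_event"].to_numpy(float) == 1
    recru = rec.get("recruitment_age", pd.Series(np.nan, index=rec.index)).to_numpy(float)
    diag = rec.get("diagnosis_age", pd.Series(np.nan, index=rec.index)).to_numpy(float)
    missing = affected & ~(np.isfinite(recru) & np.isfinite(diag))
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} affected records lack recruitment or diagnosis "
            "age; kept in the prevalent-case filter"
        )
    with np.errstate(invalid="ignore"):
        prevalent = affected & np.isfinite(recru) & np.isfinite(diag) & (
            recru - diag >= window_years
        )
    return rec.loc[~prevalent].reset_index(drop=True)


def wald_ci_from_hr_p(hr: float, p_two_sided: float) -> tuple[float, float]:
    """Reconstruct a Wald 95% CI from a printed HR and two-sided p-value.

    Inverts z = Φ⁻¹(1 − p/2), SE = |ln HR|/z, bounds = exp(ln HR ∓ 1.96·SE).
    Degenerate at HR = 1 with p < 1 (no information on the SE): returns
    (1, 1) with a warning.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0.0 < p_two_sided <= 1.0:
        raise ValueError("p-value must lie in (0, 1]")
    if hr == 1.0:
        if p_two_sided < 1.0:
            warnings.warn("HR = 1 with p < 1 is degenerate; returning (1, 1)")
        return (1.0, 1.0)
    z = stats.norm.isf(p_two_sided / 2.0)
    if z <= 0:
        warnings.warn("p-value too large to recover a standard error")
        return (np.nan, np.nan)
    se = abs(np.log(hr)) / z
    return (
        float(np.exp(np.log(hr) - 1.96 * se)),
        float(np.exp(np.log(hr) + 1.96 * se)),
    )
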