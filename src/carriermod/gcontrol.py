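"""Genomic-control inflation diagnostics for batches of 1-df score tests.

λ is the median observed chi-square divided by the 1-df chi-square median
(≈0.4549); systematic inflation from structure or miscalibration moves the
bulk of the distribution, and hence the median, while a handful of true
associations does not.  Because λ grows with sample size for a fixed level
of confounding, λ is also standardised to a notional 1000 affected / 1000
unaffected ("λ₁₀₀₀") for comparability across studies.  No correction is
applied to p-values here — these are diagnostics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.454936...


def lambda_gc(chi2_values) -> float:
    """Genomic inflation factor: median(χ²) / median of χ²₁."""
    chi2_values = np.asarray(chi2_values, dtype=float)
    chi2_values = chi2_values[np.isfinite(chi2_values)]
    if chi2_values.size == 0:
        raise ValueError("no chi-square statistics supplied")
    return float(np.median(chi2_values) / CHI2_1DF_MEDIAN)


def lambda_1000(lam: float, n_affected: int, n_unaffected: int) -> float:
    """λ rescaled to 1000 affected and 1000 unaffected samples.

    λ₁₀₀₀ = 1 + (λ − 1) · (1/n_aff + 1/n_unaff) / (1/1000 + 1/1000).
    """
    if n_affected <= 0 or n_unaffected <= 0:
        raise ValueError("group sizes must be positive")
    scale = (1.0 / n_affected + 1.0 / n_unaffected) / (2.0 / 1000.0)
    return float(1.0 + (lam - 1.0) * scale)


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed −log₁₀ p for a QQ plot.

    Expected quantiles are the medians of uniform order statistics,
    Beta(k, n+1−k) medians — exact, not the (k−1/2)/n approximation, so a
    single p-value of 1 maps to expected −log₁₀(0.5) ≈ 0.301.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = p.size
    if n == 0:
        return pd.DataFrame({"expected": [], "observed": []})
    k = np.arange(1, n + 1)
    expected = stats.beta.ppf(0.5, k, n + 1 - k)
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(p)}
    )


@dataclass
class GCReport:
    lam: float
    lam_1000: float
    n_affected: int
    n_unaffected: int
    qq: pd.DataFrame


def gc_report(chi2_values, n_affected: int, n_unaffected: int) -> GCReport:
    """Bundle λ, λ₁₀₀₀ and the QQ table for a batch of score tests."""
    lam = lambda_gc(chi2_values)
    pvals = stats.chi2.sf(np.asarray(chi2_values, dtype=float), df=1)
    return GCReport(
        lam=lam,
        lam_1000=lambda_1000(lam, n_affected, n_unaffected),
        n_affected=n_affected,
        n_unaffected=n_unaffected,
        qq=qq_data(pvals),
    )
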