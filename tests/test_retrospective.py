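"""Core model: constrained baseline, retrospective likelihood, score test."""

import math

import numpy as np
import pandas as pd
import pytest

import carriermod as cm
from carriermod.incidence import IncidenceCurve
from carriermod.retrospective import (
    _prepare,
    _resolve_curves,
    _split_strata,
    _stratified_loglik,
)


class TestConstrainedBaseline:
    def test_null_effect_recovers_input_hazard(self, flat_curve):
        m = cm.constrained_baseline(flat_curve, cm.hwe_probs(0.35), np.zeros(3))
        np.testing.assert_allclose(m.baseline, flat_curve.hazard)

    def test_first_year_closed_form(self, flat_curve):
        # with S≈1 in year one, h0 = λ / Σ p_g e^{βg} = 0.01 / 2.25
        m = cm.constrained_baseline(
            flat_curve, cm.hwe_probs(0.5), np.array([0.0, math.log(2), 2 * math.log(2)])
        )
        assert m.baseline[0] == pytest.approx(0.01 / 2.25, rel=1e-12)

    @pytest.mark.parametrize("q,beta", [(0.1, -0.5), (0.35, math.log(0.85)), (0.5, 1.0)])
    def test_mixture_hazard_invariant(self, flat_curve, q, beta):
        """Genotype-averaged hazard equals the target curve at every age."""
        m = cm.constrained_baseline(flat_curve, cm.hwe_probs(q), np.array([0, beta, 2 * beta]))
        s_grid = np.exp(-m.class_cum_hazard_grid())
        lam_hat = (m.probs @ (m.multipliers * m.baseline[None, :] * s_grid)) / (
            m.probs @ s_grid
        )
        assert np.max(np.abs(lam_hat - flat_curve.hazard)) < 1e-8

    def test_invalid_probs_rejected(self, flat_curve):
        with pytest.raises(ValueError):
            cm.constrained_baseline(flat_curve, np.array([0.5, 0.6]), np.zeros(2))


class TestRetrospectiveLoglik:
    def test_null_contribution_is_log_genotype_prob(self, flat_curve):
        m = cm.constrained_baseline(flat_curve, cm.hwe_probs(0.35), np.zeros(3))
        ll = cm.retrospective_loglik(np.array([47.3]), np.array([1.0]), np.array([1]), m)
        assert ll == pytest.approx(math.log(0.455), abs=1e-12)

    def test_null_total_is_phenotype_independent(self, flat_curve, five_carrier_records,
                                                 five_carrier_dosages):
        m = cm.constrained_baseline(flat_curve, cm.hwe_probs(0.35), np.zeros(3))
        rec = five_carrier_records
        ll = cm.retrospective_loglik(
            rec["censor_age"].to_numpy(), rec["breast_event"].to_numpy(),
            five_carrier_dosages, m,
        )
        probs = cm.hwe_probs(0.35)
        expected = sum(math.log(probs[int(g)]) for g in five_carrier_dosages)
        assert ll == pytest.approx(expected, abs=1e-10)
        # phenotypes permuted: identical at the null
        ll2 = cm.retrospective_loglik(
            rec["censor_age"].to_numpy()[::-1], rec["breast_event"].to_numpy()[::-1],
            five_carrier_dosages, m,
        )
        assert ll2 == pytest.approx(ll, abs=1e-12)

    def test_matches_brute_force_enumeration(self, flat_curve, five_carrier_records,
                                             five_carrier_dosages):
        """Independent per-carrier evaluation of the normalised ratio."""
        q, beta = 0.35, math.log(0.8)
        m = cm.constrained_baseline(flat_curve, cm.hwe_probs(q), np.array([0, beta, 2 * beta]))
        probs = cm.hwe_probs(q)
        h0 = m.baseline

        def brute_contribution(t, delta, g):
            terms = []
            for gg in range(3):
                rr = math.exp(beta * gg)
                # piecewise-constant cumulative hazard from scratch
                H = 0.0
                for b, a in enumerate(np.arange(20, 80)):
                    if t >= a + 1:
                        H += h0[b] * rr
                    elif t > a:
                        H += h0[b] * rr * (t - a)
                bin_idx = min(int(t) - 20, 59)
                hz = h0[bin_idx] * rr
                terms.append(probs[gg] * (hz ** delta) * math.exp(-H))
            return math.log(terms[int(g)] / sum(terms))

        expected = sum(
            brute_contribution(t, d, g)
            for t, d, g in zip(
                five_carrier_records["censor_age"],
                five_carrier_records["breast_event"],
                five_carrier_dosages,
            )
        )
        got = cm.retrospective_loglik(
            five_carrier_records["censor_age"].to_numpy(),
            five_carrier_records["breast_event"].to_numpy(),
            five_carrier_dosages,
            m,
        )
        assert got == pytest.approx(expected, abs=1e-9)


class TestScoreTest:
    def test_hand_worked_example(self, flat_curve):
        # two unrelated carriers, q̂=0.5, g=(2,0), δ=(1,0), Λ̄=(0.2,0.5)
        rec = pd.DataFrame(
            {"sample_id": ["a", "b"], "censor_age": [40.0, 70.0], "breast_event": [1, 0]}
        )
        u, v, chi2, p = cm.score_test(rec, np.array([2.0, 0.0]), flat_curve, strata=None)
        assert u == pytest.approx(1.3, abs=1e-12)
        assert v == pytest.approx(0.445, abs=1e-12)
        assert chi2 == pytest.approx(1.3**2 / 0.445, rel=1e-12)

    def test_analytic_score_equals_numeric_derivative(self):
        """The closed-form U is dℓ/dβ at β=0 of the constrained likelihood."""
        cfg = cm.SyntheticConfig(
            n_families=150, sibs_per_family=2, maf=0.3, per_allele_hr=1.4,
            ascertainment_policy="random", seed=5, n_strata=3,
        )
        rec, gm, _ = cm.simulate_cohort(cfg)
        g = gm.true_dosages.iloc[:, 0].to_numpy()
        u, _, _, _ = cm.score_test(rec, g, cfg.incidence, strata="stratum")
        r, gg, labels = _prepare(rec, g, "stratum")
        curves = _resolve_curves(cfg.incidence, np.unique(labels))
        sd = _split_strata(r, gg, labels, curves)

        def ll(b):
            return _stratified_loglik(
                sd, lambda c: np.array([0.0, b, 2 * b]), profile_q=False
            )

        h = 1e-5
        numeric = (ll(h) - ll(-h)) / (2 * h)
        assert abs(u - numeric) < 1e-6

    def test_duplicate_cohort_chi2_invariant(self, flat_curve):
        """Monozygotic duplication doubles U and V; χ² follows U²/V."""
        rng = np.random.default_rng(3)
        n = 120
        g = rng.binomial(2, 0.3, size=n).astype(float)
        rec = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "censor_age": rng.uniform(30, 75, n),
                "breast_event": rng.binomial(1, 0.3, n),
            }
        )
        u1, v1, chi1, _ = cm.score_test(rec, g, flat_curve, strata=None)
        # duplicate every carrier with identical genotype (2φ = 1)
        rec2 = pd.concat(
            [rec, rec.assign(sample_id=rec["sample_id"] + "_dup")], ignore_index=True
        )
        g2 = np.concatenate([g, g])
        ped = pd.DataFrame(
            {
                "family_id": [f"f{i}" for i in range(n)] * 2,
                "individual_id": rec2["sample_id"],
                "father_id": "0",
                "mother_id": "0",
                "sex": 2,
                "affection": 0,
            }
        )
        kin = cm.compute_kinship(ped)

        class MZ:
            """kinship with 2φ=1 within each duplicate pair"""

            def pairs_for(self, ids):
                ids = list(ids)
                pos = {s: i for i, s in enumerate(ids)}
                ii, jj = [], []
                for s in ids:
                    if not s.endswith("_dup") and s + "_dup" in pos:
                        ii.append(pos[s])
                        jj.append(pos[s + "_dup"])
                return np.array(ii), np.array(jj), np.ones(len(ii))

        u2, v2, chi2_, _ = cm.score_test(rec2, g2, flat_curve, kinship=MZ(), strata=None)
        assert u2 == pytest.approx(2 * u1, rel=1e-12)
        assert v2 == pytest.approx(4 * v1, rel=1e-9)
        assert chi2_ == pytest.approx(chi1, rel=1e-9)

    def test_sample_order_and_strata_label_invariance(self):
        cfg = cm.SyntheticConfig(
            n_families=200, sibs_per_family=2, maf=0.3, per_allele_hr=1.2,
            ascertainment_policy="random", seed=11, n_strata=3,
        )
        rec, gm, _ = cm.simulate_cohort(cfg)
        g = gm.true_dosages.iloc[:, 0].to_numpy()
        u, v, chi2, p = cm.score_test(rec, g, cfg.incidence, strata="stratum")
        perm = np.random.default_rng(0).permutation(len(rec))
        rec_p = rec.iloc[perm].reset_index(drop=True)
        u2, v2, chi2b, _ = cm.score_test(rec_p, g[perm], cfg.incidence, strata="stratum")
        assert chi2b == pytest.approx(chi2, rel=1e-9)
        rec_r = rec.copy()
        rec_r["stratum"] = "X" + rec_r["stratum"]
        u3, _, chi2c, _ = cm.score_test(rec_r, g, cfg.incidence, strata="stratum")
        assert chi2c == pytest.approx(chi2, rel=1e-9)

    def test_degenerate_cohort_raises(self, flat_curve):
        # zero residual (censored exactly at grid start) -> V = 0
        rec = pd.DataFrame(
            {"sample_id": ["a"], "censor_age": [20.0], "breast_event": [0]}
        )
        with pytest.raises(ValueError):
            cm.score_test(rec, np.array([1.0]), flat_curve, strata=None)


class TestFitting:
    def test_score_wald_lrt_agree_at_moderate_n(self):
        """The three classical tests agree near the null at large n."""
        cfg = cm.SyntheticConfig(
            n_families=2500, sibs_per_family=2, maf=0.35, per_allele_hr=1.0,
            ascertainment_policy="random", seed=21, n_strata=1,
        )
        rec, gm, _ = cm.simulate_cohort(cfg)
        g = gm.true_dosages.iloc[:, 0].to_numpy()
        res = cm.fit_per_allele(rec, g, cfg.incidence, strata="stratum")
        wald = (res.beta / res.se) ** 2
        null_ll = _stratified_loglik(
            _split_strata(*_prepare(rec, g, "stratum")[:3],
                          _resolve_curves(cfg.incidence, ["C0"])),
            lambda c: np.zeros(3),
            profile_q=True,
        )
        lrt = 2 * (res.loglik - null_ll)
        assert res.score_chi2 == pytest.approx(wald, rel=0.06, abs=0.05)
        assert lrt == pytest.approx(wald, rel=0.06, abs=0.05)

    def test_genotype_specific_nests_per_allele(self):
        cfg = cm.SyntheticConfig(
            n_families=800, sibs_per_family=2, maf=0.35, per_allele_hr=0.8,
            ascertainment_policy="random", seed=31, n_strata=1,
        )
        rec, gm, _ = cm.simulate_cohort(cfg)
        g = gm.true_dosages.iloc[:, 0].to_numpy()
        res = cm.fit_genotype_specific(rec, g, cfg.incidence, strata="stratum")
        # log-additive truth: β2 ≈ 2 β1 within 2 joint SEs
        se = math.hypot(2 * res.se_het, res.se_hom)
        assert abs(res.beta_hom - 2 * res.beta_het) < 2 * se
        # free fit can only improve the likelihood vs the nested model
        assert res.loglik >= cm.fit_per_allele(
            rec, g, cfg.incidence, strata="stratum"
        ).loglik - 1e-6

    def test_interaction_test_null_reduction(self):
        cfg = cm.SyntheticConfig(
            n_families=400, sibs_per_family=2, maf=0.3, per_allele_hr=0.8,
            ascertainment_policy="random", seed=41, n_strata=1,
        )
        rec, gm, _ = cm.simulate_cohort(cfg)
        g = gm.true_dosages.iloc[:, 0].to_numpy()
        chi2, p, b0, b1 = cm.genotype_age_interaction_test(rec, g, cfg.incidence,
                                                           strata="stratum")
        assert chi2 >= 0 and 0 < p <= 1
        # under proportional hazards the age term stays small
        assert abs(b1) < 0.5

    def test_single_stratum_heterogeneity_is_vacuous(self, flat_curve):
        rng = np.random.default_rng(2)
        n = 200
        rec = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "censor_age": rng.uniform(30, 75, n),
                "breast_event": rng.binomial(1, 0.3, n),
                "stratum": "only",
            }
        )
        g = rng.binomial(2, 0.3, n).astype(float)
        chi2, df, p = cm.country_heterogeneity_test(rec, g, flat_curve, strata="stratum")
        assert (chi2, df, p) == (0.0, 0, 1.0)


class TestExcludePrevalent:
    def test_window_boundary(self):
        rec = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "censor_age": [45.0, 45.0, 45.0, 60.0],
                "breast_event": [1, 1, 1, 0],
                "diagnosis_age": [45.0, 45.0, 45.0, np.nan],
                "recruitment_age": [51.0, 49.9, np.nan, 60.0],
            }
        )
        with pytest.warns(UserWarning):
            out = cm.exclude_prevalent(rec, window_years=5.0)
        kept = set(out["sample_id"])
        assert "a" not in kept      # 6 years prevalent: dropped
        assert "b" in kept          # 4.9 years: kept (strict >= rule)
        assert "c" in kept          # missing recruitment age: kept with warning
        assert "d" in kept          # unaffected: never dropped


class TestWaldCI:
    @pytest.mark.parametrize(
        "hr,p,lo,hi",
        [
            (0.85, 3.9e-8, 0.80, 0.90),
            (0.85, 3.6e-6, 0.79, 0.91),
        ],
    )
    def test_published_ci_reconstruction(self, hr, p, lo, hi):
        got_lo, got_hi = cm.wald_ci_from_hr_p(hr, p)
        assert round(got_lo, 2) == lo
        assert round(got_hi, 2) == hi

    def test_degenerate_unit_hr(self):
        with pytest.warns(UserWarning):
            assert cm.wald_ci_from_hr_p(1.0, 0.5) == (1.0, 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cm.wald_ci_from_hr_p(-1.0, 0.5)
        with pytest.raises(ValueError):
            cm.wald_ci_from_hr_p(0.85, 0.0)
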