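"""Synthetic cohort generator: genetics, onset model, ascertainment."""

import numpy as np
import pandas as pd
import pytest

import carriermod as cm


class TestSimulateFamilies:
    def test_founder_genotypes_follow_hwe(self):
        cfg = cm.SyntheticConfig(n_families=5000, sibs_per_family=1, maf=0.35, seed=1)
        gm, ped = cm.simulate_families(cfg)
        founders = gm.samples["role"] == "founder"
        g = gm.true_dosages.to_numpy()[founders.to_numpy(), 0]
        freqs = np.array([(g == k).mean() for k in range(3)])
        expect = np.array([0.4225, 0.455, 0.1225])
        se = np.sqrt(expect * (1 - expect) / g.size)
        assert np.all(np.abs(freqs - expect) < 4 * se)

    def test_sib_dosage_correlation_is_2phi(self):
        """Full sibs share alleles with kinship 1/4: dosage corr ≈ 0.5."""
        cfg = cm.SyntheticConfig(n_families=6000, sibs_per_family=2, maf=0.3, seed=2)
        gm, _ = cm.simulate_families(cfg)
        sibs = gm.samples.loc[gm.samples["role"] == "sib", "sample_id"]
        g = gm.true_dosages.loc[sibs].to_numpy()[:, 0]
        g1, g2 = g[0::2], g[1::2]
        corr = np.corrcoef(g1, g2)[0, 1]
        assert corr == pytest.approx(0.5, abs=3 / np.sqrt(len(g1)))

    def test_missing_rate_matches_target(self):
        cfg = cm.SyntheticConfig(
            n_families=1000, sibs_per_family=2, maf=0.3, n_snps=10,
            missing_rate=0.10, seed=3,
        )
        gm, _ = cm.simulate_families(cfg)
        frac = float(gm.dosages.isna().to_numpy().mean())
        n = gm.dosages.size
        assert frac == pytest.approx(0.10, abs=4 * np.sqrt(0.1 * 0.9 / n))

    def test_degenerate_maf_rejected(self):
        with pytest.raises(ValueError):
            cm.SyntheticConfig(maf=0.0)
        with pytest.raises(ValueError):
            cm.SyntheticConfig(maf=1.0)

    def test_same_seed_identical_output(self, tmp_path):
        outs = []
        for _ in range(2):
            cfg = cm.SyntheticConfig(
                n_families=50, sibs_per_family=(1, 3), maf=0.3, n_snps=5,
                per_allele_hr=0.8, missing_rate=0.05, seed=99,
            )
            rec, gm, ped = cm.simulate_cohort(cfg)
            p = tmp_path / f"g{len(outs)}.tsv"
            cm.write_genotypes(gm, p, {"seed": cfg.seed})
            outs.append((p.read_bytes(), rec.to_csv(), ped.to_csv()))
        assert outs[0] == outs[1]


class TestSimulatePhenotypes:
    def test_null_onset_matches_incidence_curve(self):
        """HR=1: empirical onset cumulative incidence tracks the input curve."""
        cfg = cm.SyntheticConfig(
            n_families=8000, sibs_per_family=1, maf=0.35, per_allele_hr=1.0,
            censor_age_mean=200.0, censor_age_sd=1.0,  # censor only at 80
            mastectomy_rate=0.0, seed=4,
        )
        gm, _ = cm.simulate_families(cfg)
        rec = cm.simulate_phenotypes(gm, cfg)
        # ignore ovarian censoring: count breast events by each age
        for age in (50.0, 80.0):
            expect = 1 - np.exp(-cfg.incidence.cum_hazard(age))
            # carriers whose breast onset occurred before `age`
            got = float(
                ((rec["breast_event"] == 1) & (rec["censor_age"] <= age)).mean()
            )
            # ovarian + mastectomy censoring pull the observed fraction down
            # by only a few percent (ovarian cumulative ~12%); allow for it
            assert got == pytest.approx(expect, abs=0.05)

    def test_pooled_incidence_invariant_under_effect(self):
        """Genotype effects leave the genotype-averaged incidence unchanged."""
        cfg = cm.SyntheticConfig(
            n_families=12000, sibs_per_family=1, maf=0.35, per_allele_hr=0.6,
            censor_age_mean=200.0, censor_age_sd=1.0, mastectomy_rate=0.0, seed=5,
        )
        cfg_null = cm.SyntheticConfig(
            n_families=12000, sibs_per_family=1, maf=0.35, per_allele_hr=1.0,
            censor_age_mean=200.0, censor_age_sd=1.0, mastectomy_rate=0.0, seed=5,
        )
        fracs = []
        for c in (cfg, cfg_null):
            gm, _ = cm.simulate_families(c)
            rec = cm.simulate_phenotypes(gm, c)
            fracs.append(
                ((rec["breast_event"] == 1) & (rec["censor_age"] <= 80)).mean()
            )
        se = np.sqrt(0.25 / 12000)
        assert fracs[0] == pytest.approx(fracs[1], abs=4 * se)

    def test_first_event_exclusivity(self):
        cfg = cm.SyntheticConfig(
            n_families=3000, sibs_per_family=2, maf=0.3, per_allele_hr=0.8, seed=6
        )
        gm, _ = cm.simulate_families(cfg)
        rec = cm.simulate_phenotypes(gm, cfg)
        assert ((rec["breast_event"] + rec["ovarian_event"]) <= 1).all()
        assert (rec["censor_age"] > 0).all()
        aff = rec["breast_event"] == 1
        np.testing.assert_allclose(
            rec.loc[aff, "diagnosis_age"], rec.loc[aff, "censor_age"]
        )


@pytest.fixture(scope="module")
def records():
    cfg = cm.SyntheticConfig(
        n_families=4000, sibs_per_family=2, maf=0.3, per_allele_hr=1.0, seed=7
    )
    gm, _ = cm.simulate_families(cfg)
    return cm.simulate_phenotypes(gm, cfg)


class TestAscertainment:
    def test_random_policy_preserves_affected_fraction(self, records):
        out = cm.apply_ascertainment(records, "random", seed=1, target_n=4000)
        se = np.sqrt(0.25 / 4000)
        assert out["breast_event"].mean() == pytest.approx(
            records["breast_event"].mean(), abs=4 * se
        )

    def test_oversampling_enriches_to_odds_formula(self, records):
        """retained affected fraction = r·a / (r·a + (1−a))."""
        out = cm.apply_ascertainment(records, ("oversample_affected", 3.0), seed=2)
        a = records["breast_event"].mean()
        expect = 3 * a / (3 * a + (1 - a))
        se = np.sqrt(expect * (1 - expect) / len(out))
        assert out["breast_event"].mean() == pytest.approx(expect, abs=4 * se)

    def test_oversampling_hits_target_size(self, records):
        out = cm.apply_ascertainment(
            records, ("oversample_affected", 3.0, 2000), seed=3
        )
        assert abs(len(out) - 2000) < 4 * np.sqrt(2000)

    def test_affected_proband_families_all_contain_a_case(self, records):
        out = cm.apply_ascertainment(records, "affected_proband", seed=4)
        per_fam = out.groupby("family_id")["breast_event"].sum()
        assert (per_fam >= 1).all()
        assert out.groupby("family_id")["proband"].sum().eq(1).all()

    def test_empty_selection_raises(self, records):
        unaffected_only = records[records["breast_event"] == 0].head(5)
        with pytest.raises(ValueError):
            cm.apply_ascertainment(unaffected_only, "affected_proband", seed=5)

    def test_unknown_policy_rejected(self, records):
        with pytest.raises(ValueError):
            cm.apply_ascertainment(records, "sample_everyone_twice", seed=6)


class TestNullSibshipGenotypes:
    def test_preserves_family_correlation_and_hwe(self):
        fams = np.repeat(np.arange(2000), 2)
        G = cm.simulate_null_sibship_genotypes(fams, n_snps=200, maf=0.3, seed=8)
        assert G.shape == (4000, 200)
        assert G.mean() / 2 == pytest.approx(0.3, abs=0.01)
        corr = np.corrcoef(G[0::2].ravel(), G[1::2].ravel())[0, 1]
        assert corr == pytest.approx(0.5, abs=0.02)
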