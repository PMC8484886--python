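"""Generator: determinism, ACE structure, measurement and missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import twinlate as tl
from twinlate.errors import ConfigError, DomainError
from twinlate.simulate import DEFAULT_APOE_FREQS, GENOTYPE_E4_COUNT


def _pair_values(truth, zygosity, column):
    g = truth.params[truth.params.zygosity == zygosity]
    wide = g.groupby("family_id")[column].apply(list)
    return np.array([v for v in wide if len(v) == 2])


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = tl.SimConfig(n_pairs_mz=30, n_pairs_dz=30, seed=5)
        c1, t1 = tl.simulate_cohort(cfg)
        c2, t2 = tl.simulate_cohort(tl.SimConfig(n_pairs_mz=30, n_pairs_dz=30, seed=5))
        pd.testing.assert_frame_equal(c1.individuals, c2.individuals)
        pd.testing.assert_frame_equal(c1.observations, c2.observations)
        pd.testing.assert_frame_equal(t1.params, t2.params)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ConfigError):
            tl.simulate_cohort(tl.SimConfig(n_pairs_mz=0, n_pairs_dz=0))


class TestComponentStructure:
    def test_true_parameter_invariants_exact(self, default_cohort):
        _, _, truth = default_cohort
        tp = truth.params
        mz = tp[tp.zygosity == "MZ"]
        assert np.all(mz[[f"aw{k}" for k in range(3)]].to_numpy() == 0.0)
        for zyg in ("MZ", "DZ"):
            for k in range(3):
                ab = _pair_values(truth, zyg, f"ab{k}")
                assert np.allclose(ab[:, 0], ab[:, 1])  # shared between-family
                cc = _pair_values(truth, zyg, f"c{k}")
                assert np.allclose(cc[:, 0], cc[:, 1])

    def test_mz_cotwins_identical_when_no_nonshared(self):
        cfg = tl.SimConfig(
            n_pairs_mz=40, n_pairs_dz=1, seed=2,
            var_e=(0.0, 0.0, 0.0), cov_is=(0.002, 0.0, 0.0),
        )
        _, truth = tl.simulate_cohort(cfg)
        for k in range(3):
            pi = _pair_values(truth, "MZ", f"pi{k}")
            assert np.allclose(pi[:, 0], pi[:, 1], atol=1e-12)

    def test_latent_iccs_match_closed_form(self):
        # unit-total intercept variance (0.4, 0.2, 0.4): rMZ = 0.6, rDZ = 0.4
        cfg = tl.SimConfig(
            n_pairs_mz=5000, n_pairs_dz=5000, seed=11,
            var_a=(0.4, 0.01, 0.0), var_c=(0.2, 0.01, 0.0),
            var_e=(0.4, 0.01, 0.001), cov_is=(0.0, 0.0, 0.0),
        )
        _, truth = tl.simulate_cohort(cfg)
        for zyg, expected in (("MZ", 0.6), ("DZ", 0.4)):
            pi = _pair_values(truth, zyg, "pi0")
            r = np.corrcoef(pi[:, 0], pi[:, 1])[0, 1]
            se = (1 - expected**2) / np.sqrt(len(pi))
            assert abs(r - expected) < 3 * se

    def test_pair_moment_identity(self):
        # Var(sum)/2 - Var(diff)/2 estimates cov = s2A + s2C in MZ pairs
        cfg = tl.SimConfig(
            n_pairs_mz=5000, n_pairs_dz=1, seed=13,
            var_a=(0.4, 0.01, 0.0), var_c=(0.2, 0.01, 0.0),
            var_e=(0.4, 0.01, 0.001), cov_is=(0.0, 0.0, 0.0),
        )
        _, truth = tl.simulate_cohort(cfg)
        pi = _pair_values(truth, "MZ", "pi0")
        est = (pi.sum(axis=1).var(ddof=1) - (pi[:, 0] - pi[:, 1]).var(ddof=1)) / 4
        assert est == pytest.approx(0.6, abs=0.05)


class TestApoe:
    def test_genotype_frequencies_converge(self):
        cfg = tl.SimConfig(n_pairs_mz=1, n_pairs_dz=20000, seed=3,
                           apoe_missing_rate=0.0)
        cohort, _ = tl.simulate_cohort(cfg)
        # DZ co-twins draw independently here; use one twin per pair
        first = cohort.individuals.groupby("family_id").head(1)
        counts = first["apoe_e4"].value_counts(normalize=True)
        expect_by_e4 = {0: 0.0, 1: 0.0, 2: 0.0}
        for g, p in DEFAULT_APOE_FREQS.items():
            expect_by_e4[GENOTYPE_E4_COUNT[g]] += p
        n = len(first)
        for e4, p in expect_by_e4.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(e4, 0.0) - p) < 4 * se

    def test_mz_share_genotype(self):
        cfg = tl.SimConfig(n_pairs_mz=300, n_pairs_dz=1, seed=4,
                           apoe_missing_rate=0.0)
        cohort, _ = tl.simulate_cohort(cfg)
        wide = cohort.individuals.groupby("family_id")["apoe_e4"].nunique()
        mz_fams = cohort.individuals[cohort.individuals.zygosity == "MZ"]["family_id"]
        assert (wide.loc[mz_fams.unique()] == 1).all()

    def test_missing_rate_applied(self, default_cohort):
        _, cohort, _ = default_cohort
        frac = cohort.individuals["apoe_e4"].isna().mean()
        assert 0.55 < frac < 0.70  # target 0.626


class TestOrdinalize:
    @pytest.mark.parametrize(
        "latent,expected", [(-5.0, 0), (2.0, 3), (0.0, 1), (1.0, 2)]
    )
    def test_cases(self, latent, expected):
        assert tl.ordinalize_latent(latent, (-0.5, 0.8, 1.8)) == expected

    def test_bad_thresholds(self):
        with pytest.raises(ConfigError):
            tl.ordinalize_latent(0.0, (1.0, 0.5, 2.0))

    def test_category_proportions_match_gaussian_cdf(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal(100_000)
        th = (-0.5, 0.8, 1.8)
        cats = tl.ordinalize_latent(z, th)
        cum = [norm.cdf(t) for t in th] + [1.0]
        expected = np.diff([0.0] + cum)
        observed = np.bincount(cats, minlength=4) / len(z)
        assert np.all(np.abs(observed - expected) < 0.01)


class TestMissingness:
    def test_rate_zero_unchanged(self, default_cohort):
        _, cohort, _ = default_cohort
        out = tl.apply_missingness(cohort, "MCAR", 0.0)
        pd.testing.assert_frame_equal(out.observations, cohort.observations)

    def test_mcar_rate_calibrated(self):
        cfg = tl.SimConfig(n_pairs_mz=500, n_pairs_dz=500, seed=6)
        cohort, _ = tl.simulate_cohort(cfg)
        out = tl.apply_missingness(cohort, "MCAR", 0.3, seed=1)
        n = len(cohort.observations)
        frac = out.observations["score"].isna().mean()
        se = np.sqrt(0.3 * 0.7 / n)
        # the keep-one-per-person guard restores only a handful of scores
        assert abs(frac - 0.3) < 3 * se + 0.005

    def test_mnar_selects_high_scores_out(self):
        cfg = tl.SimConfig(n_pairs_mz=400, n_pairs_dz=400, seed=7)
        cohort, _ = tl.simulate_cohort(cfg)
        out = tl.apply_missingness(cohort, "MNAR", 0.35, delta=0.0, seed=2)
        pre = cohort.observations["score"].astype(float)
        post = out.observations["score"].astype(float)
        assert post.mean() < pre.mean()

    def test_everyone_retains_a_score(self):
        cfg = tl.SimConfig(n_pairs_mz=100, n_pairs_dz=100, seed=9)
        cohort, _ = tl.simulate_cohort(cfg)
        out = tl.apply_missingness(cohort, "MCAR", 0.8, seed=3)
        per_person = out.observations.dropna(subset=["score"]).groupby("person_id").size()
        assert set(per_person.index) == set(cohort.individuals["person_id"])

    def test_bad_rate(self, default_cohort):
        _, cohort, _ = default_cohort
        with pytest.raises(DomainError):
            tl.apply_missingness(cohort, "MCAR", 1.0)


class TestDementiaGeneration:
    def test_incidence_monotone_in_loneliness_link(self):
        rates = []
        for coef in (0.0, 1.5):
            cfg = tl.SimConfig(n_pairs_mz=600, n_pairs_dz=600, seed=21)
            cfg.dementia_model["pi0"] = coef
            cohort, _ = tl.simulate_cohort(cfg)
            rates.append(cohort.individuals["dementia"].mean())
        assert rates[1] > rates[0]

    def test_default_incidence_near_quarter(self, default_cohort):
        _, cohort, _ = default_cohort
        assert 0.18 < cohort.individuals["dementia"].mean() < 0.33
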