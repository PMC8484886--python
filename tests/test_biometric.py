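"""ACE decomposition, Falconer/ICC arithmetic, biometric regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twinlate as tl
from twinlate.biometric import _pair_arrays
from twinlate.errors import DomainError, EstimationError, InestimableTermError


class TestFalconer:
    @pytest.mark.parametrize(
        "r_mz,r_dz,expected",
        [
            (0.29, 0.25, (0.08, 0.21, 0.71)),   # loneliness intercept
            (0.33, 0.14, (0.38, -0.05, 0.67)),  # linear slope (negative c2)
            (0.45, 0.43, (0.04, 0.41, 0.55)),   # dementia risk
        ],
    )
    def test_published_style_cells(self, r_mz, r_dz, expected):
        est = tl.falconer_estimates(r_mz, r_dz)
        assert est.as_tuple() == pytest.approx(expected, abs=1e-9)

    def test_equal_correlations_no_heritability(self):
        assert tl.falconer_estimates(0.37, 0.37).h2 == pytest.approx(0.0)

    @given(
        st.floats(-1, 1, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    )
    @settings(deadline=None)
    def test_proportions_sum_to_one_identically(self, r_mz, r_dz):
        est = tl.falconer_estimates(r_mz, r_dz)
        assert est.h2 + est.c2 + est.e2 == pytest.approx(1.0, abs=1e-12)

    def test_domain_check(self):
        with pytest.raises(DomainError):
            tl.falconer_estimates(1.2, 0.3)


class TestICC:
    @pytest.mark.parametrize(
        "within,between,expected",
        [(1.03, 0.86, 0.46), (1.00, 0.76, 0.43), (1.0, 0.0, 0.0)],
    )
    def test_ratio(self, within, between, expected):
        assert tl.intraclass_correlation(within, between).icc == pytest.approx(
            expected, abs=5e-3
        )

    def test_zero_total_variance(self):
        with pytest.raises(DomainError):
            tl.intraclass_correlation(0.0, 0.0)


@pytest.fixture(scope="module")
def decomposition(continuous_cohort):
    _, cohort, _ = continuous_cohort
    return tl.fit_twin_decomposition(cohort)


class TestDecomposition:
    def test_recovers_generating_components(self, continuous_cohort, decomposition):
        cfg, _, _ = continuous_cohort
        v = decomposition.variances
        for param, k in (("intercept", 0), ("linear", 1)):
            for comp, truthv in (("a", cfg.var_a[k]), ("c", cfg.var_c[k]),
                                 ("e", cfg.var_e[k])):
                est = v.loc[param, f"var_{comp}"]
                se = v.loc[param, f"se_var_{comp}"]
                assert abs(est - truthv) < max(3 * se, 0.02), (param, comp)

    def test_group_moments_are_algebraic_images(self, decomposition):
        v = decomposition.variances
        m = decomposition.group_moments()
        for param in ("intercept", "linear", "quadratic"):
            va, vc, ve = (v.loc[param, f"var_{x}"] for x in "ace")
            assert m.loc[param, "MZ_B"] == pytest.approx(va + vc, rel=1e-9)
            assert m.loc[param, "MZ_W"] == pytest.approx(ve, rel=1e-9)
            assert m.loc[param, "DZ_B"] == pytest.approx(0.5 * va + vc, rel=1e-9)
            assert m.loc[param, "DZ_W"] == pytest.approx(0.5 * va + ve, rel=1e-9)

    def test_ml_matches_falconer_oracle(self, continuous_cohort, decomposition):
        # moment route: Falconer on empirical twin correlations of the true
        # latent intercepts, versus the ML proportions from the fitted model
        _, _, truth = continuous_cohort
        tp = truth.params
        rs = {}
        for zyg in ("MZ", "DZ"):
            g = tp[tp.zygosity == zyg].groupby("family_id")["pi0"].apply(list)
            arr = np.array([x for x in g if len(x) == 2])
            rs[zyg] = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
        moment = tl.falconer_estimates(rs["MZ"], rs["DZ"])
        ml = decomposition.ace_proportions().loc["intercept"]
        assert abs(ml["h2"] - moment.h2) < 0.1
        assert abs(ml["c2"] - moment.c2) < 0.1
        assert abs(ml["e2"] - moment.e2) < 0.1

    @pytest.mark.parametrize("h2,c2", [(0.6, 0.1), (0.1, 0.5)])
    def test_recovery_across_heritability_grid(self, h2, c2):
        # absolute bias of recovered proportions stays small across the
        # (h2, c2) plane, not just at one generating point
        e2 = 1.0 - h2 - c2
        cfg = tl.SimConfig(
            n_pairs_mz=1000, n_pairs_dz=1000, seed=int(1e4 + 100 * h2 + 10 * c2),
            ordinal=False,
            var_a=(h2, 0.02, 0.002), var_c=(c2, 0.01, 0.001),
            var_e=(e2, 0.03, 0.004), cov_is=(0.0, 0.0, 0.0),
        )
        cohort, _ = tl.simulate_cohort(cfg)
        vc = tl.fit_twin_decomposition(cohort, compute_se=False)
        props = vc.ace_proportions().loc["intercept"]
        for key, target in (("h2", h2), ("c2", c2), ("e2", e2)):
            assert abs(props[key] - target) < 0.08, (key, props[key], target)

    def test_boundary_quadratic_reported_dropped(self, default_cohort):
        # default generating conditions put all quadratic variance in E, so
        # the between-family quadratic components sit on/near the 0 boundary
        _, cohort, _ = default_cohort
        vc = tl.fit_twin_decomposition(cohort)
        assert ("A", "quadratic") in set(vc.dropped)
        v = vc.variances
        c_quad = v.loc["quadratic", "var_c"]
        assert ("C", "quadratic") in set(vc.dropped) or (
            c_quad < 2 * v.loc["quadratic", "se_var_c"]
        )
        # between-pair share of quadratic variance is a minority share
        m = vc.group_moments().loc["quadratic"]
        assert m["MZ_B"] < m["MZ_W"]

    def test_single_zygosity_rejected(self, default_cohort):
        _, cohort, _ = default_cohort
        mz_only = cohort.subset(
            cohort.individuals.loc[cohort.individuals.zygosity == "MZ", "person_id"]
        )
        with pytest.raises(EstimationError, match="DZ"):
            tl.fit_twin_decomposition(mz_only)

    def test_likelihood_invariant_to_twin_order(self, default_cohort):
        _, cohort, _ = default_cohort
        data1, _ = _pair_arrays(cohort, risk=None)
        perm = cohort.individuals.copy()
        # reverse each family's member order
        perm = perm.iloc[::-1].reset_index(drop=True)
        flipped = tl.TwinCohort(perm, cohort.observations)
        data2, _ = _pair_arrays(flipped, risk=None)
        from twinlate._mlcore import MarginalModel
        from twinlate.biometric import _assemble_decomposition, _decomposition_k_grad

        m1 = MarginalModel(data1, _assemble_decomposition, 12, _decomposition_k_grad)
        m2 = MarginalModel(data2, _assemble_decomposition, 12, _decomposition_k_grad)
        th = np.concatenate([[0.2, 0.05, 0.02], [np.log(0.5)],
                             [0.2, 0.05, 0.1, 0.05] * 3])
        assert m1.nll_grad(th)[0] == pytest.approx(m2.nll_grad(th)[0], rel=1e-10)


@pytest.fixture(scope="module")
def biometric_with_effect():
    cfg = tl.SimConfig(
        n_pairs_mz=400, n_pairs_dz=400, seed=91, ordinal=False,
        wave_schedules={"SATSA": [3, 3, 3], "GENDER": [3, 3, 3], "OCTO": [3, 3, 3]},
        var_a=(0.3, 0.04, 0.01), var_c=(0.25, 0.04, 0.01), var_e=(0.35, 0.04, 0.02),
        cov_is=(0.0, 0.0, 0.0), resid_sd=0.5,
        reg_effects=((0.0, 0.0, 0.5), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
    )
    cohort, truth = tl.simulate_cohort(cfg)
    risk = tl.simulate_risk_scores(truth, cfg, seed=92)
    fit = tl.fit_biometric_regression(cohort, risk)
    return cfg, fit


class TestBiometricRegression:
    def test_nonshared_path_recovered(self, biometric_with_effect):
        _, fit = biometric_with_effect
        row = fit.regression("E", "intercept")
        assert abs(row["estimate"] - 0.5) < 3 * row["se"]
        # genetic and shared-environment paths stay near zero
        for comp in ("A", "C"):
            r = fit.regression(comp, "intercept")
            assert abs(r["estimate"]) < max(3 * r["se"], 0.5)

    def test_constant_risk_rejected(self, default_cohort):
        _, cohort, _ = default_cohort
        import pandas as pd
        risk = pd.DataFrame(
            {"person_id": cohort.individuals["person_id"], "resid": 1.0}
        )
        with pytest.raises(InestimableTermError):
            tl.fit_biometric_regression(cohort, risk)

    def test_null_regression_model_nested(self, biometric_with_effect):
        _, fit = biometric_with_effect
        live = [
            f"{c.lower()}reg{k + 1}"
            for c in ("A", "C", "E")
            for k, p in enumerate(("intercept", "linear", "quadratic"))
            if (c, p) not in fit.dropped_terms
        ]
        cmp = tl.constrain_and_test(fit, {"fix": {n: 0.0 for n in live}})
        assert cmp.lrt_stat >= 0.0
        assert cmp.delta_df == len(live)
        assert cmp.preferred == "full"  # the true ereg1 = 0.5 is detectable

    def test_fix_at_own_estimate_keeps_likelihood(self, biometric_with_effect):
        _, fit = biometric_with_effect
        val = float(fit.regression("E", "intercept")["estimate"])
        cmp = tl.constrain_and_test(fit, {"fix": {"ereg1": val}})
        assert cmp.delta_df == 1
        assert cmp.lrt_stat == pytest.approx(0.0, abs=1e-3)

    def test_two_equality_constraints_give_two_df(self, biometric_with_effect):
        _, fit = biometric_with_effect
        cmp = tl.constrain_and_test(
            fit,
            {"equate": [["areg1", "creg1"], ["areg2", "creg2"]]},
        )
        assert cmp.delta_df == 2
        assert cmp.lrt_stat >= 0.0

    def test_constraint_on_dropped_component_rejected(self, default_cohort):
        _, cohort, _ = default_cohort
        fit_d = tl.fit_dementia_logistic(cohort)
        risk = tl.pearson_residuals(fit_d)
        fit = tl.fit_biometric_regression(cohort, risk)
        assert ("A", "quadratic") in fit.dropped_terms
        with pytest.raises(EstimationError):
            tl.constrain_and_test(fit, {"fix": {"var_a_quadratic": 0.1}})

    def test_two_stage_close_to_joint(self, biometric_with_effect):
        cfg, joint = biometric_with_effect
        cohort, truth = tl.simulate_cohort(cfg)
        risk = tl.simulate_risk_scores(truth, cfg, seed=92)
        two = tl.fit_biometric_regression(cohort, risk, two_stage=True)
        e1_joint = joint.regression("E", "intercept")["estimate"]
        e1_two = two.regression("E", "intercept")["estimate"]
        assert abs(e1_joint - e1_two) < 0.15
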