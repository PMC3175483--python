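"""Confirmatory factor models: df counting, ML fitting, fit indices,
classification, structural regressions, second-order models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunosig.cfa import (
    CfaSpec,
    CFAModel,
    cfa_classify,
    cfa_fit,
    fit_indices,
    model_df,
    parse_spec_text,
    second_order_fit,
    sem_fit,
)

IND6 = list("abcdef")
SPEC_2F = dict(factors={"f1": IND6[:3], "f2": IND6[3:]})


def make_two_factor_data(rng, n=500, phi_off=0.3,
                         lam1=(1.0, 0.8, 0.9), lam2=(1.0, 0.7, 0.85),
                         theta=(0.4, 0.5, 0.3, 0.45, 0.35, 0.5)):
    lam = np.zeros((6, 2))
    lam[:3, 0] = lam1
    lam[3:, 1] = lam2
    phi = np.array([[1.0, phi_off], [phi_off, 1.0]])
    eta = rng.multivariate_normal([0, 0], phi, n)
    X = eta @ lam.T + rng.standard_normal((n, 6)) * np.sqrt(theta)
    return pd.DataFrame(X, columns=IND6), lam


class TestModelDf:
    def test_one_factor_three_indicators_just_identified(self):
        spec = CfaSpec(factors={"f1": ["a", "b", "c"]})
        assert model_df(spec) == 0

    def test_two_correlated_factors_six_indicators(self):
        spec = CfaSpec(**SPEC_2F)
        # 21 moments - (4 free loadings + 6 residuals + 2 variances + 1 cov)
        assert model_df(spec) == 8

    def test_underidentified_raises(self):
        spec = CfaSpec(factors={"f1": ["a", "b"]})
        with pytest.raises(ValueError, match="under-identified"):
            model_df(spec)

    def test_brute_force_parameter_enumeration(self, rng):
        """df equals v(v+1)/2 minus an explicit count of free parameters
        for randomized two-factor patterns."""
        for _ in range(20):
            n1 = int(rng.integers(3, 6))
            n2 = int(rng.integers(3, 6))
            inds1 = [f"x{i}" for i in range(n1)]
            inds2 = [f"y{i}" for i in range(n2)]
            covary = "all" if rng.random() < 0.5 else "none"
            spec = CfaSpec(factors={"f1": inds1, "f2": inds2}, covary=covary)
            v = n1 + n2
            free = (n1 - 1) + (n2 - 1)      # loadings minus scaling constraints
            free += v                        # residual variances
            free += 2                        # factor variances
            free += 1 if covary == "all" else 0
            assert model_df(spec) == v * (v + 1) // 2 - free

    def test_fixed_variance_scaling_frees_all_loadings(self):
        spec = CfaSpec(factors={"f1": ["a", "b", "c"]},
                       fixed_variance={"f1": 1.0})
        # 6 moments - (3 loadings + 3 residuals) = 0
        assert model_df(spec) == 0


class TestFitIndices:
    def test_reported_model_chi_square_tail(self):
        fi = fit_indices(14.054, 8, 191, np.eye(3), np.eye(3))
        assert fi.p_value == pytest.approx(0.0804, abs=5e-4)

    def test_rmsea_zero_when_chisq_equals_df(self):
        fi = fit_indices(8.0, 8, 100, np.eye(3), np.eye(3))
        assert fi.rmsea == 0.0

    def test_rmsea_clamped_below_df(self):
        fi = fit_indices(3.0, 8, 100, np.eye(3), np.eye(3))
        assert fi.rmsea == 0.0

    def test_df_zero_markers_but_srmr_computed(self):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        Sigma = np.array([[1.0, 0.2], [0.2, 1.0]])
        fi = fit_indices(0.0, 0, 50, S, Sigma)
        assert np.isnan(fi.rmsea) and np.isnan(fi.p_value)
        # residual only on the off-diagonal: sqrt(mean([0, 0.2^2, 0]))
        assert fi.srmr == pytest.approx(np.sqrt(0.04 / 3))

    def test_srmr_standardization_by_observed_sds(self):
        S = np.diag([4.0, 9.0])
        Sigma = np.diag([4.0, 9.0]).astype(float)
        Sigma[0, 1] = Sigma[1, 0] = 3.0  # residual -3 over sqrt(4*9)=6 -> 0.5
        fi = fit_indices(1.0, 1, 50, S, Sigma)
        assert fi.srmr == pytest.approx(np.sqrt(0.25 / 3))


class TestCfaFit:
    def test_perfect_fit_by_construction(self):
        lam = np.zeros((6, 2))
        lam[:3, 0] = [1, 0.8, 0.9]
        lam[3:, 1] = [1, 0.7, 0.85]
        phi = np.array([[1.0, 0.3], [0.3, 0.8]])
        Sigma = lam @ phi @ lam.T + np.diag([0.4, 0.5, 0.3, 0.45, 0.35, 0.5])
        res, fi = cfa_fit(CfaSpec(**SPEC_2F), (Sigma, 500))
        assert res.fmin == pytest.approx(0.0, abs=1e-6)
        assert fi.chi_square == pytest.approx(0.0, abs=1e-3)
        np.testing.assert_allclose(res.loadings.to_numpy(), lam, atol=1e-4)

    def test_just_identified_model_zero_chi_square(self, rng):
        X = rng.standard_normal((200, 3)) @ np.diag([1.0, 1.2, 0.8])
        X[:, 1] += 0.5 * X[:, 0]
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        res, fi = cfa_fit(CfaSpec(factors={"f1": ["a", "b", "c"]}), df)
        assert fi.df == 0
        assert fi.chi_square == pytest.approx(0.0, abs=1e-4)
        assert np.isnan(fi.rmsea)

    def test_loading_recovery_simulation(self, rng):
        """Standardized two-factor design (loadings 0.7-0.9, unit factor
        variances): >=95% of loading estimates land within +/-0.1 of truth."""
        spec = CfaSpec(**SPEC_2F, fixed_variance={"f1": 1.0, "f2": 1.0})
        within = 0
        total = 0
        reps = 30
        for _ in range(reps):
            lam = np.zeros((6, 2))
            lam[:3, 0] = rng.uniform(0.7, 0.9, 3)
            lam[3:, 1] = rng.uniform(0.7, 0.9, 3)
            phi = np.array([[1.0, 0.3], [0.3, 1.0]])
            eta = rng.multivariate_normal([0, 0], phi, 500)
            theta = 1 - (lam**2).sum(axis=1)
            X = eta @ lam.T + rng.standard_normal((500, 6)) * np.sqrt(theta)
            res, _ = cfa_fit(spec, pd.DataFrame(X, columns=IND6))
            est = np.abs(res.loadings.to_numpy())
            err = np.abs(est - lam)[lam != 0]
            within += int((err < 0.1).sum())
            total += err.size
        assert within / total >= 0.95

    def test_swapped_indicators_fit_strictly_worse(self, rng):
        df, _ = make_two_factor_data(rng, n=400, phi_off=0.2)
        good, fi_good = cfa_fit(CfaSpec(**SPEC_2F), df)
        swapped = CfaSpec(factors={"f1": ["a", "b", "f"], "f2": ["d", "e", "c"]})
        bad, fi_bad = cfa_fit(swapped, df)
        assert fi_bad.chi_square > fi_good.chi_square
        assert fi_bad.rmsea > fi_good.rmsea

    def test_near_singular_covariance_advises(self, rng):
        base = rng.standard_normal(100)
        X = np.column_stack([base, base * 2 + 1e-9, rng.standard_normal(100)])
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="fewer indicators"):
            CFAModel(CfaSpec(factors={"f1": ["a", "b", "c"]}), df)

    def test_sample_size_guard(self, rng):
        df, _ = make_two_factor_data(rng, n=10)
        with pytest.raises(ValueError, match="free parameters"):
            CFAModel(CfaSpec(**SPEC_2F), df.iloc[:8])

    def test_robust_ses_same_order_as_ml(self, rng):
        df, _ = make_two_factor_data(rng, n=400)
        plain, _ = cfa_fit(CfaSpec(**SPEC_2F), df, robust=False)
        robust, _ = cfa_fit(CfaSpec(**SPEC_2F), df, robust=True)
        a = plain.std_errors.to_numpy()
        b = robust.std_errors.to_numpy()
        mask = ~np.isnan(a)
        ratio = b[mask] / a[mask]
        assert np.all((ratio > 0.5) & (ratio < 2.0))


class TestCfaClassify:
    def _data(self, rng, n_per=8, n_pep=300, sep=1.2, noise=0.5):
        grp = ["g1"] * n_per + ["g2"] * n_per
        eta = np.zeros((2 * n_per, 2))
        eta[:n_per, 0] = sep
        eta[n_per:, 1] = sep
        pep = rng.standard_normal((2, n_pep))
        X = eta @ pep + noise * rng.standard_normal((2 * n_per, n_pep))
        frame = pd.DataFrame(X, index=[f"s{i}" for i in range(2 * n_per)],
                             columns=[f"p{j}" for j in range(n_pep)])
        return frame.T.T, grp  # samples x peptides

    def test_holdout_from_group_one_assigned_correctly(self, rng):
        frame, grp = self._data(rng)
        out = cfa_classify(frame, grp, holdout="s0", seed=2)
        assert out[0].assigned_factor == "g1"
        assert out[0].correct

    def test_noise_sample_unclassified_at_threshold(self, rng):
        frame, grp = self._data(rng)
        frame.loc["s0"] = rng.standard_normal(frame.shape[1])  # pure noise
        out = cfa_classify(frame, grp, holdout="s0", seed=2)
        assert out[0].assigned_factor is None

    def test_threshold_zero_always_assigns(self, rng):
        frame, grp = self._data(rng)
        frame.loc["s0"] = rng.standard_normal(frame.shape[1])
        out = cfa_classify(frame, grp, holdout="s0", threshold=0.0, seed=2)
        assert out[0].assigned_factor is not None

    def test_full_panel_accuracy(self, rng):
        frame, grp = self._data(rng)
        out = cfa_classify(frame, grp, seed=4)
        correct = [o.correct for o in out if o.correct is not None]
        assert np.mean(correct) >= 0.9


class TestSem:
    def _binary_data(self, rng, n, coef):
        lam = np.array([1, 0.8, 0.9, 0.7, 0.85, 0.75])
        eta = rng.standard_normal(n)
        X = np.outer(eta, lam) + rng.standard_normal((n, 6)) * 0.5
        p = 1 / (1 + np.exp(-coef * eta))
        y = np.where(rng.random(n) < p, "cancer", "normal")
        return pd.DataFrame(X, columns=IND6), y

    def test_two_stage_odds_ratio_recovery(self, rng):
        spec = CfaSpec(factors={"f1": IND6}, outcome="disease",
                       reference_level="normal")
        hits = 0
        reps = 25
        for _ in range(reps):
            df, y = self._binary_data(rng, 2000, np.log(2))
            _, _, st = sem_fit(spec, df, y)
            orr = st.odds_ratios.loc["f1"].iloc[0]
            hits += 1.7 <= orr <= 2.35
        assert hits / reps >= 0.9

    def test_null_outcome_or_near_one(self, rng):
        spec = CfaSpec(factors={"f1": IND6}, outcome="disease",
                       reference_level="normal")
        df, _ = self._binary_data(rng, 1500, np.log(2))
        y = np.where(rng.random(1500) < 0.5, "cancer", "normal")
        _, _, st = sem_fit(spec, df, y)
        assert st.odds_ratios.loc["f1"].iloc[0] == pytest.approx(1.0, abs=0.25)
        assert st.p_values.loc["f1"].iloc[0] > 0.01

    def test_multinomial_three_groups_both_factors_significant(self, rng):
        n = 900
        lam = np.zeros((6, 2))
        lam[:3, 0] = [1, 0.8, 0.9]
        lam[3:, 1] = [1, 0.7, 0.85]
        eta = rng.standard_normal((n, 2))
        X = eta @ lam.T + rng.standard_normal((n, 6)) * 0.5
        lin1 = 1.5 * eta[:, 0]
        lin2 = 1.5 * eta[:, 1]
        denom = 1 + np.exp(lin1) + np.exp(lin2)
        u = rng.random(n)
        y = np.where(u < np.exp(lin1) / denom, "normal",
                     np.where(u < (np.exp(lin1) + np.exp(lin2)) / denom,
                              "second_tumor", "single_tumor"))
        spec = CfaSpec(**SPEC_2F, outcome="disease", link="multinomial",
                       reference_level="single_tumor")
        _, _, st = sem_fit(spec, pd.DataFrame(X, columns=IND6), y)
        assert st.reference_level == "single_tumor"
        assert st.p_values.loc["f1", "normal"] < 0.01
        assert st.p_values.loc["f2", "second_tumor"] < 0.01

    def test_quadrature_agrees_with_two_stage(self, rng):
        spec = CfaSpec(factors={"f1": IND6}, outcome="disease",
                       reference_level="normal")
        df, y = self._binary_data(rng, 800, np.log(2.5))
        _, _, st2 = sem_fit(spec, df, y, method="two_stage")
        _, _, stq = sem_fit(spec, df, y, method="quadrature_ml")
        c2 = st2.coefficients.loc["f1"].iloc[0]
        cq = stq.coefficients.loc["f1"].iloc[0]
        assert np.sign(c2) == np.sign(cq)
        assert st2.p_values.loc["f1"].iloc[0] < 0.01
        assert stq.p_values.loc["f1"].iloc[0] < 0.01

    def test_joint_model_needs_more_observations_than_indicators(self, rng):
        spec = CfaSpec(factors={"f1": IND6}, outcome="disease")
        df, y = self._binary_data(rng, 5, 0.0)
        with pytest.raises(ValueError, match="two_stage"):
            sem_fit(spec, df, y, method="quadrature_ml")


class TestSecondOrder:
    def _hier_data(self, rng, n=500, g_load=0.8):
        g = rng.standard_normal(n)
        e1 = g_load * g + np.sqrt(1 - g_load**2) * rng.standard_normal(n)
        e2 = g_load * g + np.sqrt(1 - g_load**2) * rng.standard_normal(n)
        lam1 = np.array([1, 0.8, 0.9])
        lam2 = np.array([1, 0.85, 0.75])
        X = np.hstack([np.outer(e1, lam1), np.outer(e2, lam2)])
        X += rng.standard_normal((n, 6)) * 0.5
        return pd.DataFrame(X, columns=IND6)

    def test_genuine_hierarchy_fits(self, rng):
        rmseas = [second_order_fit(CfaSpec(**SPEC_2F),
                                   self._hier_data(rng))[1].rmsea
                  for _ in range(10)]
        assert np.median(rmseas) < 0.08

    def test_negatively_correlated_factors_misfit(self, rng):
        # the hierarchy forces a nonnegative factor covariance; data with a
        # strong negative covariance cannot be absorbed and fit collapses
        rmseas = []
        for _ in range(10):
            n = 500
            cov = np.array([[1.0, -0.6], [-0.6, 1.0]])
            eta = rng.multivariate_normal([0, 0], cov, n)
            lam = np.zeros((6, 2))
            lam[:3, 0] = [1, 0.8, 0.9]
            lam[3:, 1] = [1, 0.85, 0.75]
            X = eta @ lam.T + rng.standard_normal((n, 6)) * 0.5
            df = pd.DataFrame(X, columns=IND6)
            rmseas.append(second_order_fit(CfaSpec(**SPEC_2F), df)[1].rmsea)
        assert np.median(rmseas) > 0.1

    def test_requires_three_indicators_per_factor(self, rng):
        spec = CfaSpec(factors={"f1": ["a", "b"], "f2": ["c", "d", "e"]})
        with pytest.raises(ValueError, match="3 indicators"):
            second_order_fit(spec, self._hier_data(rng).iloc[:, :5])


class TestSpecGrammar:
    TEXT = """
    # two-antibody model
    f1: a b c
    f2: d e f
    fix: a@f1 = 1
    covary: f1 f2
    outcome: disease ~ f1 f2 multinomial ref=single_tumor
    """

    def test_parse_and_df(self):
        spec = parse_spec_text(self.TEXT)
        assert spec.factor_ids == ["f1", "f2"]
        assert spec.link == "multinomial"
        assert spec.reference_level == "single_tumor"
        assert model_df(spec) == 8

    def test_order_insensitive(self):
        lines = [l for l in self.TEXT.strip().splitlines()]
        reordered = "\n".join(lines[::-1])
        a, b = parse_spec_text(self.TEXT), parse_spec_text(reordered)
        assert a.factors == b.factors and a.fixed == b.fixed

    def test_variance_scaling_line(self):
        spec = parse_spec_text("f1: a b c\nvariance: f1 = 1\n")
        assert spec.fixed_variance == {"f1": 1.0}
        assert ("a", "f1") not in spec.fixed
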