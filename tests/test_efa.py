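"""Correlation construction, principal axis factoring, rotation, and
loading-threshold classification."""

import numpy as np
import pytest

from immunosig.arraydata import median_normalize_log10
from immunosig.efa import (
    ClassificationResult,
    CorrelationMatrix,
    FactorAnalysis,
    FactorSolution,
    classify_by_loadings,
    correlation,
    eigen_scree,
    paf_fit,
    rotate,
    suggest_n_factors,
)
from immunosig.rotation import promax, varimax
from immunosig.synthesize import generate, two_group_config


def one_factor_R(lam):
    """Correlation matrix satisfying the 1-factor model exactly."""
    lam = np.asarray(lam)
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    return R


def simple_structure(loads_a, loads_b):
    v = len(loads_a) + len(loads_b)
    L = np.zeros((v, 2))
    L[: len(loads_a), 0] = loads_a
    L[len(loads_a):, 1] = loads_b
    return L


class TestCorrelation:
    def test_identical_and_negated_samples(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])

        class Fake:
            values = np.vstack([base, base, -base + 10])
            sample_ids = ["s1", "s2", "s3"]
            peptide_ids = [f"p{i}" for i in range(6)]
            empty_spot = np.zeros(6, dtype=bool)

        C = correlation(Fake(), mode="samples_as_variables")
        assert C.matrix[0, 1] == pytest.approx(1.0)
        assert C.matrix[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_covariance_oracle(self, rng):
        X = rng.standard_normal((5, 100))

        class Fake:
            values = X
            sample_ids = [f"s{i}" for i in range(5)]
            peptide_ids = [f"p{i}" for i in range(100)]
            empty_spot = np.zeros(100, dtype=bool)

        C = correlation(Fake(), mode="samples_as_variables")
        Xc = X - X.mean(axis=1, keepdims=True)
        cov = Xc @ Xc.T / (100 - 1)
        sd = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(C.matrix, cov / np.outer(sd, sd), atol=1e-12)

    def test_zero_variance_sample_named(self):
        class Fake:
            values = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
            sample_ids = ["flat", "s2", "s3"]
            peptide_ids = [f"p{i}" for i in range(5)]
            empty_spot = np.zeros(5, dtype=bool)

        with pytest.raises(ValueError, match="flat"):
            correlation(Fake(), mode="samples_as_variables")

    def test_invalid_matrix_rejected(self):
        bad = np.array([[1.0, 0.5], [0.4, 1.0]])  # asymmetric
        with pytest.raises(ValueError):
            CorrelationMatrix(bad, ["a", "b"])


class TestScree:
    def test_identity_spectrum(self):
        ev = eigen_scree(CorrelationMatrix(np.eye(4), list("abcd")))
        np.testing.assert_allclose(ev, np.ones(4))

    def test_trace_identity(self, rng):
        for v in (3, 6, 11):
            A = rng.standard_normal((v + 5, v))
            R = np.corrcoef(A, rowvar=False)
            assert eigen_scree(R).sum() == pytest.approx(v, abs=1e-9)

    def test_rank_one_plus_noise_dominant_first(self):
        R = one_factor_R([0.9] * 6)
        ev = eigen_scree(R)
        assert ev[0] > 4.0 and ev[1] < 0.3
        assert suggest_n_factors(ev) == 1

    def test_two_block_structure_suggests_two(self):
        L = simple_structure([0.85] * 4, [0.8] * 4)
        R = L @ L.T + np.diag(1 - (L**2).sum(axis=1))
        assert suggest_n_factors(eigen_scree(R)) == 2


class TestPaf:
    def test_recovers_exact_one_factor_loadings(self):
        C = CorrelationMatrix(one_factor_R([0.8, 0.7, 0.6]), list("abc"))
        sol = paf_fit(C, 1)
        np.testing.assert_allclose(np.abs(sol.loadings.ravel()),
                                   [0.8, 0.7, 0.6], atol=1e-4)
        assert sol.converged

    def test_identity_matrix_has_no_common_variance(self):
        sol = paf_fit(CorrelationMatrix(np.eye(5), list("abcde")), 1)
        assert np.all(np.abs(sol.loadings) < 1e-6)

    def test_heywood_case_flagged_not_raised(self):
        # a doublet of near-collinear variables drives a communality past 1
        R = np.array([
            [1.0000, 0.9782, 0.4589, -0.2154],
            [0.9782, 1.0000, 0.4223, -0.1844],
            [0.4589, 0.4223, 1.0000, -0.6632],
            [-0.2154, -0.1844, -0.6632, 1.0000],
        ])
        sol = FactorAnalysis(R, n_factors=2).fit()
        assert sol.heywood_flags.any()
        assert np.all(sol.communalities <= 1.0)

    def test_factor_count_bounds(self):
        C = CorrelationMatrix(np.eye(4), list("abcd"))
        with pytest.raises(ValueError):
            FactorAnalysis(C, n_factors=4)

    def test_pca_mode_zero_uniqueness(self):
        R = one_factor_R([0.8, 0.7, 0.6])
        sol = FactorAnalysis(R, n_factors=1, method="pca").fit()
        np.testing.assert_allclose(sol.uniquenesses, 0.0)

    def test_paf_approaches_pca_as_uniqueness_vanishes(self, rng):
        # 10 variables, tiny uniquenesses: PAF ~ PCA loadings
        lam = rng.uniform(0.985, 0.999, 10)
        R = one_factor_R(lam)
        paf = FactorAnalysis(R, n_factors=1, method="paf").fit()
        pca = FactorAnalysis(R, n_factors=1, method="pca").fit()
        assert np.max(np.abs(np.abs(paf.loadings) - np.abs(pca.loadings))) < 0.02


class TestRotation:
    @pytest.fixture
    def two_factor_solution(self):
        L = simple_structure([0.8, 0.75, 0.7, 0.65], [0.8, 0.75, 0.7, 0.65])
        R = L @ L.T + np.diag(1 - (L**2).sum(axis=1))
        return FactorAnalysis(R, n_factors=2).fit()

    @pytest.mark.parametrize("method", ["varimax", "promax", "geomin"])
    def test_communalities_and_reconstruction_invariant(self, method,
                                                        two_factor_solution):
        sol = rotate(two_factor_solution, method, seed=5)
        rec = sol.reconstruction()
        np.testing.assert_allclose(rec, two_factor_solution.reconstruction(),
                                   atol=1e-6)
        np.testing.assert_allclose(
            np.diag(sol.loadings @ sol.factor_correlation @ sol.loadings.T),
            two_factor_solution.communalities, atol=1e-6)

    def test_varimax_leaves_simple_structure_unchanged(self):
        L = simple_structure([0.8, 0.75, 0.7], [0.85, 0.8, 0.7])
        rotated, _ = varimax(L)
        # up to column permutation / sign
        best = np.abs(rotated)
        np.testing.assert_allclose(np.sort(best.ravel()), np.sort(np.abs(L).ravel()),
                                   atol=1e-6)
        assert np.max(np.abs(best - np.abs(L))) < 1e-6

    def test_varimax_orthogonality_preserves_row_sums(self, rng):
        A = rng.standard_normal((8, 3)) * 0.5
        rotated, T = varimax(A)
        np.testing.assert_allclose(T.T @ T, np.eye(3), atol=1e-9)
        np.testing.assert_allclose((rotated**2).sum(axis=1), (A**2).sum(axis=1),
                                   atol=1e-9)

    def test_promax_kappa_one_reproduces_orthogonal_solution(self):
        L = simple_structure([0.8, 0.75, 0.7], [0.85, 0.8, 0.7])
        pattern, phi = promax(L, kappa=1)
        np.testing.assert_allclose(np.abs(pattern), np.abs(L), atol=1e-6)
        np.testing.assert_allclose(phi, np.eye(2), atol=1e-6)

    def test_promax_factor_correlation_near_zero_under_orthogonal_truth(self, rng):
        L = simple_structure([0.8, 0.75, 0.7, 0.65], [0.8, 0.75, 0.7, 0.65])
        eta = rng.standard_normal((1000, 2))   # uncorrelated factors
        X = eta @ L.T + rng.standard_normal((1000, 8)) * np.sqrt(
            1 - (L**2).sum(axis=1))
        R = np.corrcoef(X, rowvar=False)
        sol = FactorAnalysis(R, n_factors=2).fit(rotation="promax")
        off = sol.factor_correlation[0, 1]
        assert abs(off) < 0.15

    def test_single_factor_rotation_is_identity(self):
        C = CorrelationMatrix(one_factor_R([0.8, 0.7, 0.6]), list("abc"))
        sol = paf_fit(C, 1)
        assert rotate(sol, "promax") is sol

    def test_unknown_method_rejected(self, two_factor_solution):
        with pytest.raises(ValueError):
            rotate(two_factor_solution, "oblimin")


class TestClassification:
    def _solution(self, loadings, ids=None):
        loadings = np.asarray(loadings, dtype=float)
        v, m = loadings.shape
        return FactorSolution(
            loadings=loadings,
            factor_correlation=np.eye(m),
            uniquenesses=np.zeros(v),
            communalities=(loadings**2).sum(axis=1),
            eigenvalues=np.ones(v),
            variable_ids=ids or [f"s{i}" for i in range(v)],
            mode="samples_as_variables",
        )

    def test_clear_loading_assigns_factor(self):
        sol = self._solution([[0.9, 0.1], [0.1, 0.9]])
        res = classify_by_loadings(sol, ["a", "b"])
        assert res.assigned_factor == [0, 1]
        assert res.accuracy == 100.0

    def test_subthreshold_loadings_unclassified(self):
        sol = self._solution([[0.25, 0.28], [0.1, 0.9], [0.8, 0.05]])
        res = classify_by_loadings(sol, ["a", "b", "a"])
        assert res.assigned_factor[0] is None
        assert res.n_unclassified == 1
        # the unclassified sample cannot count as correct
        assert res.accuracy == pytest.approx(100 * 2 / 3)

    def test_factor_group_count_mismatch(self):
        sol = self._solution([[0.9, 0.1], [0.1, 0.9], [0.5, 0.5]])
        with pytest.raises(ValueError, match="group count"):
            classify_by_loadings(sol, ["a", "b", "c"])

    def test_high_separation_accuracy(self):
        accs = []
        for seed in (0, 1, 2):
            x, _ = generate(two_group_config(seed=seed))
            norm = median_normalize_log10(x)
            sol = FactorAnalysis(norm, n_factors=2).fit(rotation="promax")
            accs.append(classify_by_loadings(sol, norm.group_labels).accuracy)
        assert np.median(accs) >= 95.0

    def test_zero_separation_is_chance_level(self):
        accs = []
        for seed in range(25):
            x, _ = generate(two_group_config(
                seed=300 + seed, separation=0.0,
                group_sizes={"normal": 20, "single_tumor": 20},
                n_peptides=150, n_empty_spots=10))
            norm = median_normalize_log10(x)
            sol = FactorAnalysis(norm, n_factors=2).fit(rotation="promax")
            accs.append(classify_by_loadings(sol, norm.group_labels,
                                             threshold=0.0).accuracy)
        assert 40.0 <= np.mean(accs) <= 72.0
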