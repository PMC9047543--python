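import numpy as np
import pytest

from stsbiomech.errors import InvalidArgumentError
from stsbiomech.nlpca import NLPCAConfig, fit_nlpca
from stsbiomech.validation import (RetentionReport, RetentionRules,
                                   balanced_bootstrap_indices,
                                   bootstrap_stability, permutation_retention,
                                   select_components)


@pytest.fixture(scope="module")
def factor_data():
    """Strong 3-factor structure in 15 variables."""
    rng = np.random.default_rng(19)
    n = 100
    factors = rng.normal(size=(n, 3))
    loadings = np.zeros((3, 15))
    loadings[0, :5] = 0.9
    loadings[1, 5:10] = 0.9
    loadings[2, 10:15] = 0.9
    return factors @ loadings + 0.35 * rng.normal(size=(n, 15))


class TestPermutationRetention:
    def test_structured_factors_are_significant_noise_components_not(
            self, factor_data):
        rep = permutation_retention(factor_data, NLPCAConfig(n_components=6),
                                    n_perm=120, seed=2)
        assert rep.significant[:3].all()
        assert not rep.significant[4:].any()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 8))
        cfg = NLPCAConfig(n_components=3)
        a = permutation_retention(X, cfg, n_perm=100, seed=9)
        b = permutation_retention(X, cfg, n_perm=100, seed=9)
        assert np.array_equal(a.null_upper, b.null_upper)
        assert np.array_equal(a.significant, b.significant)

    def test_null_first_component_exceeds_uniform_share(self):
        """Max-eigenvalue bias: the permutation null is not 1/p."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 12))
        rep = permutation_retention(X, NLPCAConfig(n_components=3),
                                    n_perm=100, seed=4)
        assert rep.null_mean[0] > 1.0 / 12.0

    def test_too_few_permutations_rejected(self, factor_data):
        with pytest.raises(InvalidArgumentError):
            permutation_retention(factor_data, n_perm=50)


class TestBootstrapStability:
    def test_identity_resamples_are_perfectly_stable(self, factor_data):
        sol = fit_nlpca(factor_data, NLPCAConfig(n_components=3))
        idx = np.tile(np.arange(factor_data.shape[0]), (5, 1))
        rep = bootstrap_stability(solution=sol, indices=idx)
        for comp in rep.congruence:
            assert comp.mean == pytest.approx(1.0, abs=1e-12)
        for comp in rep.rms_difference:
            assert comp.mean == pytest.approx(0.0, abs=1e-12)
        for comp in rep.pearson:
            assert comp.mean == pytest.approx(1.0, abs=1e-10)

    def test_reference_sign_flip_leaves_metrics_unchanged(self, factor_data):
        sol = fit_nlpca(factor_data, NLPCAConfig(n_components=3))
        rep_a = bootstrap_stability(solution=sol, n_boot=60, seed=5)
        sol.loadings[:, 1] *= -1.0
        rep_b = bootstrap_stability(solution=sol, n_boot=60, seed=5)
        sol.loadings[:, 1] *= -1.0  # restore the shared fixture
        for a, b in zip(rep_a.congruence, rep_b.congruence):
            assert a.mean == pytest.approx(b.mean, abs=1e-12)
        for a, b in zip(rep_a.rms_difference, rep_b.rms_difference):
            assert a.mean == pytest.approx(b.mean, abs=1e-12)

    def test_strong_factors_are_stable_weak_factor_is_not(self):
        """Bootstrap congruence separates strong from weak structure.

        The sample is large relative to the spline degrees of freedom:
        ordinal quantification stretches extreme observations into
        high-leverage points, and at small n that leverage noise, not the
        factor strength, dominates the replicate-to-replicate rotation.
        Distinct factor strengths keep the leading eigenvalues separated
        so replicate components cannot rotate freely within a tied pair.
        """
        rng = np.random.default_rng(23)
        n = 400
        factors = rng.normal(size=(n, 3))
        loadings = np.zeros((3, 15))
        loadings[0, :6] = 0.8
        loadings[1, 6:12] = 0.75
        loadings[2, 12:15] = 0.3    # weak third factor
        noise_sd = np.sqrt(1.0 - (loadings**2).sum(axis=0))
        X = factors @ loadings + rng.normal(size=(n, 15)) * noise_sd
        sol = fit_nlpca(X, NLPCAConfig(n_components=3))
        rep = bootstrap_stability(solution=sol, n_boot=100, seed=6)
        assert rep.congruence[0].mean > 0.95
        assert rep.congruence[1].mean > 0.95
        width_strong = rep.congruence[0].ci_high - rep.congruence[0].ci_low
        width_weak = rep.congruence[2].ci_high - rep.congruence[2].ci_low
        assert width_weak > width_strong

    def test_balanced_resampling_counts_every_subject_equally(self):
        rng = np.random.default_rng(8)
        idx = balanced_bootstrap_indices(17, 40, rng)
        counts = np.bincount(idx.ravel(), minlength=17)
        assert np.all(counts == 40)

    def test_component_matching_is_a_permutation(self, factor_data):
        sol = fit_nlpca(factor_data, NLPCAConfig(n_components=3))
        rep = bootstrap_stability(solution=sol, n_boot=60, seed=7)
        # all components matched in every replicate: no NaN left behind
        assert all(np.isfinite(c.mean) for c in rep.congruence)

    def test_ci_contains_mean(self, factor_data):
        sol = fit_nlpca(factor_data, NLPCAConfig(n_components=3))
        rep = bootstrap_stability(solution=sol, n_boot=80, seed=9)
        for metric in (rep.congruence, rep.rms_difference, rep.pearson):
            for comp in metric:
                assert comp.ci_low - 1e-12 <= comp.mean <= comp.ci_high + 1e-12


class TestSelectComponents:
    @staticmethod
    def _report(observed, upper, eigenvalues, salient):
        observed = np.asarray(observed, float)
        upper = np.asarray(upper, float)
        return RetentionReport(
            observed_vaf=observed, null_mean=upper * 0.8, null_upper=upper,
            significant=observed > upper,
            kaiser_eigenvalues=np.asarray(eigenvalues, float),
            n_salient_loadings=np.asarray(salient),
            loading_threshold=0.5, n_permutations=100, alpha=0.05)

    def test_kaiser_counts_eigenvalues_above_one(self):
        rep = self._report([0.5, 0.3, 0.15, 0.05], [0.1, 0.1, 0.1, 0.1],
                           [5.0, 3.0, 1.5, 0.8], [3, 3, 2, 1])
        assert select_components(rep, RetentionRules(
            use_permutation=False, use_loading_count=False)) == 3

    def test_loading_count_rule_limits_retention(self):
        rep = self._report([0.4, 0.3, 0.2, 0.1], [0.05] * 4,
                           [4.0, 3.0, 2.0, 1.5], [3, 2, 0, 0])
        assert select_components(rep) == 2

    def test_conservative_minimum_across_rules(self):
        # permutation keeps 7-like run, kaiser keeps 3
        rep = self._report([0.3, 0.2, 0.1, 0.08, 0.06, 0.05, 0.04],
                           [0.02] * 7,
                           [4.0, 2.5, 1.2, 0.9, 0.8, 0.7, 0.6],
                           [5, 4, 2, 1, 1, 1, 1])
        assert rep.n_significant_leading == 7
        assert select_components(rep) == 3

    def test_no_rules_enabled_rejected(self):
        rep = self._report([0.3], [0.1], [2.0], [1])
        with pytest.raises(InvalidArgumentError):
            select_components(rep, RetentionRules(
                use_permutation=False, use_kaiser=False,
                use_loading_count=False))
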