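import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from itertools import permutations

from ednanet import correlation as corr
from ednanet.synthetic import CommunityScenario, generate_latent_dynamics


def naive_tau_b(x, y):
    """O(n^2) pair-counting oracle with explicit tie terms."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    C = D = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                C += 1
            else:
                D += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return np.nan if denom == 0 else (C - D) / denom


def exact_null_taus(n=8):
    """Tau of every rank order against the identity: the exact untied null."""
    perms = np.array(list(permutations(range(n))))
    a, b = np.triu_indices(n, 1)
    S = np.sign(perms[:, b] - perms[:, a])
    ref = np.sign(np.arange(n)[b] - np.arange(n)[a])
    return (S @ ref) / (n * (n - 1) / 2)


class TestKendallTauB:
    def test_identity(self):
        assert corr.kendall_tau_b([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversal(self):
        assert corr.kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_example_against_oracle(self):
        x, y = [1, 1, 2, 3], [1, 2, 2, 3]
        assert corr.kendall_tau_b(x, y) == pytest.approx(naive_tau_b(x, y))

    def test_constant_series_undefined(self):
        assert np.isnan(corr.kendall_tau_b([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            corr.kendall_tau_b([1, 2], [1, 2, 3])

    def test_against_naive_oracle_random_tied_series(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(3, 11))
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            expected = naive_tau_b(x, y)
            got = corr.kendall_tau_b(x, y)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=10),
           st.lists(st.integers(0, 5), min_size=2, max_size=10))
    def test_property_bounded_and_matches_oracle(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n], float), np.array(ys[:n], float)
        expected = naive_tau_b(x, y)
        got = corr.kendall_tau_b(x, y)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)
            assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12

    def test_against_scipy(self):
        from scipy.stats import kendalltau

        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.integers(0, 5, 8).astype(float)
            y = rng.integers(0, 5, 8).astype(float)
            expected = kendalltau(x, y).statistic
            got = corr.kendall_tau_b(x, y)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_tau_matrix_symmetric_unit_diagonal(self, rng):
        X = pd.DataFrame(rng.random((10, 8)))
        tau = corr.tau_matrix(X)
        assert np.allclose(tau, tau.T)
        assert np.allclose(np.diag(tau), 1.0)
        iu = np.triu_indices(10, 1)
        assert (np.abs(tau.to_numpy()[iu]) <= 1.0 + 1e-12).all()


class TestPermutationNull:
    def test_pair_count_348_taxa(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.random((348, 8)))
        null = corr.permutation_null(X, n_perm=1, seed=0)
        assert null.size == 348 * 347 // 2 == 60378

    def test_pooled_mean_near_zero(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.random((40, 8)))
        null = corr.permutation_null(X, n_perm=50, seed=3)
        se = null.std() / np.sqrt(null.size)
        # pooled taus are correlated; allow a generous multiple of the SE
        assert abs(null.mean()) < 30 * se

    def test_deterministic_under_seed(self):
        X = pd.DataFrame(np.random.default_rng(5).random((12, 8)))
        a = corr.permutation_null(X, n_perm=10, seed=9)
        b = corr.permutation_null(X, n_perm=10, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_tail_matches_exhaustive_enumeration(self):
        exact = float(np.mean(np.abs(exact_null_taus(8)) >= 5 / 7))
        X = pd.DataFrame(np.random.default_rng(100).standard_normal((50, 8)))
        null = corr.permutation_null(X, n_perm=100, seed=0)
        phat = float(np.mean(np.abs(null) >= 5 / 7 - 1e-12))
        ci = 2.576 * np.sqrt(exact * (1 - exact) / null.size)
        assert abs(phat - exact) <= ci

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            corr.permutation_null(pd.DataFrame(np.ones((1, 8))), seed=0)


class TestTauPvalues:
    def test_smoothing_floor(self):
        null = np.linspace(-0.5, 0.5, 10_000)
        tau = pd.DataFrame([[1.0, 0.99], [0.99, 1.0]])
        p = corr.tau_pvalues(tau, null)
        assert p.iloc[0, 1] == pytest.approx(1 / 10_001)

    def test_zero_tau_p_near_one(self):
        null = np.random.default_rng(0).uniform(-1, 1, 5000)
        tau = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        p = corr.tau_pvalues(tau, null)
        assert p.iloc[0, 1] > 0.99

    def test_matches_direct_count(self, rng):
        null = rng.uniform(-1, 1, 2000)
        obs = rng.uniform(-1, 1, (5, 5))
        obs = (obs + obs.T) / 2
        np.fill_diagonal(obs, 1.0)
        tau = pd.DataFrame(obs)
        p = corr.tau_pvalues(tau, null)
        for i in range(5):
            for j in range(5):
                expected = (1 + np.sum(np.abs(null) >= abs(obs[i, j]) - 1e-12)) \
                    / (1 + null.size)
                assert p.iloc[i, j] == pytest.approx(expected)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            corr.tau_pvalues(pd.DataFrame([[1.0]]), np.empty(0))


def reference_bh(p):
    """Independent step-up oracle, deliberately written differently."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        out[idx] = running
    return out


class TestAdjustment:
    def test_worked_example(self):
        adj = corr.benjamini_hochberg(np.array([0.01, 0.02, 0.03]))
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_adjust_to_themselves(self):
        # step-up arithmetic: with all p equal the rank-m term p*m/m = p
        # wins the running minimum, so BH returns p unchanged (Bonferroni
        # gives p*m; the two are NOT equal in this case)
        p = np.full(7, 0.004)
        assert corr.benjamini_hochberg(p) == pytest.approx(p)
        assert corr.bonferroni(p) == pytest.approx(np.minimum(p * 7, 1.0))

    def test_random_vectors_match_reference(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, int(rng.integers(2, 60)))
            assert corr.benjamini_hochberg(p) == pytest.approx(reference_bh(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 40)
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        assert corr.benjamini_hochberg(p) == pytest.approx(sm_adj)

    def test_bh_contains_bonferroni(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 0.2, 30)
            bh = corr.benjamini_hochberg(p) <= 0.05
            bf = corr.bonferroni(p) <= 0.05
            assert (bh | ~bf).all()

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 50)
        assert (corr.benjamini_hochberg(p) >= p - 1e-12).all()

    def test_critical_tau_infinite_when_nothing_significant(self):
        tau = pd.DataFrame(np.eye(3))
        p = pd.DataFrame(np.full((3, 3), 0.9))
        _, _, critical = corr.adjust_and_threshold(p, tau)
        assert np.isinf(critical)

    def test_critical_tau_is_smallest_significant(self):
        obs = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.8], [0.2, 0.8, 1.0]])
        p = np.array([[0.0, 1e-5, 0.9], [1e-5, 0.0, 1e-4], [0.9, 1e-4, 0.0]])
        adj, bon, critical = corr.adjust_and_threshold(
            pd.DataFrame(p), pd.DataFrame(obs), alpha=0.05)
        assert critical == pytest.approx(0.8)


class TestAnalyze:
    def test_planted_scenario_critical_tau_in_range(self):
        lat = generate_latent_dynamics(CommunityScenario(seed=1))
        result = corr.analyze(lat.abundance, n_perm=50, seed=1)
        assert 0.4 < result.critical_tau < 1.0

    def test_noiseless_within_module_pairs_significant(self):
        sc = CommunityScenario(n_taxa=40, n_modules=3, sigma=0.0, seed=2,
                               terrestrial_fraction=0.0)
        lat = generate_latent_dynamics(sc)
        result = corr.analyze(lat.abundance, n_perm=100, seed=2)
        pairs = result.pair_table()
        truth = lat.module_truth
        within = pairs[[truth[a] == truth[b]
                        for a, b in zip(pairs.taxon_a, pairs.taxon_b)]]
        assert within["significant"].all()

    def test_constant_taxa_excluded(self):
        X = pd.DataFrame(np.random.default_rng(0).random((6, 8)))
        X.iloc[2] = 0.7
        result = corr.analyze(X, n_perm=20, seed=0)
        assert result.undefined_taxa == [2]
        assert result.p.iloc[2].isna().all()
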