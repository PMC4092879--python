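"""DE test families: closed-form cases, oracles and statistical behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import debench as db
from debench.methods import nb_conditional_pvalues

GROUPS_4 = [1, 1, 2, 2]
GROUPS_20 = [1] * 10 + [2] * 10


def _nb(rng, mu, phi, size):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


@pytest.fixture(scope="module")
def balanced_identical():
    """Counts whose two groups are identical sample-for-sample."""
    rng = np.random.default_rng(1)
    half = _nb(rng, 80.0, 0.3, (60, 4))
    return np.hstack([half, half]), [1] * 4 + [2] * 4


class TestNormalization:
    def test_equal_totals_give_unit_factors(self):
        counts = np.tile([[10], [20]], (1, 4))
        assert np.allclose(db.normalize_total_count(counts), 1.0)

    def test_two_sample_closed_form(self):
        counts = np.array([[1_000_000, 2_000_000]])
        f = db.normalize_total_count(counts)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.integers(1, 10_000), min_size=2, max_size=8))
    def test_factors_multiply_to_one(self, totals):
        counts = np.array([totals])
        assert np.isclose(db.normalize_total_count(counts).prod(), 1.0)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="positive total"):
            db.normalize_total_count(np.array([[0, 5]]))


class TestRPKM:
    @pytest.mark.parametrize(
        "C,N,L,expected",
        [(10, 1e6, 1000, 10.0), (0, 1e6, 1000, 0.0), (100, 1e7, 2000, 5.0)],
    )
    def test_printed_formula(self, C, N, L, expected):
        assert db.compute_rpkm(C, N, L) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            db.compute_rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            db.compute_rpkm(1, 100, 0)


class TestFoldChangeEstimate:
    def test_equal_means_unit_fc(self):
        counts = np.array([[10, 10, 10, 10], [5, 5, 5, 5]])
        fc = db.fold_change_estimate(counts, GROUPS_4, pseudocount=0.0)
        assert np.allclose(fc, 1.0)

    def test_doubled_mean(self):
        # second gene balances totals so normalization factors are 1
        counts = np.array([[10, 10, 20, 20], [20, 20, 10, 10]])
        fc = db.fold_change_estimate(counts, GROUPS_4, pseudocount=0.0)
        assert np.allclose(fc, [2.0, 0.5])

    def test_all_zero_gene_pseudocount_symmetry(self):
        counts = np.array([[0, 0, 0, 0], [10, 10, 10, 10]])
        fc = db.fold_change_estimate(counts, GROUPS_4, pseudocount=0.5)
        assert fc[0] == 1.0


class TestPoissonMA:
    def test_symmetric_counts_give_p_one(self):
        counts = np.array([[10, 10], [90, 90]])
        res = db.poisson_ma_test(counts, [1, 2])
        assert np.allclose(res.p, 1.0)

    def test_closed_form_z(self):
        # k1=10, k2=0 with equal library sizes: z = sqrt(10)
        counts = np.array([[10, 0], [90, 100]])
        res = db.poisson_ma_test(counts, [1, 2])
        expected = 2 * stats.norm.sf(np.sqrt(10))
        assert res.p[0] == pytest.approx(expected, abs=2e-5)
        assert expected == pytest.approx(0.00157, abs=2e-5)

    def test_overdispersion_inflates_size(self, rng):
        # NB data with phi = 0.4: empirical size at nominal 0.05 far above 0.05
        counts = _nb(rng, 200.0, 0.4, (4000, 20))
        res = db.poisson_ma_test(counts, GROUPS_20)
        assert np.mean(res.p < 0.05) > 0.3

    def test_null_poisson_p_uniform(self, rng):
        counts = rng.poisson(rng.lognormal(np.log(100), 1.0, 10_000)[:, None],
                             (10_000, 20))
        res = db.poisson_ma_test(counts, GROUPS_20)
        assert stats.kstest(res.p, "uniform").statistic < 0.05


def exact_oracle(s1, s2, n1, n2, phi):
    """Brute-force conditional NB two-sided p-value via scipy pmfs."""
    s = s1 + s2
    r1, r2 = n1 / phi, n2 / phi
    mu = 1.0  # conditional law does not depend on the shared mean
    k = np.arange(s + 1)
    w = stats.nbinom.pmf(k, r1, r1 / (r1 + n1 * mu)) * stats.nbinom.pmf(
        s - k, r2, r2 / (r2 + n2 * mu)
    )
    w = w / w.sum()
    obs = w[s1]
    return w[w <= obs * (1 + 1e-9)].sum()


class TestExactConditionalTest:
    @pytest.mark.parametrize("phi", [0.01, 0.1, 1.0])
    @pytest.mark.parametrize("n1,n2", [(1, 1), (3, 5)])
    def test_matches_enumeration_all_totals_to_30(self, phi, n1, n2):
        cases = [(s1, s - s1) for s in range(1, 31) for s1 in range(s + 1)]
        s1 = np.array([c[0] for c in cases])
        s2 = np.array([c[1] for c in cases])
        p = nb_conditional_pvalues(s1, s2, n1, n2, np.full(len(cases), phi))
        expected = np.array(
            [exact_oracle(a, b, n1, n2, phi) for a, b in cases]
        )
        assert np.max(np.abs(p - expected)) < 1e-8

    def test_small_instance_matches_enumeration(self):
        # single observed split 3 vs 12 of a total of 15, one sample per group
        p = nb_conditional_pvalues([3], [12], 1, 1, [0.1])[0]
        assert p == pytest.approx(exact_oracle(3, 12, 1, 1, 0.1), abs=1e-10)

    def test_monotone_in_signal(self):
        # doubling the group-2 sum never increases the p-value at fixed phi
        s2 = np.array([30, 60, 120, 240])
        p = nb_conditional_pvalues(
            np.full(4, 20), s2, 5, 5, np.full(4, 0.2)
        )
        assert np.all(np.diff(p) <= 1e-12)

    def test_zero_total_gets_p_one(self):
        assert nb_conditional_pvalues([0], [0], 5, 5, [0.1])[0] == 1.0


class TestNBExact:
    def test_identical_groups_p_one(self, balanced_identical):
        counts, group = balanced_identical
        res = db.nb_exact_test(counts, group)
        assert np.allclose(res.p, 1.0)

    def test_fixed_dispersion_mode(self, rng):
        counts = _nb(rng, 100.0, 0.2, (50, 8))
        res = db.nb_exact_test(counts, [1] * 4 + [2] * 4, dispersion=0.2)
        assert res.extra["dispersion"] == "fixed"
        assert np.all((res.p >= 0) & (res.p <= 1))

    def test_single_sample_groups_fall_back(self, rng, caplog):
        counts = _nb(rng, 100.0, 0.2, (40, 2))
        with caplog.at_level("WARNING"):
            res = db.nb_exact_test(counts, [1, 2])
        assert res.extra["dispersion"] == "common-only"
        assert "single sample" in caplog.text


class TestNBPooled:
    def test_trend_recovery(self, rng):
        # phi(mu) = 0.1 + 5/mu: the parametric trend recovers both terms
        G = 5000
        mu = rng.lognormal(np.log(100), 1.2, G)
        phi = 0.1 + 5.0 / mu
        counts = np.hstack(
            [_nb(rng, mu[:, None], phi[:, None], (G, 10)) for _ in range(2)]
        )
        res = db.nb_pooled_test(counts, GROUPS_20)
        assert res.extra["dispersion"] == "trend"
        assert res.extra["trend_a0"] == pytest.approx(5.0, rel=0.30)
        assert res.extra["trend_a1"] == pytest.approx(0.1, rel=0.30)

    def test_agrees_with_shrunken_exact_at_common_dispersion(self, rng):
        # forcing both pipelines onto the common dispersion gives equal p
        counts = _nb(rng, 150.0, 0.3, (80, 20))
        a = db.nb_pooled_test(counts, GROUPS_20, trend="common")
        b = db.nb_exact_test(counts, GROUPS_20, shrinkage_weight=1e9)
        assert np.max(np.abs(a.p - b.p)) < 1e-6

    def test_identical_groups_p_one(self, balanced_identical):
        counts, group = balanced_identical
        res = db.nb_pooled_test(counts, group)
        assert np.allclose(res.p, 1.0)


class TestNBP:
    def test_alpha_two_collapses_to_constant_dispersion(self, rng):
        counts = _nb(rng, 100.0, 0.3, (60, 8))
        group = [1] * 4 + [2] * 4
        a = db.nbp_test(counts, group, dispersion_params=(0.3, 2.0))
        b = db.nb_exact_test(counts, group, dispersion=0.3)
        assert np.max(np.abs(a.p - b.p)) < 1e-6

    def test_power_dispersion_recovery(self, rng):
        G = 5000
        mu = rng.lognormal(np.log(100), 1.2, G)
        phi = 2.0 * mu ** (1.5 - 2.0)
        counts = np.hstack(
            [_nb(rng, mu[:, None], phi[:, None], (G, 10)) for _ in range(2)]
        )
        res = db.nbp_test(counts, GROUPS_20)
        assert 1.3 <= res.extra["alpha"] <= 1.7

    def test_identical_groups_p_one(self, balanced_identical):
        counts, group = balanced_identical
        res = db.nbp_test(counts, group)
        assert np.allclose(res.p, 1.0)


class TestTwoStagePoisson:
    def test_stage_one_size_on_poisson_data(self, rng):
        mu = rng.lognormal(np.log(100), 1.0, 5000)
        counts = rng.poisson(mu[:, None], (5000, 20))
        res = db.two_stage_poisson(counts, GROUPS_20)
        assert 0.03 <= res.extra["overdispersed"].mean() <= 0.07

    def test_stage_one_power_on_nb_data(self, rng):
        counts = _nb(rng, 100.0, 0.5, (2000, 20))
        res = db.two_stage_poisson(counts, GROUPS_20)
        assert res.extra["overdispersed"].mean() > 0.8

    def test_identical_groups_p_one(self, balanced_identical):
        counts, group = balanced_identical
        res = db.two_stage_poisson(counts, group)
        assert np.allclose(res.p, 1.0)

    def test_requires_replicates(self, rng):
        with pytest.raises(ValueError, match="2 samples per group"):
            db.two_stage_poisson(_nb(rng, 50.0, 0.2, (10, 2)), [1, 2])


@pytest.fixture(scope="module")
def mixed_counts():
    rng = np.random.default_rng(4)
    mus = rng.lognormal(5.0, 1.5, 999)
    null = _nb(rng, mus[:, None], 0.3, (999, 8))
    strong = np.array([[100, 110, 90, 105, 1000, 950, 1100, 1050]])
    return np.vstack([strong, null]), [1] * 4 + [2] * 4


class TestEBPosterior:
    def test_seeded_runs_identical(self, mixed_counts):
        counts, group = mixed_counts
        a = db.eb_nb_posterior(counts, group, seed=7)
        b = db.eb_nb_posterior(counts, group, seed=7)
        assert np.array_equal(a.p, b.p)

    def test_unseeded_runs_differ(self, mixed_counts):
        counts, group = mixed_counts
        a = db.eb_nb_posterior(counts, group)
        b = db.eb_nb_posterior(counts, group)
        assert np.sum(a.p != b.p) >= 1

    def test_strong_signal_posterior(self, mixed_counts):
        counts, group = mixed_counts
        res = db.eb_nb_posterior(counts, group, n_hyper_samples=500, seed=3)
        assert res.extra["posterior_de"][0] > 0.99

    def test_no_direction_field(self, mixed_counts):
        counts, group = mixed_counts
        res = db.eb_nb_posterior(counts, group, seed=1)
        assert res.direction is None
        assert np.all(res.fc_estimate > 0)

    def test_invalid_hyper_count(self, mixed_counts):
        counts, group = mixed_counts
        with pytest.raises(ValueError, match="n_hyper_samples"):
            db.eb_nb_posterior(counts, group, n_hyper_samples=0)


@pytest.mark.parametrize("name", sorted(db.METHODS))
def test_every_method_valid_on_simulator_output(name, small_experiment):
    """Finite p in [0, 1] everywhere, including an injected all-zero gene."""
    e = small_experiment
    counts = np.vstack([e.counts, np.zeros((1, e.counts.shape[1]), dtype=int)])
    res = db.run_method(name, counts, e.group, seed=0)
    assert np.all(np.isfinite(res.p))
    assert np.all((res.p >= 0) & (res.p <= 1))
    assert np.all(np.isfinite(res.p_adjusted))
    assert np.all(res.fc_estimate > 0)
    # all-zero gene policy
    assert res.p[-1] == 1.0
    assert res.fc_estimate[-1] == 1.0
    if res.direction is not None:
        assert res.direction[-1] == 0


def test_run_method_unknown_name():
    with pytest.raises(KeyError, match="unknown method"):
        db.run_method("limma", np.ones((2, 4)), GROUPS_4)
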