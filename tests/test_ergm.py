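"""ERGM statistics, exact and MCMC fitting, simulation, goodness of fit."""
import itertools

import numpy as np
import pytest

from nucgraph.ergm import (
    DegeneracyError,
    ErgmError,
    ErgmFit,
    ErgmTerm,
    _Model,
    ergm_fit,
    ergm_gof,
    graph_statistics_vector,
    parse_terms,
    simulate_from_ergm,
)


def _random_adjacency(n, p, seed):
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, 1)
    return A + A.T


def brute_force_stats(A, terms, cov):
    """Sufficient statistics by direct enumeration."""
    n = A.shape[0]
    out = []
    for t in terms:
        if t.kind == "edges":
            out.append(sum(A[i, j] for i, j in
                           itertools.combinations(range(n), 2)))
        elif t.kind == "nodecov":
            x = cov[t.arg]
            out.append(sum((x[i] + x[j]) * A[i, j] for i, j in
                           itertools.combinations(range(n), 2)))
        elif t.kind == "absdiff":
            x = cov[t.arg]
            out.append(sum(abs(x[i] - x[j]) * A[i, j] for i, j in
                           itertools.combinations(range(n), 2)))
        elif t.kind == "degree":
            out.append(sum(1 for i in range(n) if A[i].sum() == t.arg))
        elif t.kind == "triangle":
            out.append(sum(1 for i, j, k in
                           itertools.combinations(range(n), 3)
                           if A[i, j] and A[j, k] and A[i, k]))
    return np.array(out, dtype=float)


class TestStatistics:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_terms_match_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        A = _random_adjacency(12, 0.3, seed)
        cov = {"x": rng.normal(0, 1, 12)}
        terms = parse_terms("edges,nodecov:x,absdiff:x,degree:2,triangle")
        got = graph_statistics_vector(A, terms, cov)
        expected = brute_force_stats(A, terms, cov)
        np.testing.assert_allclose(got, expected)

    def test_change_statistics_consistent_with_toggles(self):
        """delta = s(G + ij) - s(G - ij) for every dyad, every term."""
        rng = np.random.default_rng(9)
        A = _random_adjacency(10, 0.3, 5)
        cov = {"x": rng.normal(0, 1, 10)}
        terms = parse_terms("edges,nodecov:x,absdiff:x,degree:1,triangle")
        model = _Model(10, terms, cov)
        for i in range(10):
            for j in range(i + 1, 10):
                on = A.copy()
                on[i, j] = on[j, i] = 1
                off = A.copy()
                off[i, j] = off[j, i] = 0
                delta = model.statistics(on) - model.statistics(off)
                np.testing.assert_allclose(model.change(A, i, j), delta)

    def test_mutual_term_rejected(self):
        with pytest.raises(ErgmError, match="undirected"):
            parse_terms("edges,mutual")

    def test_unknown_term_rejected(self):
        with pytest.raises(ErgmError):
            parse_terms("edges,gwesp")


class TestExactFit:
    def test_edges_only_closed_form(self):
        A = _random_adjacency(15, 0.3, 2)
        d = A[np.triu_indices(15, 1)].mean()
        fit = ergm_fit(A, "edges")
        assert fit.theta[0] == pytest.approx(np.log(d / (1 - d)), abs=1e-6)
        assert fit.method == "exact-logistic"

    def test_nodecov_fit_beats_theta_grid(self):
        """Exact fit maximizes the full dyad-independent likelihood:
        no point on a grid around the optimum scores higher."""
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 12)
        A = _random_adjacency(12, 0.4, 4)
        fit = ergm_fit(A, "edges,nodecov:x", covariates={"x": x})

        def loglik(theta):
            ll = 0.0
            for i, j in itertools.combinations(range(12), 2):
                eta = theta[0] + theta[1] * (x[i] + x[j])
                ll += A[i, j] * eta - np.log1p(np.exp(eta))
            return ll

        best = loglik(fit.theta)
        for d0 in np.linspace(-0.3, 0.3, 7):
            for d1 in np.linspace(-0.3, 0.3, 7):
                assert loglik(fit.theta + [d0, d1]) <= best + 1e-9

    def test_se_and_p_against_reference_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 14)
        A = _random_adjacency(14, 0.4, 6)
        fit = ergm_fit(A, "edges,nodecov:x", covariates={"x": x})
        iu, ju = np.triu_indices(14, 1)
        X = np.column_stack([np.ones(len(iu)), x[iu] + x[ju]])
        ref = sm.Logit(A[iu, ju], X).fit(disp=0)
        np.testing.assert_allclose(fit.theta, ref.params, rtol=1e-5)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_missing_covariate_rejected(self):
        A = _random_adjacency(8, 0.3, 3)
        with pytest.raises(ErgmError, match="missing"):
            ergm_fit(A, "edges,nodecov:ctcf")

    def test_separation_raises_helpful_error(self):
        A = np.ones((8, 8), dtype=int) - np.eye(8, dtype=int)
        with pytest.raises(ErgmError, match="separation"):
            ergm_fit(A, "edges")


class TestSimulation:
    def test_zero_theta_density_half(self):
        draws, stats, _ = simulate_from_ergm(
            "edges", [0.0], 12, n_sims=400, burn_in=3000, thin=66, seed=1,
            return_stats=True)
        dens = stats[:, 0] / 66.0
        se = dens.std() / np.sqrt(len(dens))
        assert abs(dens.mean() - 0.5) < max(3 * se, 0.02)

    def test_dyad_frequency_matches_logistic_closed_form(self):
        theta = -2.0
        draws = simulate_from_ergm("edges", [theta], 20, n_sims=300,
                                   burn_in=5000, thin=150, seed=2)
        freq = np.mean([B[np.triu_indices(20, 1)].mean() for B in draws])
        expected = 1.0 / (1.0 + np.exp(-theta))
        assert freq == pytest.approx(expected, abs=0.01)

    def test_seed_determinism(self):
        a = simulate_from_ergm("edges", [-1.0], 10, n_sims=5, seed=7)
        b = simulate_from_ergm("edges", [-1.0], 10, n_sims=5, seed=7)
        for A, B in zip(a, b):
            np.testing.assert_array_equal(A, B)

    def test_incremental_stats_equal_recomputation(self):
        """The sampler's running statistics match full recomputation on
        every recorded draw."""
        rng = np.random.default_rng(3)
        cov = {"x": rng.normal(0, 1, 15)}
        terms = parse_terms("edges,nodecov:x,triangle")
        draws, stats, _ = simulate_from_ergm(
            terms, [-1.5, 0.4, 0.1], 15, covariates=cov, n_sims=20,
            burn_in=2000, thin=100, seed=4, return_stats=True)
        model = _Model(15, terms, {k: np.asarray(v) for k, v in cov.items()})
        for A, s in zip(draws, stats):
            np.testing.assert_allclose(model.statistics(A), s)

    def test_infinite_theta_rejected(self):
        with pytest.raises(ErgmError):
            simulate_from_ergm("edges", [np.inf], 10)


class TestMcmcMle:
    def test_agrees_with_exact_fit_within_3_mcse(self):
        """Key cross-validation: MCMC-MLE equals the exact logistic MLE
        on a dyad-independent model, n=30, seed 42."""
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 30)
        (A,) = simulate_from_ergm("edges,nodecov:x", [-2.0, 0.8], 30,
                                  covariates={"x": x}, n_sims=1,
                                  burn_in=30_000, thin=1, seed=42)
        exact = ergm_fit(A, "edges,nodecov:x", covariates={"x": x})
        mcmc = ergm_fit(A, "edges,nodecov:x", covariates={"x": x},
                        method="mcmc-mle", seed=42)
        for t_e, t_m, se_m in zip(exact.theta, mcmc.theta, mcmc.se):
            assert abs(t_e - t_m) < 3 * se_m
        assert mcmc.diagnostics["acceptance_rate"] > 0.05
        assert mcmc.diagnostics["ess_first_stat"] > 10

    def test_degree_term_runs_mcmc(self):
        A = _random_adjacency(15, 0.25, 9)
        fit = ergm_fit(A, "edges,degree:1", seed=5,
                       mcmc_params={"n_sims": 200, "burn_in": 4000,
                                    "thin": 50, "outer_iters": 2})
        assert fit.method == "mcmc-mle"
        assert np.all(fit.se > 0)

    def test_parameter_recovery_small(self):
        """Simulate-then-fit at modest size recovers the truth."""
        rng = np.random.default_rng(30)
        x = rng.normal(0, 1, 30)
        truth = np.array([-2.0, 0.8])
        draws = simulate_from_ergm("edges,nodecov:x", truth, 30,
                                   covariates={"x": x}, n_sims=60,
                                   burn_in=10_000, thin=800, seed=6)
        ests = np.array([
            ergm_fit(A, "edges,nodecov:x", covariates={"x": x}).theta
            for A in draws])
        mean = ests.mean(axis=0)
        mcse = ests.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(mean - truth) < 3 * mcse + 0.05)


class TestGof:
    def test_esp_of_triangle(self):
        from nucgraph.ergm import _esp_dist
        A = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        esp = _esp_dist(A, 2)
        assert esp[1] == 3  # each edge has exactly one shared partner

    def test_self_consistency_envelopes(self):
        """A fit evaluated against data simulated from itself stays
        inside the simulation envelopes for >= 90% of bins."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 25)
        (A,) = simulate_from_ergm("edges,nodecov:x", [-1.5, 0.5], 25,
                                  covariates={"x": x}, n_sims=1,
                                  burn_in=20_000, thin=1, seed=3)
        fit = ergm_fit(A, "edges,nodecov:x", covariates={"x": x})
        report = ergm_gof(A, fit, n_sims=100, seed=3)
        for stat in report.STATS:
            assert report.envelope_coverage(stat) >= 0.9

    def test_empty_graph_degree_spike(self):
        A = np.zeros((10, 10), dtype=int)
        fit = ErgmFit(terms=parse_terms("edges"), theta=np.array([-10.0]),
                      se=np.array([1.0]), p=np.array([0.0]),
                      method="exact-logistic", n_vertices=10)
        report = ergm_gof(A, fit, n_sims=50, seed=1)
        assert report.observed["degree"][0] == 10
        assert report.envelope_coverage("degree") == 1.0

    def test_fit_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10)
        A = _random_adjacency(10, 0.4, 5)
        fit = ergm_fit(A, "edges,nodecov:x", covariates={"x": x})
        path = str(tmp_path / "fit.json")
        fit.to_json(path)
        back = ErgmFit.from_json(path)
        np.testing.assert_allclose(back.theta, fit.theta)
        assert [t.label for t in back.terms] == [t.label for t in fit.terms]
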