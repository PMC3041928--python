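"""Additive-bias model: log joint, identification, DIC, recovery, variants."""

import numpy as np
import pytest
from scipy import stats

import biasblend as bb
from conftest import short_mcmc


@pytest.fixture
def tiny_state(small_table):
    rng = np.random.default_rng(1)
    A, S = small_table.y.shape
    return {
        "theta": np.array([21.5, 24.8, 23.1]),
        "mu": np.array([-0.8, 0.4, 1.6]),
        "tau": np.array([0.9, 1.1, 0.7]),
        "delta": rng.normal(0, 1, (A, S)),
    }


class TestLogJoint:
    def test_matches_brute_force_summation(self, small_table, tiny_state):
        priors = bb.PriorConfig()
        got = bb.log_joint_model1(tiny_state, small_table, priors)
        # independent hand-summed oracle, cell by cell
        expected = 0.0
        for i in range(3):
            for j in range(3):
                m = tiny_state["theta"][i] + tiny_state["delta"][i, j]
                expected += stats.norm.logpdf(small_table.y[i, j], m,
                                              small_table.se[i, j])
                expected += stats.norm.logpdf(tiny_state["delta"][i, j],
                                              tiny_state["mu"][j],
                                              tiny_state["tau"][j])
        for j in range(3):
            expected += stats.norm.logpdf(tiny_state["mu"][j], 0.0, 100.0)
            expected += -np.log(100.0)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_residual_free_configuration(self, small_table, tiny_state):
        # delta soaking up all residuals: data term is the zero-residual density
        state = dict(tiny_state)
        state["delta"] = small_table.y - state["theta"][:, None]
        comp = bb.log_joint_model1(state, small_table, components=True)
        expected = stats.norm.logpdf(0.0, 0.0, small_table.se).sum()
        assert comp["data"] == pytest.approx(expected, abs=1e-10)

    def test_shift_leaves_data_term_invariant(self, small_table, tiny_state):
        comp0 = bb.log_joint_model1(tiny_state, small_table, components=True)
        c = 3.7
        shifted = {
            "theta": tiny_state["theta"] + c,
            "mu": tiny_state["mu"] - c,
            "tau": tiny_state["tau"],
            "delta": tiny_state["delta"] - c,
        }
        comp1 = bb.log_joint_model1(shifted, small_table, components=True)
        assert comp1["data"] == pytest.approx(comp0["data"], abs=1e-10)

    def test_tau_outside_support_gives_minus_inf(self, small_table, tiny_state):
        for bad in (-0.5, 0.0, 150.0):
            state = dict(tiny_state)
            state["tau"] = np.array([0.9, bad, 0.7])
            assert bb.log_joint_model1(state, small_table) == -np.inf


class TestRecenterDraws:
    @pytest.fixture
    def raw_draws(self):
        rng = np.random.default_rng(3)
        return {
            "theta": rng.normal(30, 5, (2, 40, 6)),
            "mu": rng.normal(0, 2, (2, 40, 4)),
            "delta": rng.normal(0, 1, (2, 40, 6, 4)),
        }

    def test_mean_equals_anchor_in_every_draw(self, raw_draws):
        out = bb.recenter_draws(raw_draws, 23.0)
        np.testing.assert_allclose(out["theta"].mean(axis=-1), 23.0, atol=1e-9)

    def test_pairwise_differences_unchanged(self, raw_draws):
        out = bb.recenter_draws(raw_draws, 23.0)
        np.testing.assert_allclose(
            out["theta"][..., 0] - out["theta"][..., 3],
            raw_draws["theta"][..., 0] - raw_draws["theta"][..., 3], atol=1e-12)

    def test_cell_means_invariant(self, raw_draws):
        out = bb.recenter_draws(raw_draws, 23.0)
        before = raw_draws["theta"][..., None] + raw_draws["delta"]
        after = out["theta"][..., None] + out["delta"]
        np.testing.assert_allclose(after, before, atol=1e-12)


class TestDic:
    def test_point_posterior_has_zero_pd(self, small_table):
        cm = np.tile(small_table.y[None, None], (1, 10, 1, 1))
        dic = bb.compute_dic({"cell_mean": cm}, small_table)
        assert dic["pD"] == pytest.approx(0.0, abs=1e-9)
        assert dic["DIC"] == pytest.approx(dic["Dbar"], abs=1e-9)

    def test_identity_holds_on_real_fit(self, small_table):
        post = bb.fit_model1(small_table, mcmc=short_mcmc(0, 600, 200))
        assert post.dic["DIC"] == pytest.approx(
            post.dic["Dbar"] + post.dic["pD"], abs=1e-9)

    def test_too_few_draws_rejected(self, small_table):
        with pytest.raises(ValueError, match="2 retained draws"):
            bb.compute_dic({"cell_mean": small_table.y[None, None]}, small_table)


class TestModel1Fit:
    def test_noiseless_additive_recovers_bias_means(self):
        theta = np.array([20.0, 22.0, 24.0, 26.0, 23.0, 21.0, 25.0, 23.0])
        mu = np.array([1.5, -2.0, 0.5])
        y = theta[:, None] + mu[None, :]
        t = bb.EstimateTable([f"a{i}" for i in range(8)], list("pqr"),
                             y, np.full((8, 3), 0.05))
        post = bb.fit_model1(t, anchor=float(theta.mean()),
                             mcmc=short_mcmc(1, 1500, 500))
        mcse = post.summary.set_index("parameter").mcse
        for j, lab in enumerate("pqr"):
            tol = max(3 * float(mcse[f"mu[{lab}]"]), 0.02)
            assert post.mu_mean[j] == pytest.approx(mu[j], abs=tol)
        np.testing.assert_array_less(post.tau_mean, 0.2)

    def test_anchor_constraint_holds_in_every_draw(self, small_table):
        post = bb.fit_model1(small_table, anchor=24.0,
                             mcmc=short_mcmc(2, 600, 200))
        np.testing.assert_allclose(post.draws["theta"].mean(axis=-1), 24.0,
                                   atol=1e-9)

    def test_anchor_shift_equivariance(self, default_table):
        # same seed: raw chains coincide, so the shift is exact
        table, _ = default_table
        p23 = bb.fit_model1(table, anchor=23.0, mcmc=short_mcmc(3))
        p25 = bb.fit_model1(table, anchor=25.0, mcmc=short_mcmc(3))
        np.testing.assert_allclose(p25.theta_mean - p23.theta_mean, 2.0,
                                   atol=1e-9)
        np.testing.assert_allclose(
            p25.theta_mean[:-1] - p25.theta_mean[1:],
            p23.theta_mean[:-1] - p23.theta_mean[1:], atol=1e-9)

    def test_posterior_ssr_near_cell_count(self, default_table):
        table, _ = default_table
        post = bb.fit_model1(table, mcmc=short_mcmc(4))
        n_cells = int(table.present.sum())
        assert abs(post.ssr - n_cells) < 3 * np.sqrt(2 * n_cells)

    def test_se_misstatement_compensated_by_tau(self, default_table):
        # doubling one source's stated SEs: the marginal cell variance
        # sigma^2 + tau^2 for that source should move by far less
        table, _ = default_table
        post = bb.fit_model1(table, mcmc=short_mcmc(5))
        j = 0  # smallest stated SEs, substantial bias SD
        inflated = table.copy()
        inflated.se[:, j] *= 2.0
        post2 = bb.fit_model1(inflated, mcmc=short_mcmc(5))
        v1 = (table.se2[:, j] + post.tau_mean[j] ** 2).mean()
        v2 = (inflated.se2[:, j] + post2.tau_mean[j] ** 2).mean()
        assert abs(v2 - v1) / v1 < 0.25


class TestVariants:
    def test_equal_tau_recovers_common_value(self):
        cfg = bb.SimConfig(seed=31, tau=(1.2,) * 7)
        table, _ = bb.simulate_dataset(cfg)
        post = bb.fit_model1_variant(table, "equal_tau", mcmc=short_mcmc(6))
        mcse = post.summary.set_index("parameter").mcse
        sd = post.summary.set_index("parameter").sd
        lab = table.source_labels[0]
        tol = 3 * float(mcse[f"tau[{lab}]"]) + 2 * float(sd[f"tau[{lab}]"])
        assert post.tau_mean[0] == pytest.approx(1.2, abs=tol)
        assert np.ptp(post.tau_mean) < 1e-9  # single shared parameter

    def test_anchored_source_matches_anchor_identification(self):
        # generating mean bias of the anchored source is 0, so the two
        # identification strategies should agree after recentring
        cfg = bb.SimConfig(seed=32, mu=(2.5, -2.5, -2.0, -1.5, 0.5, 0.0, 0.3))
        table, truth = bb.simulate_dataset(cfg)
        pa = bb.fit_model1_variant(table, "anchored_source", source="HP02",
                                   mcmc=short_mcmc(7, 1400, 400))
        p1 = bb.fit_model1(table, mcmc=short_mcmc(8, 1400, 400))
        ca = pa.theta_mean - pa.theta_mean.mean()
        c1 = p1.theta_mean - p1.theta_mean.mean()
        assert np.abs(ca - c1).max() < 0.25
        assert pa.mu_mean[table.source_labels.index("HP02")] == 0.0

    def test_exchangeable_tau_runs_with_two_sources(self):
        cfg = bb.SimConfig(n_areas=10, n_sources=2, seed=33, mu=(1.0, -1.0),
                           tau=(1.0, 1.0), se_range=(0.5, 1.0))
        table, _ = bb.simulate_dataset(cfg)
        post = bb.fit_model1_variant(table, "exchangeable_tau",
                                     mcmc=short_mcmc(9, 700, 250))
        st = post.draws["sigma_tau"]
        assert np.isfinite(st).all() and (st > 0).all()

    def test_unknown_variant_and_source_rejected(self, small_table):
        with pytest.raises(ValueError, match="variant"):
            bb.fit_model1_variant(small_table, "nonsense")
        with pytest.raises(ValueError, match="source"):
            bb.fit_model1_variant(small_table, "anchored_source",
                                  source="not-there")


class TestSamplerCrossChecks:
    def test_marginal_and_hierarchical_backends_agree(self):
        cfg = bb.SimConfig(n_areas=8, n_sources=3, seed=5,
                           sample_sizes=(3000, 2000, 1000))
        table, _ = bb.simulate_dataset(cfg)
        pc = bb.fit_model1(table, mcmc=short_mcmc(3, 2200, 600))
        ph = bb.fit_model1(table, mcmc=short_mcmc(4, 3500, 1200),
                           sampler="hierarchical")
        assert np.abs(pc.theta_mean - ph.theta_mean).max() < 0.15
        assert np.abs(pc.mu_mean - ph.mu_mean).max() < 0.2
        assert np.abs(pc.tau_mean - ph.tau_mean).max() < 0.3

    def test_against_independent_ensemble_sampler(self):
        emcee = pytest.importorskip("emcee")
        cfg = bb.SimConfig(n_areas=4, n_sources=3, seed=8,
                           sample_sizes=(2000, 1000, 800))
        table, _ = bb.simulate_dataset(cfg)
        A, S = 4, 3
        y, se2 = table.y, table.se2

        def logpost(p):
            theta, mu, tau = p[:A], p[A:A + S], p[A + S:]
            if np.any(tau <= 0) or np.any(tau >= 100):
                return -np.inf
            v = se2 + (tau ** 2)[None, :]
            ll = -0.5 * np.sum(np.log(2 * np.pi * v)
                               + (y - theta[:, None] - mu[None, :]) ** 2 / v)
            return ll + stats.norm.logpdf(mu, 0, 100).sum()

        nw = 32
        rng = np.random.default_rng(1)
        p0 = np.concatenate([np.full(A, 23.0), np.zeros(S), np.ones(S)])
        start = p0 + rng.normal(0, 0.3, (nw, A + 2 * S))
        start[:, A + S:] = np.abs(start[:, A + S:]) + 0.2
        sampler = emcee.EnsembleSampler(nw, A + 2 * S, logpost)
        sampler._random = np.random.RandomState(2)  # deterministic run
        sampler.run_mcmc(start, 6000, progress=False)
        chain = sampler.get_chain(discard=2500, flat=False)  # (steps, nw, d)
        flat = chain.reshape(-1, A + 2 * S)
        th = flat[:, :A]
        phi = th.mean(axis=1) - 23.0
        th = th - phi[:, None]
        mu = flat[:, A:A + S] + phi[:, None]
        post = bb.fit_model1(table, mcmc=short_mcmc(2, 2500, 700))

        # tolerance from the actual Monte Carlo error of both samplers
        import arviz as az

        def mc_se(arr3):  # (chains, draws, k) -> per-parameter MCSE of mean
            ds = az.convert_to_dataset({"v": arr3})
            ess = np.asarray(az.ess(ds)["v"]).reshape(-1)
            sd = arr3.reshape(-1, arr3.shape[-1]).std(axis=0, ddof=1)
            return sd / np.sqrt(np.maximum(ess, 4))

        em_th = np.swapaxes(chain[..., :A] - phi.reshape(
            chain.shape[0], nw, 1), 0, 1)
        em_mu = np.swapaxes(chain[..., A:A + S] + phi.reshape(
            chain.shape[0], nw, 1), 0, 1)
        tol_th = 6 * np.hypot(mc_se(em_th), mc_se(post.draws["theta"]))
        tol_mu = 6 * np.hypot(mc_se(em_mu), mc_se(post.draws["mu"]))
        assert np.all(np.abs(th.mean(axis=0) - post.theta_mean) < tol_th)
        assert np.all(np.abs(mu.mean(axis=0) - post.mu_mean) < tol_mu)

    def test_nonconvergence_is_flagged_not_raised(self, default_table):
        table, _ = default_table
        with pytest.warns(bb.ConvergenceWarning):
            post = bb.fit_model1(table, mcmc=bb.McmcConfig(
                n_chains=2, n_iter=60, n_burnin=20, seed=0))
        assert not post.converged
        assert post.convergence["flagged"]


class TestEstimatorInterface:
    def test_sklearn_contract(self, small_table):
        from sklearn.base import clone
        est = bb.AdditiveBiasModel(anchor=24.0, mcmc=short_mcmc(0, 400, 150))
        cloned = clone(est)
        assert cloned.get_params()["anchor"] == 24.0
        cloned.set_params(anchor=22.0)
        fitted = cloned.fit(small_table)
        assert fitted.theta_.mean() == pytest.approx(22.0, abs=1e-9)
        assert fitted.posterior_.model == "model1"
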