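"""Latent Markov model: emissions, recursions, EM, standard errors,
decoding — each checked against closed forms or enumeration oracles."""

import dataclasses

import numpy as np
import pytest

import fecundlmm as f
from fecundlmm.lm import _em_run, _standardize
from conftest import random_panel
from oracles import enum_loglik, enum_posteriors, enum_path_probs


class TestEmission:
    def test_closed_forms(self):
        p = f.LMParameters(pi=[0.5, 0.5], Pi=np.eye(2), mu=0.0, alpha2=0.0,
                           beta=np.zeros(2))
        assert f.emission_probability(np.zeros(2), 1, p) == pytest.approx(0.5)
        p2 = dataclasses.replace(p, alpha2=2.0)
        assert f.emission_probability(np.zeros(2), 2, p2) == \
            pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)

    def test_state2_dominates_state1(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = f.LMParameters(pi=[0.5, 0.5], Pi=np.eye(2), mu=rng.normal(),
                               alpha2=rng.uniform(0, 4),
                               beta=rng.normal(size=3))
            x = rng.normal(size=3)
            assert f.emission_probability(x, 2, p) >= \
                f.emission_probability(x, 1, p)

    def test_dimension_mismatch(self):
        p = f.LMParameters(pi=[0.5, 0.5], Pi=np.eye(2), mu=0.0, alpha2=1.0,
                           beta=np.zeros(3))
        with pytest.raises(ValueError):
            f.emission_probability(np.zeros(2), 1, p)


class TestForwardBackward:
    def test_T1_closed_form(self):
        rng = np.random.default_rng(1)
        panel, params = random_panel(rng, n=6, T=1, equal_lengths=True)
        post = f.forward_backward(panel, params)
        for i in range(panel.n):
            x, y = panel.X[i], panel.Y[i, 0]
            probs = np.array([
                params.pi[u] * (f.emission_probability(x, u + 1, params)
                                if y == 1 else
                                1 - f.emission_probability(x, u + 1, params))
                for u in (0, 1)])
            np.testing.assert_allclose(post.gamma[i, 0], probs / probs.sum(),
                                       rtol=1e-12)
        lls = [np.log(sum(enum_path_probs(panel.Y[i, :1], panel.X[i],
                                          params)[1]))
               for i in range(panel.n)]
        assert post.loglik == pytest.approx(sum(lls), rel=1e-12)

    def test_frozen_chain_gamma_constant(self):
        rng = np.random.default_rng(2)
        panel, params = random_panel(rng, n=8, T=5)
        params = dataclasses.replace(params, Pi=np.eye(2))
        post = f.forward_backward(panel, params)
        for i in range(panel.n):
            T = panel.lengths[i]
            g = post.gamma[i, :T, :]
            np.testing.assert_allclose(g, np.broadcast_to(g[0], g.shape),
                                       atol=1e-12)

    def test_zero_probability_sequence(self):
        params = f.LMParameters(pi=[1.0, 0.0], Pi=np.eye(2), mu=-60.0,
                                alpha2=0.0, beta=np.zeros(1))
        panel = f.PanelData(X=np.zeros((1, 1)), Y=np.array([[1.0]]),
                            lengths=np.array([1]))
        post = f.forward_backward(panel, params)
        assert np.isfinite(post.loglik)  # clipped emission, not an exception
        params2 = dataclasses.replace(params, pi=np.array([0.0, 1.0]),
                                      alpha2=np.inf)
        # a structurally impossible state assignment yields -inf, no raise
        s = f.complete_data_loglik(panel, np.array([[1]]), params2)
        assert s == -np.inf

    def test_xi_marginalizes_to_gamma(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            panel, params = random_panel(rng, n=4, T=5)
            post = f.forward_backward(panel, params)
            for i in range(panel.n):
                for t in range(panel.lengths[i] - 1):
                    np.testing.assert_allclose(post.xi[i, t].sum(axis=1),
                                               post.gamma[i, t], atol=1e-10)
                    np.testing.assert_allclose(post.xi[i, t].sum(axis=0),
                                               post.gamma[i, t + 1], atol=1e-10)


class TestCompleteDataLoglik:
    def test_single_couple_two_terms(self):
        rng = np.random.default_rng(4)
        panel, params = random_panel(rng, n=1, T=1, equal_lengths=True)
        got = f.complete_data_loglik(panel, np.array([[1]]), params)
        phi = f.emission_probability(panel.X[0], 1, params)
        want = np.log(params.pi[0]) + np.log(phi if panel.Y[0, 0] == 1
                                             else 1 - phi)
        assert got == pytest.approx(want, rel=1e-10)

    def test_marginalization_identity(self):
        # summing exp(complete-data loglik) over all paths gives the
        # manifest likelihood
        rng = np.random.default_rng(5)
        import itertools

        for _ in range(10):
            panel, params = random_panel(rng, n=3, T=4)
            manifest = f.forward_backward(panel, params).loglik
            total = 1.0
            for i in range(panel.n):
                T = panel.lengths[i]
                sub = f.PanelData(X=panel.X[i:i + 1],
                                  Y=panel.Y[i:i + 1, :T],
                                  lengths=np.array([T]))
                s = 0.0
                for path in itertools.product([1, 2], repeat=T):
                    states = np.array([path])
                    s += np.exp(f.complete_data_loglik(sub, states, params))
                total *= s
            assert manifest == pytest.approx(np.log(total), rel=1e-9)

    def test_couple_order_invariance(self):
        rng = np.random.default_rng(6)
        panel, params = random_panel(rng, n=5, T=3, equal_lengths=True)
        states = rng.integers(1, 3, size=(5, 3))
        v1 = f.complete_data_loglik(panel, states, params)
        perm = rng.permutation(5)
        panel2 = f.PanelData(X=panel.X[perm], Y=panel.Y[perm],
                             lengths=panel.lengths[perm])
        v2 = f.complete_data_loglik(panel2, states[perm], params)
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestESrep:
    def test_degenerate_params_all_mass_state1(self):
        rng = np.random.default_rng(7)
        panel, params = random_panel(rng, n=5, T=4)
        params = dataclasses.replace(params, pi=np.array([1.0, 0.0]),
                                     Pi=np.eye(2))
        post = f.e_step(panel, params)
        mask = panel.mask()
        assert np.allclose(post.gamma[:, :, 0][mask], 1.0)

    def test_counts_normalize(self):
        rng = np.random.default_rng(8)
        panel, params = random_panel(rng, n=30, T=4)
        post = f.e_step(panel, params)
        assert post.gamma[:, 0, :].sum() == pytest.approx(panel.n, rel=1e-10)

    def test_agrees_with_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            panel, params = random_panel(rng, n=4, T=6)
            post = f.e_step(panel, params)
            want = enum_posteriors(panel, params)
            mask = panel.mask()
            np.testing.assert_allclose(post.gamma[mask], want[mask],
                                       atol=1e-10)


class TestMStep:
    def test_transitions_from_deterministic_path(self):
        # posterior concentrated on one known path -> transition update is
        # that path's empirical transition frequency
        rng = np.random.default_rng(10)
        panel, params = random_panel(rng, n=1, T=6, equal_lengths=True)
        path = np.array([0, 0, 1, 1, 0, 0])
        post = f.e_step(panel, params)
        post.gamma[...] = 0.0
        post.gamma[0, np.arange(6), path] = 1.0
        post.xi[...] = 0.0
        for t in range(5):
            post.xi[0, t, path[t], path[t + 1]] = 1.0
        new = f.m_step(post, panel, params)
        np.testing.assert_allclose(new.Pi[0], [2 / 3, 1 / 3], atol=1e-12)
        np.testing.assert_allclose(new.Pi[1], [1 / 2, 1 / 2], atol=1e-12)
        np.testing.assert_allclose(new.pi, [1.0, 0.0], atol=1e-12)

    def test_matches_classic_reestimate_without_covariates(self):
        # with no covariates the measurement update must equal the classic
        # Baum-Welch emission re-estimate  p_u = sum(gamma*y)/sum(gamma)
        rng = np.random.default_rng(11)
        n, T = 40, 5
        Y = rng.integers(0, 2, size=(n, T)).astype(float)
        panel = f.PanelData(X=np.zeros((n, 0)), Y=Y, lengths=np.full(n, T))
        params = f.LMParameters(pi=[0.6, 0.4],
                                Pi=[[0.7, 0.3], [0.2, 0.8]],
                                mu=-0.3, alpha2=1.2, beta=np.zeros(0))
        post = f.e_step(panel, params)
        new = f.m_step(post, panel, params)
        for u in (0, 1):
            w = post.gamma[:, :, u].ravel()
            p_hat = float(np.sum(w * Y.ravel()) / np.sum(w))
            z = new.mu + (new.alpha2 if u == 1 else 0.0)
            assert 1 / (1 + np.exp(-z)) == pytest.approx(p_hat, abs=1e-8)

    def test_em_step_never_decreases_loglik(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            panel, params = random_panel(rng, n=30, T=4)
            ll0 = f.forward_backward(panel, params).loglik
            post = f.e_step(panel, params)
            new = f.m_step(post, panel, params)
            ll1 = f.forward_backward(panel, new).loglik
            assert ll1 >= ll0 - 1e-8


class TestFitEM:
    def test_recovers_alpha2_within_3se(self, medium_fit):
        panel, sim, fit = medium_fit
        se = f.standard_errors(panel, fit.params)
        assert abs(fit.params.alpha2 - 2.0) < 3 * se["alpha2"]

    def test_trace_monotone_on_every_start(self, medium_fit):
        _, _, fit = medium_fit
        for tr in [fit.loglik_trace] + fit.start_traces:
            d = np.diff(tr)
            assert np.all(d >= -1e-8 * (np.abs(tr[1:]) + 1))

    def test_fitted_loglik_dominates_truth(self, medium_fit, ref_params):
        panel, _, fit = medium_fit
        assert fit.loglik >= f.forward_backward(panel, ref_params).loglik

    def test_relabeling_preserves_likelihood(self, medium_fit):
        panel, _, fit = medium_fit
        q = fit.params
        swapped = f.LMParameters(pi=q.pi[::-1], Pi=q.Pi[::-1, ::-1],
                                 mu=q.mu + q.alpha2, alpha2=-q.alpha2,
                                 beta=q.beta)
        ll1 = f.forward_backward(panel, q).loglik
        ll2 = f.forward_backward(panel, swapped.relabeled()).loglik
        assert ll1 == pytest.approx(ll2, rel=1e-12)
        assert swapped.relabeled().alpha2 >= 0

    def test_empty_panel_rejected(self):
        panel = f.PanelData(X=np.zeros((1, 1)), Y=np.array([[0.0]]),
                            lengths=np.array([1]))
        with pytest.raises(ValueError):
            f.fit_em(f.PanelData(X=np.zeros((0, 1)),
                                 Y=np.zeros((0, 1)),
                                 lengths=np.zeros(0, dtype=int)))


class TestAgainstPlainHMM:
    def test_matches_hmmlearn_without_covariates(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(13)
        n, T = 200, 6
        # well-separated two-state Bernoulli HMM
        truth = f.LMParameters(pi=[0.6, 0.4], Pi=[[0.85, 0.15], [0.25, 0.75]],
                               mu=-2.0, alpha2=4.0, beta=np.zeros(0))
        states = np.zeros((n, T), dtype=int)
        Y = np.zeros((n, T))
        for i in range(n):
            s = int(rng.uniform() < truth.pi[1])
            for t in range(T):
                if t:
                    s = int(rng.uniform() < truth.Pi[s, 1])
                states[i, t] = s
                p = 1 / (1 + np.exp(-(truth.mu + truth.alpha2 * s)))
                Y[i, t] = float(rng.uniform() < p)
        panel = f.PanelData(X=np.zeros((n, 0)), Y=Y, lengths=np.full(n, T))
        ours = f.fit_em(panel, n_random_starts=5, seed=0)

        best = -np.inf
        obs = Y.astype(int).reshape(-1, 1)
        lengths = [T] * n
        for s in range(5):
            m = hmmlearn.CategoricalHMM(n_components=2, n_iter=500,
                                        tol=1e-8, random_state=s)
            m.fit(obs, lengths)
            best = max(best, m.score(obs, lengths))
        assert ours.loglik >= best - 0.05
        assert abs(ours.loglik - best) < 2.0


class TestLogisticCollapse:
    def test_alpha2_zero_equals_pooled_logit(self, ref_params):
        statsmodels = pytest.importorskip("statsmodels.api")
        cov = f.simulate_covariates(1500, seed=31)
        sim = f.simulate_lm_sequences(ref_params, cov, T_max=4, seed=32,
                                      absorbing=False)
        panel = f.PanelData.from_simulated(sim)
        fit = f.fit_em(panel, n_random_starts=2, seed=33, fix_alpha2=0.0)

        mask = panel.mask()
        ii, tt = np.nonzero(mask)
        X = np.column_stack([np.ones(ii.size), panel.X[ii]])
        y = panel.Y[ii, tt]
        sm_fit = statsmodels.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params.beta, sm_fit.params[1:],
                                   atol=1e-4)
        assert fit.params.mu == pytest.approx(sm_fit.params[0], abs=1e-4)


@pytest.fixture(scope="module")
def se_fits(ref_params):
    """Fits and observed-information SEs at n = 500, 2000, 8000."""
    out = {}
    for n in (500, 2000, 8000):
        cov = f.simulate_covariates(n, seed=50)
        sim = f.simulate_lm_sequences(ref_params, cov, T_max=4, seed=51,
                                      absorbing=False)
        panel = f.PanelData.from_simulated(sim)
        fit = f.fit_em(panel, n_random_starts=1, seed=52)
        out[n] = (panel, fit.params, f.standard_errors(panel, fit.params))
    return out


class TestStandardErrors:
    def test_shrink_as_sqrt_n(self, se_fits):
        for key in ("beta_intercourse_freq", "beta_woman_age"):
            r1 = se_fits[500][2][key] / se_fits[2000][2][key]
            r2 = se_fits[2000][2][key] / se_fits[8000][2][key]
            assert 1.3 < r1 < 3.1 and 1.3 < r2 < 3.1  # ~ sqrt(4) = 2

    def test_couple_order_invariance(self, se_fits):
        panel, params, se = se_fits[500]
        perm = np.random.default_rng(0).permutation(panel.n)
        panel2 = f.PanelData(X=panel.X[perm], Y=panel.Y[perm],
                             lengths=panel.lengths[perm],
                             covariate_names=panel.covariate_names)
        se2 = f.standard_errors(panel2, params)
        # finite-difference Hessians amplify summation-order noise
        for k in se:
            assert se[k] == pytest.approx(se2[k], rel=1e-4)

    def test_intercourse_se_near_published_scale(self, ref_params):
        # at the cohort's size the SE of the intercourse-frequency effect
        # should be on the printed scale (0.0377), within a factor 1.5
        cov = f.simulate_covariates(673, seed=60)
        sim = f.simulate_lm_sequences(ref_params, cov, T_max=4, seed=61,
                                      absorbing=False)
        panel = f.PanelData.from_simulated(sim)
        fit = f.fit_em(panel, n_random_starts=4, seed=62)
        se = f.standard_errors(panel, fit.params)
        assert 0.0377 / 1.5 < se["beta_intercourse_freq"] < 0.0377 * 1.5


class TestDecode:
    def test_posterior_argmax_and_tie_to_state1(self):
        rng = np.random.default_rng(14)
        panel, params = random_panel(rng, n=6, T=3)
        post = f.forward_backward(panel, params)
        states = f.decode_states(panel, params)
        mask = panel.mask()
        want = np.where(post.gamma[:, :, 1] > post.gamma[:, :, 0], 2, 1)
        np.testing.assert_array_equal(states[mask], want[mask])
        assert (states[~mask] == 0).all()

    def test_frozen_chain_constant_decoding(self):
        rng = np.random.default_rng(15)
        panel, params = random_panel(rng, n=10, T=5)
        params = dataclasses.replace(params, Pi=np.eye(2))
        states = f.decode_states(panel, params)
        for i in range(panel.n):
            T = panel.lengths[i]
            assert len(set(states[i, :T])) == 1

    def test_accuracy_with_separated_states(self, ref_params):
        params = dataclasses.replace(ref_params, alpha2=3.0)
        cov = f.simulate_covariates(800, seed=70)
        sim = f.simulate_lm_sequences(params, cov, T_max=4, seed=71,
                                      absorbing=False)
        panel = f.PanelData.from_simulated(sim)
        decoded = f.decode_states(panel, params)
        mask = panel.mask()
        acc = (decoded[mask] == sim.states[mask]).mean()
        assert acc > 0.8
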