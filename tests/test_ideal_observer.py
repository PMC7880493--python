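import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.special import logsumexp

from itdppc import (
    Posterior,
    StimulusParams,
    generate_stimulus,
    make_prior,
    posterior_summaries,
    post_marg_loglik,
    post_marg_logpost,
    pre_marg_loglik,
    pre_marg_logpost,
    simulate_ears,
    sufficient_stats,
)
from itdppc.ideal_observer import DelayGrid

from conftest import DT_US, toy_params


class TestSufficientStats:
    def test_identical_channels_zero_lag(self, toy_grid):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(32)
        stats = sufficient_stats(s, s, toy_grid)
        # CC(0) = s.s = 2V only when both channels carry the same energy
        assert stats.cc[4] == pytest.approx(np.dot(s, s))
        assert stats.v == pytest.approx(np.dot(s, s))

    def test_matches_brute_force_double_loop(self, toy_grid):
        rng = np.random.default_rng(3)
        t = 16
        s_r, s_l = rng.standard_normal((2, t))
        stats = sufficient_stats(s_r, s_l, toy_grid)
        for k, d in enumerate(toy_grid.delta_samples):
            direct = sum(s_r[i] * s_l[(i + d) % t] for i in range(t))
            assert stats.cc[k] == pytest.approx(direct)
        assert stats.v == pytest.approx(
            0.5 * (np.sum(s_r**2) + np.sum(s_l**2))
        )

    def test_cauchy_schwarz_bound(self, box_grid):
        p = StimulusParams.from_bc(0.9, duration=0.001, seed=8)
        s_r, s_l = simulate_ears(p, 200)
        stats = sufficient_stats(s_r, s_l, box_grid)
        assert np.all(np.abs(stats.cc) / stats.v[:, None] <= 1.0 + 1e-9)

    def test_empty_rejected(self, toy_grid):
        with pytest.raises(ValueError):
            sufficient_stats(np.empty(0), np.empty(0), toy_grid)


class TestPreMarginalization:
    def test_matches_dense_gaussian_oracle(self, toy_grid):
        """The cross-covariance form equals the full 2T x 2T Gaussian
        log-likelihood up to a delta-independent constant."""
        t = 16
        p = toy_params(t=t, seed=3)
        stim = generate_stimulus(p)
        stats = sufficient_stats(stim.s_r, stim.s_l, toy_grid)
        ll = pre_marg_loglik(stats, p.sigma_s, p.sigma_n, p.sigma_0)
        se2 = p.sigma_n**2 + p.sigma_0**2
        x = np.concatenate([stim.s_r, stim.s_l])
        oracle = []
        for d in toy_grid.delta_samples:
            perm = np.zeros((t, t))
            for i in range(t):
                perm[(i + d) % t, i] = 1.0  # (P s)(i) = s(i - d)
            cross = p.sigma_s**2 * perm.T  # E[s_R s_L^T]
            cov = np.block([
                [(p.sigma_s**2 + se2) * np.eye(t), cross],
                [cross.T, (p.sigma_s**2 + se2) * np.eye(t)],
            ])
            _, logdet = np.linalg.slogdet(cov)
            oracle.append(
                -0.5 * x @ np.linalg.solve(cov, x) - 0.5 * logdet
            )
        oracle = np.asarray(oracle)
        diff_impl = ll - ll[0]
        diff_oracle = oracle - oracle[0]
        np.testing.assert_allclose(
            diff_impl, diff_oracle,
            rtol=1e-8, atol=1e-8 * np.abs(diff_oracle).max(),
        )

    def test_no_signal_gives_prior(self, toy_grid):
        p = toy_params(sigma_s=0.0, sigma_n=1.0, delta_samples=0, seed=1)
        stim = generate_stimulus(p)
        stats = sufficient_stats(stim.s_r, stim.s_l, toy_grid)
        post = pre_marg_logpost(stats, 0.0, 1.0, p.sigma_0, toy_grid)
        np.testing.assert_allclose(post.log_post, toy_grid.log_prior)

    def test_loglik_linear_in_cc(self, toy_grid):
        p = toy_params(seed=5)
        stim = generate_stimulus(p)
        stats = sufficient_stats(stim.s_r, stim.s_l, toy_grid)
        ll = pre_marg_loglik(stats, p.sigma_s, p.sigma_n, p.sigma_0)
        doubled = sufficient_stats(stim.s_r * 2, stim.s_l, toy_grid)
        ll2 = pre_marg_loglik(doubled, p.sigma_s, p.sigma_n, p.sigma_0)
        np.testing.assert_allclose(ll2 - ll2[0], 2 * (ll - ll[0]), rtol=1e-10)

    def test_zero_noise_rejected(self, toy_grid):
        p = toy_params(seed=0)
        stim = generate_stimulus(p)
        stats = sufficient_stats(stim.s_r, stim.s_l, toy_grid)
        with pytest.raises(ValueError):
            pre_marg_loglik(stats, 1.0, 0.0, 0.0)


class TestPostMarginalization:
    def test_zero_cc_first_term_vanishes(self):
        lm = post_marg_loglik(np.array([[0.0]]), np.array([32.0]), 32)
        # only the split-probability terms remain: log P(g+>=c) + log P(c>=g-)
        from itdppc._special import log_gammainc_lower, log_gammaincc

        s = 16.0
        expected = log_gammaincc(s, np.array([s])) + log_gammainc_lower(
            s, np.array([s])
        )
        assert lm[0, 0] == pytest.approx(expected[0])

    def test_monotone_increasing_in_cc(self):
        v, t = 48.0, 48
        cc = np.linspace(0.0, 0.95 * v, 60)[None, :]
        lm = post_marg_loglik(cc, np.array([v]), t)
        assert np.all(np.diff(lm[0]) > 0)

    def test_matches_quadrature_oracle_near_mode(self, rng):
        """Marginalized posterior vs direct 2-D quadrature over the
        (sigma_S, sigma_N) nuisance grid with the flat-in-Gamma-parameter
        improper prior, on informative T=32 stimuli."""
        t, n_seeds = 32, 12
        k = 6
        deltas = np.arange(-k, k + 1) * DT_US
        grid = DelayGrid(deltas, np.full(2 * k + 1, -np.log(2 * k + 1.0)))
        sg = np.linspace(1e-3, 5.0, 300)
        ss_, nn_ = np.meshgrid(sg, sg, indexing="ij")
        s2, n2 = ss_**2, nn_**2
        denom = n2**2 + 2 * s2 * n2
        b1, b2 = (s2 + n2) / denom, s2 / denom
        log_prior_sn = np.log(ss_ * nn_**3 * (n2 + 2 * s2))
        kls = []
        for seed in range(n_seeds):
            p = toy_params(t=t, seed=seed, sigma_s=np.sqrt(0.6),
                           sigma_n=np.sqrt(0.4), sigma_0=0.0)
            stim = generate_stimulus(p)
            stats = sufficient_stats(stim.s_r, stim.s_l, grid)
            lm = post_marg_loglik(stats.cc, stats.v, t)
            oracle = np.array([
                logsumexp(-b1 * stats.v + b2 * cc - (t / 2)
                          * np.log(denom) + log_prior_sn)
                for cc in stats.cc
            ])
            lp_a = lm - logsumexp(lm)
            lp_o = oracle - logsumexp(oracle)
            po = np.exp(lp_o)
            mask = po > 1e-2 * po.max()
            lo = lp_o[mask] - logsumexp(lp_o[mask])
            la = lp_a[mask] - logsumexp(lp_a[mask])
            kls.append(float(np.sum(np.exp(lo) * (lo - la))))
        # the approximation is advertised as tight around the mode; a
        # minority of weakly informative trials may disagree
        assert np.median(kls) < 0.3

    def test_clipping_on_degenerate_correlation(self, toy_grid):
        s = np.random.default_rng(0).standard_normal(16)
        stats = sufficient_stats(s, s, toy_grid)
        lm = post_marg_loglik(stats.cc, stats.v, stats.t)  # |CC|/V hits 1
        assert np.all(np.isfinite(lm))

    def test_negative_v_rejected(self):
        with pytest.raises(ValueError):
            post_marg_loglik(np.zeros((1, 3)), np.array([0.0]), 16)

    def test_average_variance_decreases_with_bc(self, box_grid):
        mean_vars = []
        for bc in (0.0975, 0.19, 0.4071, 0.9375):
            p = StimulusParams.from_bc(bc, delta_us=0.0, duration=0.001,
                                       seed=17)
            s_r, s_l = simulate_ears(p, 500)
            stats = sufficient_stats(s_r, s_l, box_grid)
            post = post_marg_logpost(stats, box_grid)
            mean_vars.append(post.variance.mean())
        assert np.all(np.diff(mean_vars) < 0)


class TestPosteriorSummaries:
    def test_point_mass(self, box_grid):
        lp = np.full(25, -1e3)
        lp[12] = 0.0
        var, ent, map_us = posterior_summaries(Posterior(lp, box_grid))
        assert var == pytest.approx(0.0, abs=1e-6)
        assert ent == pytest.approx(0.0, abs=1e-6)
        assert map_us == pytest.approx(0.0)

    def test_uniform_entropy(self, box_grid):
        post = Posterior(np.zeros(25), box_grid)
        assert post.entropy == pytest.approx(np.log(25))

    def test_two_equal_spikes_at_100us(self):
        # 25 us lattice (40 kHz) so that +/-100 us sit exactly on the grid
        grid = DelayGrid(
            np.arange(-8, 9) * 25.0, np.full(17, -np.log(17.0)),
            sample_rate=40_000,
        )
        lp = np.full(17, -1e3)
        lp[8 - 4] = lp[8 + 4] = 0.0
        post = Posterior(lp, grid)
        assert post.mean == pytest.approx(0.0, abs=1e-9)
        assert post.variance == pytest.approx(10_000.0)

    @given(
        lp=arrays(np.float64, 25, elements=st.floats(-50, 50)),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_normalization_and_bounds(self, lp, box_grid):
        post = Posterior(lp, box_grid)
        assert np.sum(post.post) == pytest.approx(1.0)
        assert 0 <= post.entropy <= np.log(25) + 1e-12
        assert post.variance >= -1e-9


class TestPriors:
    def test_box_is_uniform(self, box_grid):
        np.testing.assert_allclose(box_grid.prior, 1 / 25)
        assert box_grid.n == 25
        assert box_grid.delta_us[0] == pytest.approx(-250.0)
        assert box_grid.delta_us[-1] == pytest.approx(250.0)

    def test_unbalanced_box_extends_range(self):
        grid = make_prior("unbalanced_box")
        assert grid.delta_us[-1] == pytest.approx(500.0)
        np.testing.assert_allclose(grid.prior, 1 / grid.n)

    def test_gaussian_symmetric_and_monotone(self):
        grid = make_prior("gaussian")
        prior = grid.prior
        np.testing.assert_allclose(prior, prior[::-1], rtol=1e-12)
        center = grid.n // 2
        assert np.all(np.diff(prior[: center + 1]) > 0)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError):
            make_prior("box", lo_us=5.0, hi_us=6.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_prior("cauchy")
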