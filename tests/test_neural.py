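import numpy as np
import pytest

from itdppc import (
    OTConfig,
    StimulusParams,
    build_filterbank,
    descriptive_model_response,
    ic_response,
    make_prior,
    ot_response,
    pre_marg_logpost,
    simulate_ears,
    sufficient_stats,
    tuning_curve,
)
from itdppc.ideal_observer import Posterior, post_marg_loglik
from itdppc.neural import _quadrature_pair, smooth_along_delays
from itdppc.stimulus import bandlimit


@pytest.fixture(scope="module")
def bank():
    return build_filterbank(432)


class TestFilterBank:
    def test_squared_transfers_tile_to_one_below_cutoff(self, bank):
        freqs = np.fft.rfftfreq(432, 1 / 48000)
        tile = np.sum(bank.response**2, axis=0)
        assert np.abs(tile[freqs <= 12000] - 1.0).max() < 1e-6
        assert np.all(tile[freqs > 12000] == 0)

    def test_tile_is_one_at_4khz(self, bank):
        freqs = np.fft.rfftfreq(432, 1 / 48000)
        j = np.argmin(np.abs(freqs - 4000))
        assert np.sum(bank.response[:, j] ** 2) == pytest.approx(1.0)

    def test_double_filter_reconstruction(self, bank, rng):
        x = bandlimit(rng.standard_normal(432), 48000, 0, 8000)
        rec = sum(bank.apply(bank.apply(x, n), n) for n in range(4))
        assert np.abs(rec - x).max() < 1e-6 * np.abs(x).max()

    def test_bandwise_covariance_decomposition(self, box_grid, rng):
        """Band cross-covariances sum exactly to the broadband
        cross-covariance for band-limited inputs, on many random stimuli."""
        bank48 = build_filterbank(48)
        p = StimulusParams.from_bc(0.5, delta_us=62.5, duration=0.001,
                                   seed=4)
        s_r, s_l = simulate_ears(p, 50)
        stats = sufficient_stats(s_r, s_l, box_grid)
        resp = ic_response(s_r, s_l, bank48, box_grid, "linear")
        band_sum = resp.rates.reshape(50, 4, 25).sum(axis=1)
        np.testing.assert_allclose(
            band_sum, stats.cc, atol=1e-6 * np.abs(stats.cc).max()
        )

    def test_bad_band_edges_rejected(self):
        with pytest.raises(ValueError):
            build_filterbank(48, f_lo=9000, f_hi=500)
        with pytest.raises(ValueError):
            build_filterbank(48, n_bands=1)


class TestICResponse:
    def test_zero_input_silent(self, box_grid):
        bank48 = build_filterbank(48)
        resp = ic_response(np.zeros((2, 48)), np.zeros((2, 48)), bank48,
                           box_grid)
        assert np.all(resp.rates == 0)

    def test_half_rectified_rates_nonnegative(self, box_grid):
        bank48 = build_filterbank(48)
        p = StimulusParams.from_bc(0.3, duration=0.001, seed=9)
        s_r, s_l = simulate_ears(p, 20)
        resp = ic_response(s_r, s_l, bank48, box_grid)
        assert np.all(resp.rates >= 0)
        assert resp.n_units == 100

    def test_unknown_nonlinearity_rejected(self, box_grid):
        bank48 = build_filterbank(48)
        with pytest.raises(ValueError, match="nonlinearity"):
            ic_response(np.zeros((1, 48)), np.zeros((1, 48)), bank48,
                        box_grid, "cubic")

    def test_prerectification_is_exact_lppc(self, box_grid):
        """A fixed linear readout (uniform band weights x the known-BC
        scale) of the linear IC population reproduces the observer's
        log-posterior."""
        bank48 = build_filterbank(48)
        p = StimulusParams.from_bc(0.4071, duration=0.001, seed=13)
        s_r, s_l = simulate_ears(p, 30)
        resp = ic_response(s_r, s_l, bank48, box_grid, "linear")
        stats = sufficient_stats(s_r, s_l, box_grid)
        true_post = pre_marg_logpost(
            stats, p.sigma_s, p.sigma_n, p.sigma_0, box_grid
        )
        se2 = p.sigma_n**2 + p.sigma_0**2
        scale = p.sigma_s**2 / (se2**2 + 2 * p.sigma_s**2 * se2)
        readout = scale * resp.rates.reshape(30, 4, 25).sum(axis=1)
        decoded = Posterior.from_loglik(readout, box_grid)
        np.testing.assert_allclose(
            decoded.log_post, true_post.log_post, atol=1e-8
        )

    @pytest.mark.parametrize("nl", ["sigmoid", "exponential"])
    def test_variant_nonlinearities_in_range(self, box_grid, nl):
        bank48 = build_filterbank(48)
        p = StimulusParams.from_bc(0.5, duration=0.001, seed=3)
        s_r, s_l = simulate_ears(p, 5)
        resp = ic_response(s_r, s_l, bank48, box_grid, nl)
        assert np.all(resp.rates > 0)
        assert resp.nonlinearity == nl


class TestOTResponse:
    def test_rates_nonnegative(self, box_grid):
        p = StimulusParams.from_bc(0.19, duration=0.001, seed=21)
        s_r, s_l = simulate_ears(p, 50)
        stats = sufficient_stats(s_r, s_l, box_grid)
        resp = ot_response(stats, box_grid)
        assert np.all(resp.rates >= 0)
        assert resp.n_units == 50

    def test_smoothing_pair_self_inverts_before_rectification(self, rng):
        transfer = _quadrature_pair(25)
        assert np.abs(np.sum(transfer**2, axis=0) - 1).max() < 1e-12
        lm = rng.standard_normal((10, 25))
        sm = smooth_along_delays(lm, transfer)
        rec = (
            smooth_along_delays(sm[:, 0, :], transfer)[:, 0, :]
            + smooth_along_delays(sm[:, 1, :], transfer)[:, 1, :]
        )
        np.testing.assert_allclose(rec, lm, atol=1e-6)

    def test_tuning_peak_nondecreasing_in_bc(self, box_grid):
        peaks = []
        for bc in (0.0975, 0.19, 0.4071, 0.9375):
            curves = tuning_curve("ot", bc, box_grid, n_trials=60, seed=5)
            peaks.append(curves[:, 12].max())
        assert np.all(np.diff(peaks) >= 0)

    def test_tuning_main_peak_with_side_peaks_at_high_bc(self, box_grid):
        curves = tuning_curve("ot", 0.9375, box_grid, n_trials=120, seed=6)
        c = curves[:, 12]  # smoothing sub-population, preferred delay 0
        assert np.argmax(c) == 12
        side = [
            i for i in range(14, 24)
            if c[i] > c[i - 1] and c[i] >= c[i + 1]
        ]
        assert side, "expected a secondary peak beyond the main lobe"
        assert c[side[0]] < c[12]

    def test_tuning_flat_without_binaural_information(self, box_grid):
        curves = tuning_curve("ot", 0.0, box_grid, n_trials=150, seed=7)
        c = curves[:, 12]
        assert np.ptp(c) < 0.5 * c.mean() + 0.5

    def test_manipulation_orderings(self, box_grid):
        """Shorter and band-limited stimuli scale the OT tuning peak down;
        low-pass pushes side peaks out of range, high-pass makes them more
        prominent at or inside the broadband spacing."""
        def peak_and_side(**kw):
            c = tuning_curve("ot", 0.9375, box_grid, n_trials=80, seed=9,
                             **kw)[:, 12]
            # a side peak requires a genuine dip after the main lobe
            right = c[12:]
            i_min = int(np.argmin(right))
            after = right[i_min + 1:]
            if len(after) and after.max() > 2 * right[i_min] + 0.5:
                j = i_min + 1 + int(np.argmax(after))
                return c[12], box_grid.delta_us[12 + j], right[j] / c[12]
            return c[12], np.inf, 0.0

        peak_o, dist_o, side_o = peak_and_side(duration=0.009)
        peak_s, _, _ = peak_and_side(duration=0.003)
        peak_lp, dist_lp, _ = peak_and_side(
            duration=0.009, stim_band=(0.0, 2000.0)
        )
        peak_hp, dist_hp, side_hp = peak_and_side(
            duration=0.009, stim_band=(6000.0, 8000.0)
        )
        assert peak_s < peak_o
        assert peak_lp < peak_o and peak_hp < peak_o
        assert dist_lp > dist_o          # side peaks move outward
        assert dist_hp <= dist_o         # ... and not outward under high-pass
        assert side_hp > side_o          # side peaks more prominent


class TestDescriptiveModel:
    def test_zero_input_silent(self, box_grid):
        bank48 = build_filterbank(48)
        resp = descriptive_model_response(
            np.zeros((2, 48)), np.zeros((2, 48)), bank48, box_grid
        )
        assert np.all(resp.rates == 0)

    def test_insensitive_to_duration(self, box_grid):
        long_c = tuning_curve("descriptive", 0.9375, box_grid, n_trials=150,
                              seed=3, duration=0.009)[:, 12]
        short_c = tuning_curve("descriptive", 0.9375, box_grid, n_trials=150,
                               seed=4, duration=0.003)[:, 12]
        np.testing.assert_allclose(long_c.max(), short_c.max(), rtol=0.15)

    def test_qualitatively_similar_tuning_to_ot(self, box_grid):
        desc = tuning_curve("descriptive", 0.9375, box_grid, n_trials=80,
                            seed=5)[:, 12]
        ot = tuning_curve("ot", 0.9375, box_grid, n_trials=80, seed=5)[:, 12]
        assert np.argmax(desc) == np.argmax(ot) == 12
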