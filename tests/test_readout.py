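"""Latent featurization, Poisson readout, CC_norm, and model comparison."""

import numpy as np
import pytest

from predstack.readout import (
    NeuralRecording,
    bootstrap_compare,
    build_latent,
    cc_max,
    cc_norm,
    cross_validate_lambda,
    default_lambda_grid,
    features_from_movie,
    fit_pca_basis,
    fit_readout,
    score_features,
    softplus,
    synth_neurons,
)


def _latents(t=1200, d=40, seed=0):
    rng = np.random.default_rng(seed)
    # temporally correlated activity, like smoothed hidden-unit traces
    x = rng.standard_normal((t + 10, d))
    k = np.ones(5) / 5
    x = np.apply_along_axis(lambda v: np.convolve(v, k, mode="same"), 0, x)
    return x[:t]


class TestBuildLatent:
    def test_dimension_capped_by_available_features(self):
        x = _latents(d=40)
        lat = build_latent(x, n_components=500)
        assert lat.h_lat.shape[1] == 80  # 2 lags x min(500, 40)

    def test_component_variances_non_increasing(self):
        basis = fit_pca_basis(_latents(), n_components=20)
        v = basis.explained_variance_
        assert (np.diff(v) <= 1e-12).all()

    def test_more_components_reconstruct_no_worse(self):
        x = _latents(d=60)
        errs = []
        for k in (10, 40):
            basis = fit_pca_basis(x, n_components=k)
            rec = basis.inverse_transform(basis.transform(x))
            errs.append(np.mean((rec - x) ** 2))
        assert errs[1] <= errs[0]

    def test_leading_lag_bins_marked_invalid(self):
        lat = build_latent(_latents(), span=(1, 2))
        assert not lat.valid[:2].any() and lat.valid[2:].all()


class TestFitReadout:
    def test_planted_sparse_readout_recovered(self):
        x = _latents(t=3000, d=30, seed=1)
        rng = np.random.default_rng(2)
        m_true = np.zeros((30, 3))
        for l in range(3):
            idx = rng.choice(30, size=6, replace=False)
            m_true[idx, l] = rng.standard_normal(6)
        y = softplus(x @ m_true + 0.5)
        ro = fit_readout(x, y, lam=1e-5, seed=0, epochs=150)
        for l in range(3):
            r = np.corrcoef(ro.weights[:, l], m_true[:, l])[0, 1]
            assert r > 0.9

    def test_huge_penalty_shrinks_weights(self):
        x = _latents(t=800, d=20)
        y = softplus(x @ np.random.default_rng(3).standard_normal((20, 2)))
        free = fit_readout(x, y, lam=0.0, seed=0, epochs=60)
        squeezed = fit_readout(x, y, lam=10.0, seed=0, epochs=60)
        assert (np.abs(squeezed.weights).sum()
                < 0.01 * np.abs(free.weights).sum())

    def test_training_loss_decreases_smoothed(self):
        x = _latents(t=800, d=20, seed=4)
        y = softplus(x @ np.random.default_rng(5).standard_normal((20, 2)))
        ro = fit_readout(x, y, lam=1e-6, seed=0, epochs=60)
        loss = np.asarray(ro.log["loss"])
        early, late = loss[:10].mean(), loss[-10:].mean()
        assert late < early

    def test_predictions_strictly_positive(self):
        x = _latents(t=200, d=10)
        ro = fit_readout(x, np.abs(x[:, :2]), lam=1e-4, seed=0, epochs=5)
        assert (ro.predict(x) > 0).all()


class TestCcNorm:
    def test_noiseless_identical_trials_reach_the_ceiling(self):
        sig = np.sin(np.linspace(0, 8 * np.pi, 200)) + 2
        trials = np.tile(sig, (4, 1))
        assert cc_norm(sig, trials) == pytest.approx(1.0)

    def test_poisson_neuron_with_known_rate_scores_near_one(self):
        rng = np.random.default_rng(0)
        vals = []
        for seed in range(5):
            rate = 5 + 3 * np.sin(np.linspace(0, 10 * np.pi, 300))
            trials = np.random.default_rng(seed).poisson(
                rate[None].repeat(200, axis=0))
            vals.append(cc_norm(rate, trials))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.02)

    def test_independent_prediction_scores_near_zero(self):
        rng = np.random.default_rng(1)
        t = 400
        rate = 5 + np.sin(np.linspace(0, 6 * np.pi, t))
        trials = rng.poisson(rate[None].repeat(8, axis=0))
        pred = rng.standard_normal(t)
        assert abs(cc_norm(pred, trials)) < 2 / np.sqrt(t) * 3

    def test_ceiling_shrinks_toward_one_with_more_trials(self):
        rng = np.random.default_rng(2)
        rate = 4 + 2 * np.sin(np.linspace(0, 6 * np.pi, 300))
        excess = []
        for n in (4, 64):
            vals = [cc_norm(rate, np.random.default_rng(s).poisson(
                rate[None].repeat(n, axis=0))) for s in range(8)]
            excess.append(abs(np.mean(vals) - 1.0))
        assert excess[1] < excess[0] + 0.02

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            cc_max(np.ones((1, 10)))


class TestLambdaSelection:
    def test_default_grid_spacing_is_half_a_decade(self):
        g = np.log10(default_lambda_grid())
        assert g[0] == pytest.approx(-6.5) and g[-1] == pytest.approx(-2.5)
        np.testing.assert_allclose(np.diff(g), 0.5)

    def test_single_lambda_grid_returned_unchanged(self):
        x = _latents(t=300, d=10)
        rec, _ = synth_neurons(x, n_neurons=2, n_trials=4, seed=0)
        lam, _ = cross_validate_lambda(x, rec.responses, lam_grid=[1e-4],
                                       fit_kwargs={"epochs": 3})
        assert lam == 1e-4


class TestBootstrap:
    def test_identical_scores_give_half(self):
        a = np.random.default_rng(0).standard_normal(40)
        p, q = bootstrap_compare(a, a.copy(), n_boot=10_000, seed=0)
        assert p == pytest.approx(0.5, abs=3 / np.sqrt(10_000) * 5)
        assert q == 1 - p

    def test_strict_dominance_gives_one(self):
        a = np.random.default_rng(1).standard_normal(25)
        p, _ = bootstrap_compare(a + 1.0, a, n_boot=2000, seed=0)
        assert p == 1.0

    def test_planted_shift_matches_analytic_paired_comparison(self):
        """Bootstrap P(mean A* > mean B*) for a 0.5 SD paired shift tracks
        the normal-approximation probability of the mean difference."""
        from scipy import stats

        rng = np.random.default_rng(2)
        n = 23
        ps = []
        for _ in range(20):
            d = rng.standard_normal(n) + 0.5
            p, _ = bootstrap_compare(d, np.zeros(n), n_boot=2000, seed=0)
            ps.append(p)
        # analytic oracle: P(mean resampled diff > 0) ~ Phi(mean/ (sd/sqrt n))
        exact = []
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = rng.standard_normal(n) + 0.5
            exact.append(stats.norm.cdf(d.mean() / (d.std(ddof=0) / np.sqrt(n))))
        assert np.mean(ps) == pytest.approx(np.mean(exact), abs=0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_compare(np.ones(3), np.ones(4))


class TestSynthNeurons:
    def test_seed_determinism(self):
        x = _latents(t=200, d=10)
        a, _ = synth_neurons(x, 3, n_trials=4, seed=7)
        b, _ = synth_neurons(x, 3, n_trials=4, seed=7)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_trial_mean_converges_to_planted_rate(self):
        x = _latents(t=300, d=10)
        rec, planted = synth_neurons(x, 2, n_trials=1000, seed=0, gain=4.0)
        for l in range(2):
            r = np.corrcoef(rec.trial_mean()[:, l], planted["rates"][:, l])[0, 1]
            assert r > 0.99

    def test_sparsity_orders_support_sizes(self):
        x = _latents(t=200, d=40)
        _, dense = synth_neurons(x, 2, sparsity=0.0, n_trials=2, seed=1)
        _, sparse = synth_neurons(x, 2, sparsity=0.95, n_trials=2, seed=1)
        assert (np.count_nonzero(sparse["weights"])
                < np.count_nonzero(dense["weights"]))

    def test_counts_nonnegative_and_split_by_file(self):
        x = _latents(t=200, d=10)
        groups = np.repeat(np.arange(10), 20)
        rec, _ = synth_neurons(x, 2, n_trials=3, seed=0, groups=groups)
        rec.assign_split(seed=0)
        assert (rec.responses >= 0).all()
        test_files = set(rec.groups[rec.split == "test"])
        cv_files = set(rec.groups[rec.split == "crossval"])
        assert not test_files & cv_files


class TestRescaleSearch:
    def test_best_configuration_is_the_argmax_and_recovers_planted_scale(self):
        """Neurons planted on scale-1 stack-1 features are best predicted at
        scale 1, and the reported best is the argmax over the table."""
        from handbuilt import single_gabor_model
        from predstack.readout import rescale_search

        model = single_gabor_model(size=9, depth=2, theta_deg=0.0, f=0.2,
                                   n_units=3)
        model.weights[0].w[1, 0, :, :, -1] = np.random.default_rng(0).normal(
            size=(9, 9)) * 0.3
        model.weights[0].w[2, 0, 4, 4, -1] = 1.0
        rng = np.random.default_rng(1)
        movie = rng.standard_normal((24, 24, 400))
        feats = features_from_movie(model, movie, 1)
        groups = np.repeat(np.arange(10), 40)
        x_lagged = np.vstack([feats[:1], feats[:-1]])
        rec, _ = synth_neurons(x_lagged, n_neurons=5, sparsity=0.5,
                               n_trials=6, seed=0, gain=2.0, groups=groups)
        best, table = rescale_search(
            model, movie, rec, scales=(0.66, 1.0, 1.5), stacks=[1],
            lam_grid=[1e-5], folds=3, fit_kwargs={"epochs": 40})
        assert best.meta["scale"] == 1.0
        assert best.mean == max(s.mean for s in table.values())
        assert len(table) == 3


class TestMoviePath:
    def test_repeated_frame_features_reach_a_steady_state(self):
        """An image presented as a repeated-frame movie must featurize, after
        the temporal transient, identically at every bin (the static path)."""
        from handbuilt import single_gabor_model

        model = single_gabor_model(size=15, depth=3)
        rng = np.random.default_rng(0)
        frame = rng.standard_normal((15, 15))
        movie = np.repeat(frame[:, :, None], 8, axis=2)
        feats = features_from_movie(model, movie, 1)
        assert feats.shape[0] == 8
        for t in range(3, 8):
            np.testing.assert_allclose(feats[t], feats[2], atol=1e-10)

    def test_end_to_end_recovery_same_features_beat_random_features(self):
        """Neurons built from a feature bank are predicted well from that
        bank (CC_norm > 0.8) and better than from an unrelated random bank
        (paired bootstrap), with ground truth known by construction."""
        x = _latents(t=1500, d=30, seed=3)
        groups = np.repeat(np.arange(15), 100)
        # neurons respond to the features one bin back, inside the t-1/t-2
        # latency span the readout is given
        x_lagged = np.vstack([x[:1], x[:-1]])
        rec, _ = synth_neurons(x_lagged, n_neurons=8, sparsity=0.8, n_trials=8,
                               seed=0, gain=2.0, groups=groups)
        rec.assign_split(seed=0)
        kw = dict(lam_grid=[1e-5], folds=3, fit_kwargs={"epochs": 80})
        score_same = score_features(x, rec, **kw)
        rng = np.random.default_rng(9)
        score_rand = score_features(_latents(t=1500, d=30, seed=11), rec, **kw)
        assert score_same.mean > 0.8
        p, _ = bootstrap_compare(score_same.cc_norm, score_rand.cc_norm,
                                 n_boot=5000, seed=0)
        assert p > 0.99
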