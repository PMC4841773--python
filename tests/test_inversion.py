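"""Model space, posterior updating, prediction, change inference, regressors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oscinfer import (
    ConfigurationError,
    DegeneratePosteriorError,
    UndefinedEvidenceError,
    inversion,
    stimgen,
)


class TestModelSpace:
    def test_every_column_is_normalised(self, model_space):
        sums = model_space.cube.sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert (model_space.cube >= 0).all()

    def test_default_grids_cover_generator_ranges(self, model_space):
        assert model_space.mu_grid[0] == 120 and model_space.mu_grid[-1] == 140
        assert model_space.sigma_grid[0] == pytest.approx(1 / 128)
        assert model_space.sigma_grid[-1] == pytest.approx(1 / 16)
        # f grid extends at least 4 max-sigma beyond the mu range
        assert model_space.f_edges_oct[0] <= math.log2(120) - 4 / 16 + 1e-9
        assert model_space.f_edges_oct[-1] >= math.log2(140) + 4 / 16 - 1e-9

    def test_discretised_column_moments(self, model_space):
        """Direct-summation moments of a column match its Gaussian."""
        mu_idx = int(np.argmin(np.abs(model_space.mu_grid - 130)))
        sg_idx = int(np.argmin(np.abs(model_space.sigma_grid - 1 / 16)))
        col = model_space.cube[:, mu_idx, sg_idx]
        x = model_space.f_centers_oct
        mean = col @ x
        sd = np.sqrt(col @ (x - mean) ** 2)
        bin_w = x[1] - x[0]
        assert abs(mean - math.log2(130)) < bin_w / 2
        assert abs(sd - 1 / 16) / (1 / 16) < 0.05

    def test_too_narrow_f_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            inversion.build_model_space(f_range_oct=(math.log2(121), math.log2(139)))

    def test_too_few_grid_points_rejected(self):
        with pytest.raises(ConfigurationError):
            inversion.build_model_space(n_mu=1)


class TestUpdatePosterior:
    def test_single_observation_is_inverse_plane(self, model_space):
        post = inversion.update_posterior(model_space, [130.0])
        b = model_space.f_to_bin(130.0)
        expected = model_space.flat[b] / model_space.flat[b].sum()
        np.testing.assert_allclose(post.plane.ravel(), expected, atol=1e-12)

    def test_posterior_mode_consistency(self, model_space):
        """50 draws from a fixed population put the mode within one cell."""
        rng = np.random.default_rng(4)
        mu, sigma = 128.0, 1 / 32
        f = 2.0 ** rng.normal(math.log2(mu), sigma, size=50)
        post = inversion.update_posterior(model_space, f)
        i, j = np.unravel_index(post.plane.argmax(), post.plane.shape)
        dmu = model_space.mu_grid[1] - model_space.mu_grid[0]
        dsg = model_space.sigma_grid[1] - model_space.sigma_grid[0]
        assert abs(model_space.mu_grid[i] - mu) <= 1.5 * dmu
        assert abs(model_space.sigma_grid[j] - sigma) <= 1.5 * dsg

    def test_order_invariance(self, model_space):
        f = np.array([128.0, 131.0, 126.5, 129.8])
        a = inversion.update_posterior(model_space, f)
        b = inversion.update_posterior(model_space, f[::-1])
        np.testing.assert_allclose(a.plane, b.plane, atol=1e-12)

    def test_plane_sums_to_one(self, model_space):
        post = inversion.update_posterior(model_space, [125.0, 131.0])
        assert post.plane.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_observation_raises(self, model_space):
        with pytest.raises(DegeneratePosteriorError):
            inversion.update_posterior(model_space, [2000.0, 60.0])


class TestPredict:
    def test_uniform_posterior_equals_change_predictive(self, model_space):
        n_mu, n_sg = len(model_space.mu_grid), len(model_space.sigma_grid)
        uniform = inversion.ParameterPosterior(
            plane=np.full((n_mu, n_sg), 1.0 / (n_mu * n_sg)), segments_used=[]
        )
        pred = inversion.predict(model_space, uniform, p_change=0.3)
        change = model_space.flat.mean(axis=1)
        np.testing.assert_allclose(pred.p, change / change.sum(), atol=1e-12)

    def test_zero_change_prob_gives_no_change_predictive(self, model_space):
        post = inversion.update_posterior(model_space, [128.0, 129.0])
        pred = inversion.predict(model_space, post, p_change=0.0)
        expected = model_space.flat @ post.plane.ravel()
        np.testing.assert_allclose(pred.p, expected / expected.sum(), atol=1e-12)

    def test_mean_converges_to_population_mean(self, model_space):
        rng = np.random.default_rng(11)
        mu = 133.0
        f = 2.0 ** rng.normal(math.log2(mu), 1 / 64, size=100)
        post = inversion.update_posterior(model_space, f)
        pred = inversion.predict(model_space, post, p_change=1 / 8)
        bin_w = model_space.f_centers_oct[1] - model_space.f_centers_oct[0]
        # the mixture tail pulls the mean slightly; allow a few bins
        assert abs(pred.mu_t - math.log2(mu)) < 5 * bin_w

    def test_precision_variance_duality(self, model_space):
        post = inversion.update_posterior(model_space, [127.0])
        pred = inversion.predict(model_space, post)
        assert pred.pi_t * pred.var_t == 1.0


class TestChangePosterior:
    def test_equal_likelihoods_return_prior(self):
        assert inversion.change_posterior(0.3, 0.3, 1 / 8) == pytest.approx(1 / 8)

    def test_impossible_under_no_change(self):
        assert inversion.change_posterior(0.4, 0.0, 1 / 8) == 1.0

    def test_decision_boundary_at_one_seventh(self):
        # P(c|f) = 0.5 exactly when P(f|~c)/P(f|c) = 1/7 for prior 1/8
        assert inversion.change_posterior(7.0, 1.0, 1 / 8) == pytest.approx(0.5)

    def test_both_zero_raises(self):
        with pytest.raises(UndefinedEvidenceError):
            inversion.change_posterior(0.0, 0.0)

    @given(
        lc=st.floats(1e-6, 1e3),
        lnc=st.floats(1e-6, 1e3),
        p=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_bayes_rule_identity(self, lc, lnc, p):
        """Matches the direct Bayes computation and stays in [0, 1]."""
        got = inversion.change_posterior(lc, lnc, p)
        expected = lc * p / (lc * p + lnc * (1 - p))
        assert got == pytest.approx(expected, rel=1e-9)
        assert 0.0 <= got <= 1.0


class TestInferChange:
    def test_first_segment_change_by_fiat(self, model_space):
        obs = inversion.IdealObserver(model_space)
        rec = obs.step(130.0)
        assert rec["change_at"] == 0
        assert obs.change_events[0] == (0, 0, 1.0)

    def test_value_at_population_mean_triggers_no_change(self, model_space):
        rng = np.random.default_rng(21)
        obs = inversion.IdealObserver(model_space)
        for f in 2.0 ** rng.normal(math.log2(128), 1 / 64, size=60):
            obs.step(float(f))
        rec = obs.step(128.0)
        assert rec["change_at"] is None
        assert max(rec["inference"].p_change_given_f.values()) < 0.5

    def test_outlier_triggers_change(self, model_space):
        rng = np.random.default_rng(22)
        obs = inversion.IdealObserver(model_space)
        for f in 2.0 ** rng.normal(math.log2(128), 1 / 64, size=60):
            obs.step(float(f))
        f_out = 2.0 ** (math.log2(128) + 8 / 64)    # 8 sigma away
        rec = obs.step(float(f_out))
        assert rec["change_at"] == rec["segment_index"]

    def test_one_shot_wrapper_detects_a_large_jump(self, model_space):
        history = np.full(30, 126.0)     # pins the posterior tightly
        inf = inversion.infer_change(model_space, history, 139.0)
        assert inf.inferred_lag is not None
        assert inf.p_change_given_f[inf.inferred_lag] > 0.5


class TestComputeRegressors:
    def test_probability_conservation_along_the_run(self, model_space):
        seq = stimgen.generate_sequence(40, rng=31)
        regs = inversion.compute_regressors(seq, model_space, store_priors=True)
        np.testing.assert_allclose(regs.priors.sum(axis=1), 1.0, atol=1e-9)

    def test_surprise_monotone_in_prediction_error(self, model_space):
        """For one fixed prior, S is non-decreasing in |f - mu|."""
        rng = np.random.default_rng(32)
        post = inversion.update_posterior(
            model_space, 2.0 ** rng.normal(math.log2(130), 1 / 32, size=40)
        )
        pred = inversion.predict(model_space, post)
        x = model_space.f_centers_oct
        s = -np.log(np.maximum(pred.p, 1e-12))
        order = np.argsort(np.abs(x - pred.mu_t))
        # scan outward from the mean on each side separately
        for side in (x >= pred.mu_t, x <= pred.mu_t):
            vals = s[side][np.argsort(np.abs(x[side] - pred.mu_t))]
            assert (np.diff(vals) >= -1e-9).all()
        del order

    def test_gaussian_limit_of_surprise(self, model_space):
        """With a sharply peaked near-Gaussian prior the density surprise
        matches the closed form 0.5*log(2*pi/Pi) + Pi*xi^2/2."""
        rng = np.random.default_rng(33)
        seq_f = 2.0 ** rng.normal(math.log2(130), 1 / 64, size=300)
        obs = inversion.IdealObserver(model_space, p_change=1e-9)
        for f in seq_f:
            rec = obs.step(float(f))
        pred = obs.current_prior()
        bin_w = model_space.f_centers_oct[1] - model_space.f_centers_oct[0]
        prior_sd = math.sqrt(pred.var_t)
        for xi_mult in (0.0, 1.0, 2.0, 3.0):
            f_test = 2.0 ** (pred.mu_t + xi_mult * prior_sd)
            b = int(model_space.f_to_bin(f_test))
            s_density = -math.log(pred.p[b]) + math.log(bin_w)
            xi = abs(model_space.f_centers_oct[b] - pred.mu_t)
            closed = 0.5 * math.log(2 * math.pi / pred.pi_t) + pred.pi_t * xi**2 / 2
            assert s_density == pytest.approx(closed, rel=0.05, abs=0.05)

    def test_certain_prior_gives_zero_surprise(self, model_space):
        """Prior mass concentrated at the observed bin: S -> 0, xi below
        half a bin width."""
        pred_p = np.zeros(model_space.n_f)
        b = int(model_space.f_to_bin(130.0))
        pred_p[b] = 1.0
        pred = inversion.PredictiveDistribution.from_mass(
            pred_p, model_space.f_centers_oct
        )
        s = -math.log(max(pred.p[b], 1e-12))
        xi = abs(math.log2(130.0) - pred.mu_t)
        bin_w = model_space.f_centers_oct[1] - model_space.f_centers_oct[0]
        assert s == 0.0
        assert xi <= bin_w / 2

    def test_first_segment_df_is_flagged_undefined(self, model_space):
        seq = stimgen.generate_sequence(20, rng=35)
        regs = inversion.compute_regressors(seq, model_space)
        df = regs["df"]
        assert np.isnan(df[0]) and np.isfinite(df[1:]).all()

    def test_change_detection_beats_chance(self, run8000):
        seq, regs = run8000
        truth = regs["change_true"].astype(bool)
        inferred = regs["change_inferred"].astype(bool)
        hit = inferred[truth].mean()
        fa = inferred[~truth].mean()
        assert hit > 1 / 8
        assert hit > fa

    def test_outputs_round_trip_to_disk(self, model_space, tmp_path):
        import h5py
        import pandas as pd

        seq = stimgen.generate_sequence(30, rng=36)
        regs = inversion.compute_regressors(seq, model_space, store_priors=True)
        regs.to_csv(tmp_path / "regs.csv")
        back = pd.read_csv(tmp_path / "regs.csv")
        np.testing.assert_allclose(back["surprise"], regs["surprise"])
        regs.write_priors_hdf5(tmp_path / "priors.h5")
        with h5py.File(tmp_path / "priors.h5") as h5:
            assert h5["priors"].shape == (31, model_space.n_f)   # n + 1 priors
            assert h5.attrs["p_change"] == pytest.approx(1 / 8)

    def test_grid_refinement_stability(self, model_space):
        """Doubling all grid resolutions moves r(S, xi) by < 0.01."""
        seq = stimgen.generate_sequence(1500, rng=7)
        fine = inversion.build_model_space(n_mu=82, n_sigma=58, n_f=1026)
        r = {}
        for name, space in (("base", model_space), ("fine", fine)):
            frame = inversion.compute_regressors(seq, space).frame
            r[name] = np.corrcoef(frame["surprise"], frame["pe"])[0, 1]
        assert abs(r["fine"] - r["base"]) < 0.01
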