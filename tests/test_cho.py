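import math

import numpy as np
import pytest
from scipy import stats

from choiq.cho import (
    ChannelParams,
    SingularCovarianceError,
    analytic_cho_auc,
    build_channel_bank,
    build_template,
    channelize,
    ddog_response,
    decision_variables,
    estimate_covariance,
    fit_cho_model,
    load_scores,
    mean_signal_channelised,
    save_model,
    save_scores,
    score_dataset,
    theoretical_signal_channelised,
    white_noise_channel_covariance,
)
from choiq.roc import auc_mann_whitney
from choiq.synthetic import SIGNAL_ABSENT, SIGNAL_PRESENT, SyntheticConfig, generate_dataset


class TestChannelParams:
    def test_defaults(self, default_params):
        assert default_params.sigma0 == 0.005
        assert default_params.alpha == 1.4
        assert default_params.q == 1.67
        assert default_params.n_channels == 10

    def test_sigma_geometric_sequence(self, default_params):
        assert default_params.sigma(1) == pytest.approx(0.005)
        assert default_params.sigma(2) == pytest.approx(0.007)
        assert default_params.sigma(10) == pytest.approx(0.005 * 1.4**9)
        assert default_params.sigma(10) == pytest.approx(0.10331, abs=5e-6)
        sigmas = [default_params.sigma(j) for j in range(1, 11)]
        assert all(b > a for a, b in zip(sigmas, sigmas[1:]))

    def test_sigma_out_of_range(self, default_params):
        for j in (0, 11):
            with pytest.raises(ValueError, match="out of range"):
                default_params.sigma(j)

    @pytest.mark.parametrize(
        "kwargs", [dict(sigma0=0.0), dict(alpha=1.0), dict(q=0.9), dict(n_channels=0)]
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            ChannelParams(**kwargs)


class TestDdogResponse:
    def test_zero_frequency_is_zero_for_all_channels(self, default_params):
        for j in range(1, 11):
            assert ddog_response(0.0, j, default_params) == 0.0

    def test_value_at_sigma_j_is_channel_independent(self, default_params):
        expected = math.exp(-1.0 / (2 * 1.67**2)) - math.exp(-0.5)
        assert expected == pytest.approx(0.22934, abs=5e-6)
        for j in range(1, 11):
            rho = default_params.sigma(j)
            assert ddog_response(rho, j, default_params) == pytest.approx(
                expected, rel=1e-12
            )

    def test_negative_rho_rejected(self, default_params):
        with pytest.raises(ValueError):
            ddog_response(-0.1, 1, default_params)

    def test_array_input(self, default_params):
        rho = np.array([0.0, 0.01, 0.1])
        out = ddog_response(rho, 5, default_params)
        assert out.shape == (3,)
        assert out[0] == 0.0


class TestChannelBank:
    def test_spatial_templates_sum_to_zero(self, bank64):
        sums = np.abs(bank64.spatial_templates.sum(axis=0))
        norms = np.linalg.norm(bank64.spatial_templates, axis=0)
        assert np.all(sums < 1e-10 * norms)

    def test_dc_bin_exactly_zero(self, bank64):
        assert np.all(bank64.frequency_responses[:, 0, 0] == 0.0)

    def test_templates_radially_symmetric(self, bank64):
        n = bank64.roi_size_px
        for j in range(bank64.n_channels):
            t = bank64.spatial_templates[:, j].reshape(n, n)
            assert np.allclose(t, t.T, atol=1e-10)
            # even symmetry about the centre pixel (row/col 0 is its own mirror)
            core = t[1:, 1:]
            assert np.allclose(core, core[::-1, ::-1], atol=1e-10)

    def test_parseval_identity(self, bank64, rng):
        # spatial inner product == frequency-domain inner product of spectra
        n = bank64.roi_size_px
        img = rng.standard_normal((n, n))
        v_spatial = channelize([img], bank64).vectors[0]
        g_hat = np.fft.fft2(img)
        for j in range(bank64.n_channels):
            t = bank64.spatial_templates[:, j].reshape(n, n)
            t_hat = np.fft.fft2(t)
            v_freq = np.vdot(t_hat, g_hat).real / n**2
            assert v_freq == pytest.approx(v_spatial[j], rel=1e-8, abs=1e-12)

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError):
            build_channel_bank(4)


class TestChannelize:
    def test_linearity(self, bank64, rng):
        g1 = rng.standard_normal((64, 64))
        g2 = rng.standard_normal((64, 64))
        v1 = channelize([g1], bank64).vectors[0]
        v2 = channelize([g2], bank64).vectors[0]
        v = channelize([2.5 * g1 - 1.5 * g2], bank64).vectors[0]
        assert np.allclose(v, 2.5 * v1 - 1.5 * v2, rtol=1e-10)

    def test_offset_invariance(self, bank64, rng):
        g = rng.standard_normal((64, 64))
        v0 = channelize([g], bank64).vectors[0]
        v1 = channelize([g + 1000.0], bank64).vectors[0]
        norms = np.linalg.norm(bank64.spatial_templates, axis=0)
        assert np.all(np.abs(v1 - v0) < 1e-8 * 1000.0 * norms)

    def test_size_mismatch_named(self, bank64):
        with pytest.raises(ValueError, match="image 0"):
            channelize([np.zeros((32, 32))], bank64)

    def test_sinusoid_peaks_in_matching_channel(self, bank64):
        # oracle: brute-force argmax of the radial response over channels
        n = bank64.roi_size_px
        x = np.arange(n) - n // 2
        for k in (1, 2, 3, 4, 6, 8, 12):
            f = k / n
            img = np.cos(2 * np.pi * f * x)[None, :] * np.ones((n, 1))
            v = channelize([img], bank64).vectors[0]
            brute = [
                ddog_response(f, j, bank64.params) for j in range(1, 11)
            ]
            assert int(np.argmax(np.abs(v))) == int(np.argmax(brute))

    def test_own_peak_frequency_for_resolvable_channels(self, bank64):
        # channels whose peak lies on the 64-px grid respond most to it
        n = bank64.roi_size_px
        x = np.arange(n) - n // 2
        grid = np.arange(1, n // 2) / n
        for j in range(6, 11):
            resp = ddog_response(grid, j, bank64.params)
            f = grid[int(np.argmax(resp))]
            img = np.cos(2 * np.pi * f * x)[None, :] * np.ones((n, 1))
            v = channelize([img], bank64).vectors[0]
            assert int(np.argmax(np.abs(v))) + 1 == j


class TestCovariance:
    def test_hand_case(self):
        k = estimate_covariance(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        assert np.allclose(k, [[2.0, 0.0], [0.0, 0.0]])

    def test_identical_samples_zero_covariance(self):
        k = estimate_covariance(np.tile([3.0, -2.0, 5.0], (7, 1)))
        assert np.allclose(k, 0.0)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            estimate_covariance(np.ones((1, 3)))

    def test_monte_carlo_recovery(self, rng):
        a = rng.standard_normal((5, 5))
        k_true = a @ a.T + np.eye(5)
        samples = rng.multivariate_normal(np.zeros(5), k_true, size=50_000)
        k_hat = estimate_covariance(samples)
        n = samples.shape[0]
        d = np.diag(k_true)
        se = np.sqrt((np.outer(d, d) + k_true**2) / n)
        assert np.all(np.abs(k_hat - k_true) < 3.5 * se)


class TestTheoreticalSignal:
    def test_zero_amplitude_zero_vector(self, bank64):
        v = theoretical_signal_channelised(bank64, 5.0, 0.7227, 0.0)
        assert np.allclose(v, 0.0)

    def test_amplitude_linearity(self, bank64):
        v1 = theoretical_signal_channelised(bank64, 5.0, 0.7227, 1.0)
        v2 = theoretical_signal_channelised(bank64, 5.0, 0.7227, 2.0)
        assert np.allclose(v2, 2.0 * v1, rtol=1e-12)

    def test_components_non_degenerate(self, bank64):
        from choiq.synthetic import make_gaussian_signal

        v = theoretical_signal_channelised(bank64, 5.0, 370.0 / 512.0, 1.0)
        pixel_norm = np.linalg.norm(make_gaussian_signal(64, 370.0 / 512.0, 5.0, 1.0))
        assert np.abs(v).max() > 1e-6 * pixel_norm

    def test_subpixel_fwhm_warns(self, bank64):
        with pytest.warns(RuntimeWarning, match="aliasing"):
            theoretical_signal_channelised(bank64, 1.0, 0.7227, 1.0)

    def test_invalid_arguments(self, bank64):
        with pytest.raises(ValueError):
            theoretical_signal_channelised(bank64, -5.0, 0.7, 1.0)


class TestBuildTemplate:
    def test_identity_covariance(self):
        v = np.array([1.0, -2.0, 3.0])
        assert np.allclose(build_template(np.eye(3), v), v)

    def test_diagonal_solve(self):
        w = build_template(np.diag([2.0, 4.0]), np.array([2.0, 4.0]))
        assert np.allclose(w, [1.0, 1.0])

    def test_singular_covariance_raises(self):
        with pytest.raises(SingularCovarianceError, match="ridge"):
            build_template(np.array([[2.0, 0.0], [0.0, 0.0]]), np.array([1.0, 1.0]))

    def test_ridge_rescues_singular_covariance(self):
        k = np.array([[2.0, 0.0], [0.0, 0.0]])
        w = build_template(k, np.array([1.0, 1.0]), ridge=0.5)
        assert np.allclose(w, [1.0 / 2.5, 2.0])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            build_template(np.array([[1.0, 0.5], [0.0, 1.0]]), np.ones(2))


class TestDecisionVariables:
    def _sets(self):
        from choiq.cho import ChannelisedSet

        absent = ChannelisedSet(np.array([[3.0, 5.0], [1.0, 2.0]]), SIGNAL_ABSENT)
        present = ChannelisedSet(np.array([[4.0, 1.0]]), SIGNAL_PRESENT)
        return absent, present

    def test_dot_product(self):
        absent, present = self._sets()
        s = decision_variables(np.array([1.0, 0.0]), absent, present)
        assert np.allclose(s.lambda_absent, [3.0, 1.0])
        assert np.allclose(s.lambda_present, [4.0])

    def test_zero_template(self):
        absent, present = self._sets()
        s = decision_variables(np.zeros(2), absent, present)
        assert np.all(s.lambda_absent == 0.0) and np.all(s.lambda_present == 0.0)

    def test_dimension_mismatch(self):
        absent, present = self._sets()
        with pytest.raises(ValueError, match="template length"):
            decision_variables(np.zeros(3), absent, present)

    def test_channel_recombination_invariance(self, bank64, rng):
        from choiq.cho import ChannelisedSet

        cfg = SyntheticConfig(seed=17, n_signal_absent=30, n_signal_present=10)
        rois = generate_dataset(cfg)
        absent = channelize([r for r in rois if r.label == SIGNAL_ABSENT], bank64)
        present = channelize([r for r in rois if r.label == SIGNAL_PRESENT], bank64)
        v_theo = theoretical_signal_channelised(bank64, 5.0, cfg.pixel_spacing_mm)
        k = estimate_covariance(absent)
        w = build_template(k, v_theo)
        base = decision_variables(w, absent, present)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.standard_normal((10, 10)))
            a = q @ np.diag(rng.uniform(0.5, 2.0, 10))
            absent_t = ChannelisedSet(absent.vectors @ a, SIGNAL_ABSENT)
            present_t = ChannelisedSet(present.vectors @ a, SIGNAL_PRESENT)
            w_t = build_template(a.T @ k @ a, a.T @ v_theo)
            s = decision_variables(w_t, absent_t, present_t)
            scale = np.abs(base.lambda_absent).max()
            assert np.abs(s.lambda_absent - base.lambda_absent).max() < 1e-8 * scale
            assert np.abs(s.lambda_present - base.lambda_present).max() < 1e-8 * scale


class TestAnalyticAUC:
    def test_no_signal_gives_half(self):
        assert analytic_cho_auc(np.eye(3), np.zeros(3)) == pytest.approx(0.5)

    def test_unit_signal_closed_form(self):
        v = np.zeros(4)
        v[0] = 1.0
        assert analytic_cho_auc(np.eye(4), v) == pytest.approx(0.76025, abs=5e-6)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            analytic_cho_auc(np.diag([1.0, 0.0]), np.ones(2))

    def test_monte_carlo_oracle(self, rng):
        # brute-force AUC from simulated Gaussian decision variables
        d = np.array([0.5, 1.0, 2.0, 4.0])
        k = np.diag(d)
        v = np.array([0.3, -0.2, 0.5, 0.1])
        w = v / d  # K^{-1} v for diagonal K
        n = 1_000_000
        absent = rng.multivariate_normal(np.zeros(4), k, size=n) @ w
        present = rng.multivariate_normal(v, k, size=n) @ w
        mc = (present > absent).mean()
        assert analytic_cho_auc(k, v) == pytest.approx(mc, abs=0.002)


class TestPipeline:
    def test_score_dataset_counts(self, default_dataset):
        s = score_dataset(default_dataset)
        assert s.lambda_absent.size == 90
        assert s.lambda_present.size == 40

    def test_scale_invariance_of_auc(self, default_dataset):
        s1 = score_dataset(default_dataset)
        scaled = [
            type(r)(r.pixels * 3.0, r.pixel_spacing_mm, r.label,
                    r.lesion_diameter_mm, r.source_id)
            for r in default_dataset
        ]
        s2 = score_dataset(scaled)
        # lambda scales by 1/c; AUC is unchanged
        assert np.allclose(s2.lambda_absent, s1.lambda_absent / 3.0, rtol=1e-6)
        a1 = auc_mann_whitney(s1.lambda_absent, s1.lambda_present)
        a2 = auc_mann_whitney(s2.lambda_absent, s2.lambda_present)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_offset_invariance_of_scores(self, default_dataset):
        s1 = score_dataset(default_dataset)
        shifted = [
            type(r)(r.pixels + 100.0, r.pixel_spacing_mm, r.label,
                    r.lesion_diameter_mm, r.source_id)
            for r in default_dataset
        ]
        s2 = score_dataset(shifted)
        scale = np.abs(s1.lambda_absent).max()
        assert np.abs(s2.lambda_absent - s1.lambda_absent).max() < 1e-6 * scale

    def test_mean_signal_mode(self, default_dataset):
        s = score_dataset(default_dataset, signal_mode="mean")
        assert auc_mann_whitney(s.lambda_absent, s.lambda_present) > 0.9

    def test_empirical_auc_matches_analytic_oracle(self, bank64):
        # fitted observer on large-n white-noise data vs the analytic model
        sd, amp = 30.0, 6.0
        spacing = 370.0 / 512.0
        cfg = SyntheticConfig(
            seed=77, n_signal_absent=2000, n_signal_present=2000,
            noise_sd_hu=sd, lesion_amplitude_hu=amp, pixel_spacing_mm=spacing,
        )
        s = score_dataset(generate_dataset(cfg))
        empirical = auc_mann_whitney(s.lambda_absent, s.lambda_present)
        k_true = white_noise_channel_covariance(bank64, sd)
        v_sig = theoretical_signal_channelised(bank64, 5.0, spacing, amp)
        assert empirical == pytest.approx(analytic_cho_auc(k_true, v_sig), abs=0.02)

    def test_fit_cho_model_and_persistence(self, bank64, tmp_path, default_dataset):
        absent = [r for r in default_dataset if r.label == SIGNAL_ABSENT]
        model = fit_cho_model(absent, bank64, 5.0, 370.0 / 512.0)
        assert np.allclose(
            (model.K) @ model.w, model.v_theo, atol=1e-8 * np.abs(model.v_theo).max()
        )
        assert model.condition_number < 1e12
        save_model(model, tmp_path / "model.yaml")
        assert (tmp_path / "model.yaml").stat().st_size > 0

    def test_scores_csv_round_trip(self, tmp_path, default_dataset):
        s = score_dataset(default_dataset)
        save_scores(s, tmp_path / "scores.csv")
        loaded = load_scores(tmp_path / "scores.csv")
        assert np.allclose(loaded.lambda_absent, s.lambda_absent)
        assert np.allclose(loaded.lambda_present, s.lambda_present)
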