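"""Inverse operators: covariance, depth weights, kernels, resolution matrix."""

import numpy as np
import pytest

from dba.anatomy import build_sensors
from dba.forward import GainMatrix
from dba.inverse import (NoiseCovariance, depth_weights, dspm_kernel,
                         estimate_noise_cov, kernel_family, resolution_matrix,
                         sloreta_kernel, wmne_kernel)


def _toy_gain(values):
    """Wrap a plain matrix as a GainMatrix with a free-orientation block whose
    per-source Frobenius norms equal the fixed column norms."""
    values = np.asarray(values, dtype=float)
    free = np.zeros((values.shape[0], values.shape[1], 3))
    free[:, :, 0] = values
    return GainMatrix(values=values, free=free, source_space=None, sensors=None)


class TestNoiseCov:
    def test_independent_channels_give_near_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 20000))
        cov = estimate_noise_cov(x, loading_fraction=0.0).matrix
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.05
        assert np.allclose(np.diag(cov), 1.0, atol=0.05)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 500))
        c1 = estimate_noise_cov(x, 0.0).matrix
        c3 = estimate_noise_cov(3 * x, 0.0).matrix
        assert np.allclose(c3, 9 * c1)

    def test_loading_makes_positive_definite(self):
        x = np.zeros((6, 100))
        x[0] = np.random.default_rng(2).standard_normal(100)
        with pytest.warns(UserWarning, match="constant"):
            cov = estimate_noise_cov(x, loading_fraction=0.1)
        assert np.linalg.eigvalsh(cov.matrix).min() > 0

    def test_short_baseline_gets_heavier_loading(self):
        rng = np.random.default_rng(3)
        cov = estimate_noise_cov(rng.standard_normal((100, 10)), loading_fraction=0.01)
        assert cov.regularization_applied >= 0.1


class TestDepthWeights:
    def test_w_zero_is_identity(self, small_gain):
        assert np.allclose(depth_weights(small_gain, 0.0), 1.0)

    def test_weight_ratio_for_norm_ratio_two(self):
        g = _toy_gain(np.array([[1.0, 2.0], [0.0, 0.0]]))
        w = depth_weights(g, 0.5)
        assert w[0] / w[1] == pytest.approx(2.0)

    def test_silent_source_capped_with_warning(self):
        g = _toy_gain(np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.warns(UserWarning, match="silent"):
            w = depth_weights(g, 0.6)
        assert w[1] == pytest.approx(100.0)  # limit^2 over the strongest source
        with pytest.warns(UserWarning, match="silent"):
            w = depth_weights(g, 0.6, limit=None, ceiling=1e6)
        assert w[1] == 1e6

    def test_limit_caps_dynamic_range(self):
        """No source is boosted more than limit^2 in power relative to the
        strongest one, matching standard depth-weighting practice."""
        g = _toy_gain(np.array([[1000.0, 1.0, 0.01]]))
        w = depth_weights(g, 0.6, limit=10.0)
        assert w.max() / w.min() == pytest.approx(100.0)

    def test_weighting_raises_deep_source_amplitude(self, small_space, small_gain, noise_cov):
        """Depth weighting lifts the estimated amplitude of a deep point
        source compared with plain minimum norm."""
        i = int(small_space.indices("thalamus")[30])
        data = small_gain.values[:, i] * 1e-8
        k0 = wmne_kernel(small_gain, noise_cov, w=0.0)
        k6 = wmne_kernel(small_gain, noise_cov, w=0.6)
        assert abs(k6.matrix[i] @ data) > abs(k0.matrix[i] @ data)


class TestWmne:
    def test_regularization_matches_hand_computed_trace_ratio(self):
        g = _toy_gain(np.diag([2.0, 3.0, 6.0]))
        cov = NoiseCovariance(np.eye(3), 100, 0.0)
        k = wmne_kernel(g, cov, source_cov_diag=np.ones(3), snr_reg=3.0)
        assert k.lambda2 == pytest.approx(49.0 / 27.0, rel=1e-12)

    def test_exact_inverse_limit(self):
        """Orthogonal G with negligible regularization (snr_reg -> inf, so
        lambda^2 -> 0): K -> G^-1 and R -> I."""
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        g = _toy_gain(q * 1.0)
        cov = NoiseCovariance(np.eye(4), 100, 0.0)
        k = wmne_kernel(g, cov, source_cov_diag=np.ones(4), snr_reg=1e6)
        assert np.allclose(k.matrix, q.T, atol=1e-9)
        assert np.allclose(k.matrix @ q, np.eye(4), atol=1e-9)

    def test_plain_mne_biased_superficial_weighting_reduces_it(
            self, small_space, small_gain, noise_cov):
        """Point-source maxima land shallower than truth at w=0; the bias
        shrinks at w=0.6."""
        depths = small_space.depths()
        deep = small_space.indices("thalamus")[::10]
        err = {}
        for w in (0.0, 0.6):
            k = wmne_kernel(small_gain, noise_cov, w=w)
            r = k.matrix @ small_gain.values[:, deep]
            am = np.abs(r).argmax(axis=0)
            err[w] = np.linalg.norm(small_space.positions[am]
                                    - small_space.positions[deep], axis=1)
            if w == 0.0:
                assert np.median(depths[am]) < np.median(depths[deep])
        assert np.median(err[0.6]) < np.median(err[0.0])


class TestDspm:
    def test_unit_noise_sensitivity_by_construction(self, small_gain, noise_cov):
        base = wmne_kernel(small_gain, noise_cov, w=0.6)
        kd = dspm_kernel(base, noise_cov)
        diag = np.einsum("is,st,it->i", kd.matrix, noise_cov.matrix, kd.matrix)
        assert np.abs(diag - 1).max() < 1e-9

    def test_scale_invariance_of_normalized_estimates(self, small_gain, noise_cov):
        """Scaling the noise covariance by c^2 and the data by c leaves the
        dSPM map unchanged."""
        c = 7.0
        cov2 = NoiseCovariance(noise_cov.matrix * c ** 2, noise_cov.n_samples_used, 0.0)
        data = small_gain.values[:, 10] * 1e-8
        kd1 = dspm_kernel(wmne_kernel(small_gain, noise_cov, w=0.6), noise_cov)
        kd2 = dspm_kernel(wmne_kernel(small_gain, cov2, w=0.6), cov2)
        assert np.allclose(kd1.matrix @ data, kd2.matrix @ (c * data), rtol=1e-9)

    def test_pure_noise_variance_near_one(self, small_gain, noise_cov):
        base = wmne_kernel(small_gain, noise_cov, w=0.6)
        kd = dspm_kernel(base, noise_cov)
        rng = np.random.default_rng(5)
        chol = np.linalg.cholesky(noise_cov.matrix)
        noise = chol @ rng.standard_normal((small_gain.n_sensors, 10000))
        v = (kd.matrix @ noise).var(axis=1)
        assert np.abs(v - 1).max() < 0.1


class TestSloreta:
    def test_two_by_two_hand_computation(self):
        """Diagonal 2-sensor/2-source system frozen by hand: lambda^2 = 5/18,
        wMNE rows (18/23, 36/77), sLORETA rows (sqrt(18/23), 6/sqrt(154))."""
        g = _toy_gain(np.diag([1.0, 2.0]))
        cov = NoiseCovariance(np.eye(2), 100, 0.0)
        k = wmne_kernel(g, cov, source_cov_diag=np.ones(2), snr_reg=3.0)
        assert k.lambda2 == pytest.approx(5.0 / 18.0, rel=1e-12)
        assert np.allclose(np.diag(k.matrix), [18 / 23, 36 / 77])
        ks = sloreta_kernel(k, g)
        assert np.allclose(np.diag(ks.matrix),
                           [np.sqrt(18 / 23), 6 / np.sqrt(154)])

    def test_zero_localization_error_noiseless(self, small_space, small_gain):
        """Classical sLORETA finds every non-silent point source exactly."""
        cov = NoiseCovariance(np.eye(small_gain.n_sensors) * 1e-26, 100, 0.0)
        ks = sloreta_kernel(wmne_kernel(small_gain, cov, w=0.0), small_gain)
        r = np.abs(ks.matrix @ small_gain.values)
        assert (r.argmax(axis=0) == np.arange(small_space.n_sources)).all()

    def test_resolution_rows_proportional_to_base(self, small_gain, noise_cov):
        base = wmne_kernel(small_gain, noise_cov, w=0.6)
        ks = sloreta_kernel(base, small_gain)
        r_base = base.matrix @ small_gain.values
        r_slo = ks.matrix @ small_gain.values
        ratios = r_slo[:50] / r_base[:50]
        assert np.allclose(ratios, ratios[:, :1])  # constant per row


class TestResolutionMatrix:
    def test_exact_product_and_identity_case(self):
        rng = np.random.default_rng(6)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        g = _toy_gain(q)
        cov = NoiseCovariance(np.eye(3), 10, 0.0)
        k = wmne_kernel(g, cov, source_cov_diag=np.ones(3), snr_reg=1e7)
        r = resolution_matrix(k, g)
        assert np.allclose(r.matrix, k.matrix @ q)
        assert np.allclose(r.matrix, np.eye(3), atol=1e-9)

    def test_trace_bounded_by_sensor_count(self, small_gain, noise_cov):
        for w in (0.0, 0.6):
            k = wmne_kernel(small_gain, noise_cov, w=w)
            r = resolution_matrix(k, small_gain)
            assert np.trace(r.matrix) <= small_gain.n_sensors

    def test_normalized_ctf_rows_identical_across_methods(self, small_gain, noise_cov):
        """Noise normalization rescales rows of R but never reshapes them."""
        fam = kernel_family(small_gain, noise_cov, sloreta_unweighted=False)
        rows = {}
        for m, k in fam.items():
            r = np.abs(k.matrix @ small_gain.values)
            rows[m] = r / r.max(axis=1, keepdims=True)
        assert np.abs(rows["wmne"] - rows["dspm"]).max() < 1e-10
        assert np.abs(rows["wmne"] - rows["sloreta"]).max() < 1e-10
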