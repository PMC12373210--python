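import numpy as np
import pytest
from skimage.metrics import peak_signal_noise_ratio as sk_psnr
from skimage.metrics import structural_similarity as sk_ssim

from tomofield._autodiff import Tensor
from tomofield.losses import (
    FeatureExtractor,
    dag_training_loss,
    hinge_loss_d,
    hinge_loss_g,
    inference_loss,
    perceptual_loss,
    psnr_term,
)
from tomofield.metrics import psnr, rmse, ssim, to_hounsfield


class TestPsnr:
    @pytest.mark.parametrize("r,expected", [(0.1, 20.0), (0.01, 40.0)])
    def test_known_values(self, r, expected):
        a = np.zeros((10, 10))
        b = np.full((10, 10), r)
        assert psnr(a, b, max_val=1.0) == pytest.approx(expected, abs=1e-9)

    def test_identity_sentinel(self):
        a = np.random.default_rng(0).uniform(size=(5, 5))
        assert psnr(a, a) == float("inf")

    def test_matches_reference_implementation(self, rng):
        for _ in range(20):
            a = rng.uniform(size=(12, 12))
            b = rng.uniform(size=(12, 12))
            assert abs(psnr(a, b, 1.0) - sk_psnr(a, b, data_range=1.0)) < 1e-6


class TestSsim:
    def test_identity(self, rng):
        a = rng.uniform(size=(9, 9))
        assert ssim(a, a) == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        """SSIM(0, L) with zero variances reduces to c1/(L^2 + c1)."""
        L = 1.0
        a = np.zeros((8, 8))
        b = np.full((8, 8), L)
        c1 = (0.01 * L) ** 2
        assert ssim(a, b, dynamic_range=L) == pytest.approx(c1 / (L**2 + c1), rel=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.uniform(size=(7, 7)), rng.uniform(size=(7, 7))
        assert ssim(a, b) == pytest.approx(ssim(b, a), rel=1e-12)

    def test_matches_reference_full_window(self, rng):
        """Global-statistics form equals a windowed reference whose window
        covers the whole image."""
        for _ in range(20):
            a = rng.uniform(size=(21, 21))
            b = rng.uniform(size=(21, 21))
            ref = sk_ssim(a, b, win_size=21, data_range=1.0, gaussian_weights=False)
            assert abs(ssim(a, b) - ref) < 1e-4


class TestRmse:
    def test_identity_and_offset(self, rng):
        a = rng.uniform(size=(6, 6))
        assert rmse(a, a) == 0.0
        assert rmse(a, a - 2.0) == pytest.approx(2.0)

    def test_matches_naive_loop(self, rng):
        a = rng.uniform(size=(4, 4))
        b = rng.uniform(size=(4, 4))
        total = 0.0
        for i in range(4):
            for j in range(4):
                total += (a[i, j] - b[i, j]) ** 2
        assert rmse(a, b) == pytest.approx(np.sqrt(total / 16), rel=1e-12)

    def test_hounsfield_units(self):
        assert to_hounsfield(np.array(0.0)) == -1000.0
        assert to_hounsfield(np.array(0.5)) == 0.0


class TestHinge:
    def test_worked_cases(self):
        assert hinge_loss_d(np.array([5.0]), np.array([-5.0])).item() == 0.0
        assert hinge_loss_d(np.array([0.0]), np.array([0.0])).item() == 2.0
        assert hinge_loss_d(np.array([-1.0]), np.array([1.0])).item() == 4.0

    def test_nonnegative(self, rng):
        for _ in range(10):
            v = hinge_loss_d(rng.normal(size=5), rng.normal(size=5)).item()
            assert v >= 0.0

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            hinge_loss_d(np.array([]), np.array([1.0]))

    def test_generator_side(self):
        assert hinge_loss_g(np.array([2.0, 4.0])).item() == pytest.approx(-3.0)


class TestDagCombination:
    def test_equal_losses_algebra(self):
        ell = 1.7
        out = dag_training_loss([ell] * 5, lambda1=0.2).item()
        assert out == pytest.approx(ell * (1 + 0.2 * 4 / 3), rel=1e-5)

    def test_lambda1_zero_keeps_identity_only(self):
        out = dag_training_loss([3.0, 100.0, 100.0, 100.0, 100.0], lambda1=0.0).item()
        assert out == pytest.approx(3.0)

    def test_lambda2_zero_drops_patch_terms(self):
        entries = [(1.0, 2.0, 50.0, 60.0)] * 3  # n = 2 augmentations
        out = dag_training_loss(entries, lambda1=0.2, lambda2=0.0).item()
        # each L(k) keeps only the volume terms (1 + 2); total = L0 + 0.2/1 * (L1 + L2)
        assert out == pytest.approx(3.0 + 0.2 * 6.0, rel=1e-5)

    def test_too_few_augmentations_rejected(self):
        with pytest.raises(ValueError):
            dag_training_loss([1.0, 2.0], lambda1=0.2)

    def test_linearity(self, rng):
        """Superposition: the combination is linear in each per-k loss."""
        a = rng.uniform(size=5)
        b = rng.uniform(size=5)
        la = dag_training_loss(list(a), 0.2).item()
        lb = dag_training_loss(list(b), 0.2).item()
        lab = dag_training_loss(list(a + b), 0.2).item()
        assert lab == pytest.approx(la + lb, rel=1e-4)


class TestPerceptual:
    def test_identity_is_zero(self, rng):
        a = rng.uniform(size=(8, 8))
        fx = FeatureExtractor(2, (4, 8), seed=1)
        assert perceptual_loss(a, a, fx).item() == 0.0

    def test_symmetry(self, rng):
        a, b = rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8))
        fx = FeatureExtractor(2, (4, 8), seed=1)
        assert perceptual_loss(a, b, fx).item() == pytest.approx(
            perceptual_loss(b, a, fx).item(), rel=1e-4)

    def test_identity_feature_map_reduces_to_mse(self, rng):
        """With the identity extractor and no standardization the loss equals
        the plain mean squared difference (closed-form reduction)."""
        for _ in range(5):
            a, b = rng.uniform(size=(6, 6)), rng.uniform(size=(6, 6))
            ours = perceptual_loss(a, b, None, standardize_inputs=False).item()
            assert ours == pytest.approx(np.mean((a - b) ** 2), rel=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            perceptual_loss(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_extractor_deterministic(self, rng):
        x = rng.uniform(size=(8, 8))
        f1 = FeatureExtractor(2, (4, 8), seed=3)(Tensor(x)).data
        f2 = FeatureExtractor(2, (4, 8), seed=3)(Tensor(x)).data
        assert np.array_equal(f1, f2)


class TestInferenceLoss:
    def test_identity_reduces_to_floor(self, rng):
        a = rng.uniform(size=(8, 8))
        fx = FeatureExtractor(2, (4, 8), seed=0)
        # perceptual and NLL vanish; the PSNR shortfall is clipped at zero
        assert inference_loss(a, a, fx).item() == pytest.approx(0.0, abs=1e-6)

    def test_monotone_along_interpolation_path(self, rng):
        ref = rng.uniform(size=(8, 8))
        noise = rng.normal(size=(8, 8)) * 0.3
        fx = FeatureExtractor(2, (4, 8), seed=0)
        vals = [inference_loss(ref + alpha * noise, ref, fx).item()
                for alpha in np.linspace(1.0, 0.0, 10)]
        assert all(v2 <= v1 + 1e-7 for v1, v2 in zip(vals, vals[1:]))

    def test_lambda_isolation(self, rng):
        a, b = rng.uniform(size=(6, 6)), rng.uniform(size=(6, 6))
        only_psnr = inference_loss(a, b, None, lambdas=(0.0, 1.0, 0.0)).item()
        assert only_psnr == pytest.approx(psnr_term(a, b).item(), rel=1e-5)

    def test_psnr_term_vanishes_above_threshold(self, rng):
        ref = rng.uniform(size=(8, 8))
        assert psnr_term(ref + 1e-4, ref, stop_psnr=25.0).item() == 0.0
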