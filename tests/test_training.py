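import numpy as np
import pytest

import zsdeconv as z
from zsdeconv.losses import loss2d
from zsdeconv.nn import Adam, Param
from zsdeconv.recorruption import RecorruptionParams, recorrupt
from zsdeconv.training import ZSDeconvNet2D, ZSDeconvNet3D, learning_rate, finetune_tta


def test_learning_rate_schedule_exact():
    assert learning_rate(0) == 0.5e-4
    assert learning_rate(9_999) == 0.5e-4
    assert learning_rate(10_000) == 0.25e-4
    assert learning_rate(25_000) == 0.125e-4
    assert learning_rate(40_000) == 0.5e-4 * 0.5**4


def small_image(psf_cam, camera, seed=3, photons=15.0, shape=(64, 64)):
    ph = z.generate_filaments(shape, 3, seed=seed, pixel_size=62.5)
    return z.render_noisy(ph, psf_cam, camera, photons, seed=seed + 100)


def tiny_estimator(psf_sr, **kw):
    defaults = dict(
        psf=psf_sr, iterations=60, n_patches=60, batch_size=2, patch_size=32,
        base_channels=8, depth=2, initial_lr=2e-4, seed=0,
    )
    defaults.update(kw)
    return ZSDeconvNet2D(**defaults)


class TestTrain2D:
    def test_smoke_descent(self, psf_cam, psf_sr, camera):
        img = small_image(psf_cam, camera)
        est = tiny_estimator(psf_sr, iterations=200, n_patches=100).fit(img)
        losses = est.report_.total_losses
        assert len(losses) == 200
        assert losses[-20:].mean() < losses[:20].mean()

    def test_seed_reproducibility(self, psf_cam, psf_sr, camera):
        img = small_image(psf_cam, camera)
        a = tiny_estimator(psf_sr, iterations=25).fit(img)
        b = tiny_estimator(psf_sr, iterations=25).fit(img)
        assert np.array_equal(a.report_.total_losses, b.report_.total_losses)
        for pa, pb in zip(a.model_.params(), b.model_.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_zero_shot_api_never_sees_clean_reference(self, psf_cam, psf_sr, camera):
        # training consumes only counts: attaching/removing the clean
        # reference cannot change the trained weights
        img = small_image(psf_cam, camera)
        blind = z.NoisyImage(counts=img.counts, camera=img.camera, clean=None)
        a = tiny_estimator(psf_sr, iterations=15).fit(img)
        b = tiny_estimator(psf_sr, iterations=15).fit(blind)
        for pa, pb in zip(a.model_.params(), b.model_.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_missing_psf_rejected(self, camera):
        with pytest.raises(ValueError, match="PSF"):
            ZSDeconvNet2D(psf=None).fit(np.zeros((32, 32)) + 100)


class TestDivergenceGuard:
    def test_nan_loss_restores_last_good_checkpoint(self):
        est = ZSDeconvNet2D()
        model_params = [Param(np.ones(3))]

        class FakeModel:
            def params(self):
                return model_params

        model = FakeModel()
        opt = Adam(model_params, clip_norm=None)
        calls = {"n": 0}

        def serve(it):
            return None

        def loss_of_batch(model, batch):
            calls["n"] += 1
            if calls["n"] >= 4:
                return {"total": float("nan")}
            model_params[0].grad += 0.1
            return {"total": 1.0 / calls["n"]}

        from zsdeconv.training import TrainConfig

        with pytest.warns(UserWarning, match="diverged"):
            report = est._run_loop(model, opt, serve, loss_of_batch,
                                   TrainConfig(iterations=10, batch_size=1))
        assert report.diverged
        assert len(report.loss_components) == 3
        assert np.all(np.isfinite(model_params[0].value))


class TestTrain3D:
    @pytest.fixture(scope="class")
    def bead_stack(self):
        sig_lat = 275.0 / (2 * np.sqrt(2 * np.log(2)))
        sig_ax = 800.0 / (2 * np.sqrt(2 * np.log(2)))
        psf3 = z.make_gaussian_psf(sig_lat, sig_ax, pixel_size=(200.0, 62.5, 62.5),
                                   support=9, support_axial=7)
        ph = z.generate_puncta((20, 40, 40), 20, seed=5, min_separation=6.0,
                               pixel_size=(200.0, 62.5, 62.5))
        cam = z.CameraModel(background_offset_b=100.0, gaussian_variance_beta2=4.0)
        return z.render_noisy(ph, psf3, cam, 15.0, seed=9), psf3

    def test_smoke_descent_and_gar_ablation(self, bead_stack):
        stack, psf3 = bead_stack
        kw = dict(psf=psf3, iterations=40, n_patches=60, batch_size=2,
                  patch_size=24, patch_depth=8, base_channels=6,
                  initial_lr=2e-4, seed=0)
        est = ZSDeconvNet3D(**kw).fit(stack)
        losses = est.report_.total_losses
        assert losses[-10:].mean() < losses[:10].mean()
        assert est.report_.loss_components[0]["gar_dec"] > 0
        est0 = ZSDeconvNet3D(**{**kw, "gamma_gar": 0.0}).fit(stack)
        assert est0.report_.total_losses[-10:].mean() < est0.report_.total_losses[:10].mean()
        # ablation changes the GAR component trace (gap reference removed)
        gar1 = [c["gar_dec"] for c in est.report_.loss_components]
        gar0 = [c["gar_dec"] for c in est0.report_.loss_components]
        assert not np.allclose(gar1, gar0)


class TestTestTimeAdaptation:
    @pytest.fixture(scope="class")
    def pretrained(self, psf_cam, psf_sr, camera):
        img = small_image(psf_cam, camera, seed=3)
        est = tiny_estimator(psf_sr, iterations=120, n_patches=100).fit(img)
        return est

    def test_zero_steps_bit_exact(self, pretrained, psf_cam, camera):
        img = small_image(psf_cam, camera, seed=8)
        adapted = finetune_tta(pretrained, img, steps=0)
        for pa, pb in zip(adapted.model_.params(), pretrained.model_.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_original_model_untouched(self, pretrained, psf_cam, camera):
        before = [p.value.copy() for p in pretrained.model_.params()]
        img = small_image(psf_cam, camera, seed=9)
        finetune_tta(pretrained, img, steps=10)
        for p, b in zip(pretrained.model_.params(), before):
            assert np.array_equal(p.value, b)

    def test_adaptation_reduces_loss_on_timepoint(self, pretrained, psf_cam, psf_sr, camera):
        """50 adaptation steps reduce the self-supervised loss on the new
        timepoint for at least 9 of 10 recorruption seeds."""
        img = small_image(psf_cam, camera, seed=11, photons=8.0)
        params = RecorruptionParams(beta2=4.0, background_b=100.0)
        fm = pretrained.forward_model_
        w = z.LossWeights(mu=0.5, lambda_hessian=0.02)

        def mean_loss(est, seeds):
            vals = []
            for s in seeds:
                pair = recorrupt(img.counts, params, seed=s)
                xin = (pair.input_yhat - est.offset_) / est.scale_
                tgt = (pair.target_ytilde - est.offset_) / est.scale_
                s1, s2 = est.model_.forward(xin[None, None].astype(np.float32))
                vals.append(loss2d(tgt, s1[0, 0], s2[0, 0], fm, w).total)
            return float(np.mean(vals))

        eval_seeds = list(range(500, 510))
        base = mean_loss(pretrained, eval_seeds)
        wins = 0
        seed0 = pretrained.seed
        try:
            for k in range(10):
                pretrained.seed = seed0 + k  # varies the adaptation noise stream
                adapted = pretrained.adapt(img, steps=50)
                if mean_loss(adapted, eval_seeds) <= base:
                    wins += 1
        finally:
            pretrained.seed = seed0
        assert wins >= 9
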