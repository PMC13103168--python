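"""Latent inversion mechanics and the ID/OOD decision rule."""

import numpy as np
import pytest

from ganscreen.detector import (FailureMode, InversionConfig, detect,
                                detect_from_trajectory, invert,
                                invert_trajectories, reconstruction_loss)
from ganscreen.errors import ValidationError
from ganscreen.gan import (GanConfig, build_models, generate,
                           generator_backward_to_z, train_gan)
from ganscreen.synthetic import ImageSample, PhantomSpec, ViewLabel, generate_dataset


@pytest.fixture(scope="module")
def small_models():
    """A briefly trained 16x16 model (enough structure for inversion tests)."""
    cfg = GanConfig(latent_dim=16, resolution=16, base_feature_maps=8,
                    batch_size=8, train_steps=60, seed=3)
    imgs = generate_dataset(32, 0, PhantomSpec(ViewLabel.FRONTAL, 16), 4)
    models, _ = train_gan(build_models(cfg), imgs, cfg)
    return models


def cfg16(**kw):
    base = dict(loss_threshold=0.15, extra_steps=10, max_steps=120, z_seed=5)
    base.update(kw)
    return InversionConfig(**base)


class TestReconstructionLoss:
    def test_zero_iff_exact(self, small_models):
        z = np.random.default_rng(0).standard_normal(16).astype(np.float32)
        x = generate(small_models, z)
        assert reconstruction_loss(small_models, z, x) == 0.0

    def test_matches_elementwise_oracle(self, small_models):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(16).astype(np.float32)
        x = ImageSample(rng.uniform(-1, 1, (16, 16)))
        got = reconstruction_loss(small_models, z, x)
        img = generate(small_models, z).pixels
        expect = sum((img[i, j] - x.pixels[i, j]) ** 2
                     for i in range(16) for j in range(16)) / 256
        assert got == pytest.approx(expect, rel=1e-12)
        assert got >= 0.0

    def test_shape_mismatch(self, small_models):
        with pytest.raises(ValidationError):
            reconstruction_loss(small_models, np.zeros(16), ImageSample(np.zeros((8, 8))))


def test_latent_gradient_matches_finite_differences(small_models):
    """Analytic d(loss)/dz agrees with central differences to 1e-4 relative."""
    import copy
    models = copy.deepcopy(small_models)
    models.generator.cast(np.float64)
    rng = np.random.default_rng(2)
    z = rng.standard_normal((1, 16))
    x = rng.uniform(-1, 1, (1, 1, 16, 16))

    def loss(zv):
        out = models.generator.forward(zv[:, :, None, None], False)
        return float(np.mean((out - x) ** 2))

    out = models.generator.forward(z[:, :, None, None], False)
    grad = generator_backward_to_z(models, 2.0 / out.size * (out - x))[0]
    eps = 1e-6
    for i in range(0, 16, 3):
        zp, zm = z.copy(), z.copy()
        zp[0, i] += eps
        zm[0, i] -= eps
        num = (loss(zp) - loss(zm)) / (2 * eps)
        assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-10)


class TestInvert:
    def test_self_reconstruction_reaches_threshold(self, small_models):
        z_star = np.random.default_rng(3).standard_normal(16).astype(np.float32)
        x = generate(small_models, z_star)
        res = invert(small_models, x, cfg16(loss_threshold=0.01, max_steps=300))
        assert res.reached_threshold
        assert res.loss_trace[res.steps_to_threshold] <= 0.01
        assert res.loss_trace[-1] <= 0.011  # refinement does not blow up

    def test_budget_exhaustion(self, small_models):
        x = ImageSample(np.full((16, 16), 1.0))
        res = invert(small_models, x, cfg16(loss_threshold=1e-9, max_steps=1,
                                            extra_steps=0))
        assert not res.reached_threshold
        assert res.total_steps == 1

    def test_deterministic(self, small_models):
        x = generate_dataset(1, 0, PhantomSpec(ViewLabel.FRONTAL, 16), 9)[0]
        r1 = invert(small_models, x, cfg16())
        r2 = invert(small_models, x, cfg16())
        assert r1.loss_trace == r2.loss_trace
        assert np.array_equal(r1.z_final, r2.z_final)

    def test_restarts_pick_lowest_final_loss(self, small_models):
        x = generate_dataset(1, 0, PhantomSpec(ViewLabel.FRONTAL, 16), 10)[0]
        single = invert(small_models, x, cfg16(max_steps=40, extra_steps=0))
        multi = invert(small_models, x, cfg16(max_steps=40, extra_steps=0, restarts=3))
        assert multi.loss_trace[-1] <= single.loss_trace[-1] + 1e-12

    def test_invalid_config(self):
        with pytest.raises(ValidationError):
            InversionConfig(loss_threshold=0.0).validate()
        with pytest.raises(ValidationError):
            InversionConfig(max_steps=5, extra_steps=10).validate()
        with pytest.raises(ValidationError):
            InversionConfig(alpha=0.0).validate()


class TestDetect:
    def test_identity_limit_is_id(self, small_models):
        z_star = np.random.default_rng(4).standard_normal(16).astype(np.float32)
        x = generate(small_models, z_star)
        d = detect(small_models, x, cfg16(loss_threshold=0.02, max_steps=300))
        assert d.failure_mode is FailureMode.NONE
        assert not d.is_ood

    def test_threshold_not_reached_is_ood(self, small_models):
        x = ImageSample(np.full((16, 16), 1.0))
        d = detect(small_models, x, cfg16(loss_threshold=1e-8, max_steps=5,
                                          extra_steps=0))
        assert d.is_ood
        assert d.failure_mode is FailureMode.THRESHOLD_NOT_REACHED
        assert d.ks is not None  # diagnostics still reported

    def test_alpha_one_boundary(self, small_models):
        z_star = np.random.default_rng(6).standard_normal(16).astype(np.float32)
        x = generate(small_models, z_star)
        d = detect(small_models, x, cfg16(loss_threshold=0.05, max_steps=300,
                                          alpha=1.0))
        if d.ks.p_value < 1.0:
            assert d.is_ood

    def test_decision_monotone_in_alpha(self, small_models):
        x = generate_dataset(1, 0, PhantomSpec(ViewLabel.FRONTAL, 16), 11)[0]
        decisions = {}
        for alpha in (0.01, 0.05, 0.2):
            d = detect(small_models, x, cfg16(loss_threshold=0.05, max_steps=300,
                                              alpha=alpha))
            decisions[alpha] = (d.is_ood, d.failure_mode)
        modes = {m for _, m in decisions.values()}
        if modes == {FailureMode.NONE}:
            # ID at some alpha implies ID at every smaller alpha
            for a1 in decisions:
                for a2 in decisions:
                    if a2 < a1 and not decisions[a1][0]:
                        assert not decisions[a2][0]


class TestTrajectoryCache:
    def test_cached_decision_equals_direct(self, small_models):
        """Re-reading a full trajectory under any tau reproduces invert().

        Batched and single-image runs follow the same update rule; tiny
        last-ulp float32 differences can accumulate across Adam steps, so
        traces are compared at tight tolerance while the discrete outcomes
        (threshold hits, step counts, decisions) must agree exactly.
        """
        samples = generate_dataset(2, 2, PhantomSpec(ViewLabel.FRONTAL, 16), 12)
        base = cfg16(max_steps=80, extra_steps=7)
        trajs = invert_trajectories(small_models, samples, base)
        for tau in (0.01, 0.08, 0.3):
            c = cfg16(loss_threshold=tau, max_steps=80, extra_steps=7)
            for x, tj in zip(samples, trajs):
                direct = invert(small_models, x, c)
                cached = detect_from_trajectory(small_models, x, tj, c)
                inv = cached.inversion
                assert inv.reached_threshold == direct.reached_threshold
                assert inv.steps_to_threshold == direct.steps_to_threshold
                assert inv.total_steps == direct.total_steps
                np.testing.assert_allclose(inv.z_final, direct.z_final,
                                           rtol=1e-4, atol=1e-6)
                np.testing.assert_allclose(inv.loss_trace, direct.loss_trace,
                                           rtol=1e-4)
                direct_det = detect(small_models, x, c)
                assert cached.is_ood == direct_det.is_ood

    def test_tau_rereading_is_exact(self, small_models):
        """The same trajectory re-read under different taus is self-consistent:
        identical prefixes, stop indices obeying first-hit + extra-steps."""
        x = generate_dataset(1, 0, PhantomSpec(ViewLabel.FRONTAL, 16), 13)[0]
        base = cfg16(max_steps=80, extra_steps=7)
        tj = invert_trajectories(small_models, [x], base)[0]
        for tau in (1e-6, 0.05, 0.2, 1.0):
            idx, reached, s = tj.stop_index(tau, 7)
            if reached:
                assert tj.losses[s] <= tau
                assert np.all(tj.losses[:s] > tau)
                assert idx == min(s + 7, 79)
            else:
                assert np.all(tj.losses > tau)
                assert idx == 79

    def test_empty_batch(self, small_models):
        assert invert_trajectories(small_models, [], cfg16()) == []
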