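"""Training-loop contracts: the granularity schedule, the loss against an
explicit loop oracle, determinism, the static baseline's frozen motion and
the post-hoc queries of a fitted model."""

import numpy as np
import pandas as pd
import pytest

from nstm import (
    DPCSystem,
    MeasurementSet,
    MLPConfig,
    NSTMModel,
    OptimizerConfig,
    alpha_schedule,
    nstm_loss,
)


SIZE = 16
TINY_MLP = dict(
    scene_mlp=MLPConfig(hidden_layers=1, width=16, out_channels=2),
    motion_mlp=MLPConfig(hidden_layers=1, width=8, out_channels=2, zero_init_final=True),
)


@pytest.fixture(scope="module")
def tiny_system():
    return DPCSystem.from_optics((SIZE, SIZE))


@pytest.fixture(scope="module")
def tiny_measurements(tiny_system):
    rng = np.random.default_rng(0)
    images = 0.01 * rng.normal(size=(4, SIZE, SIZE))
    return MeasurementSet(images, tiny_system.times, "dpc")


def tiny_model(measurements, system, **opt):
    defaults = dict(epochs=20, lr_motion=3e-3, lr_scene=3e-3, seed=0)
    defaults.update(opt)
    return NSTMModel(
        measurements, system, optimizer=OptimizerConfig(**defaults), **TINY_MLP
    )


class TestAlphaSchedule:
    def test_starts_at_zero(self):
        assert alpha_schedule(0, 100, 0.8) == 0.0

    def test_reaches_one_at_ramp_end_and_stays(self):
        # the coarse-to-fine process ends at 80% of the epochs
        assert alpha_schedule(80, 100, 0.8) == 1.0
        assert alpha_schedule(95, 100, 0.8) == 1.0

    def test_linear_ramp_midpoint(self):
        assert alpha_schedule(40, 100, 0.8) == pytest.approx(0.5)

    def test_schedule_monotone(self):
        vals = [alpha_schedule(e, 50, 0.8) for e in range(50)]
        assert np.all(np.diff(vals) >= 0)


class TestOptimizerConfig:
    def test_decay_reaches_tenth_at_end(self):
        cfg = OptimizerConfig(epochs=200)
        assert cfg.learning_rate(0, 1e-3) == pytest.approx(1e-3)
        assert cfg.learning_rate(200, 1e-3) == pytest.approx(1e-4)

    @pytest.mark.parametrize(
        "kwargs", [dict(epochs=0), dict(lr_scene=-1.0), dict(c2f_end_fraction=0.0)]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OptimizerConfig(**kwargs)


class TestLoss:
    def test_self_consistent_measurements_give_zero_loss(self, tiny_system):
        # measurements rendered from the model itself: perfect fit, no reg
        model = tiny_model(
            MeasurementSet(np.zeros((4, SIZE, SIZE)), tiny_system.times, "dpc"),
            tiny_system,
        )
        nstm = model._build(seed=1)
        scene = nstm.render_scene(0.0, (SIZE, SIZE))  # motion is zero-init
        raw = tiny_system.simulate(lambda t: scene)
        ms = MeasurementSet(raw, tiny_system.times, "dpc")
        loss, report = nstm_loss(nstm, tiny_system, ms, alpha=1.0)
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert report["reg"] == 0.0

    def test_residual_scaling_is_quadratic(self, tiny_system):
        rng = np.random.default_rng(3)
        model = tiny_model(
            MeasurementSet(np.zeros((4, SIZE, SIZE)), tiny_system.times, "dpc"),
            tiny_system,
        )
        nstm = model._build(seed=1)
        scene = nstm.render_scene(0.0, (SIZE, SIZE))
        raw = tiny_system.simulate(lambda t: scene)
        resid = rng.normal(size=raw.shape)
        loss1, _ = nstm_loss(
            nstm, tiny_system, MeasurementSet(raw + resid, tiny_system.times, "dpc")
        )
        loss2, _ = nstm_loss(
            nstm, tiny_system, MeasurementSet(raw + 2 * resid, tiny_system.times, "dpc")
        )
        assert loss2 == pytest.approx(4.0 * loss1, rel=1e-6)

    def test_matches_per_measurement_loop_oracle(self, tiny_system, tiny_measurements):
        model = tiny_model(tiny_measurements, tiny_system)
        nstm = model._build(seed=2)
        nstm.motion.mlp.biases[-1][:] = [0.1, -0.2]  # nonzero motion
        alpha = 0.7
        loss, _ = nstm_loss(nstm, tiny_system, tiny_measurements, alpha=alpha,
                            tikhonov_weight=1e-4)
        # oracle: render each measurement independently, loop over pixels
        total = 0.0
        reg = 0.0
        for i, t in enumerate(tiny_system.times):
            scene = nstm.render_scene(float(t), (SIZE, SIZE), alpha=alpha)
            pred = tiny_system.render(scene.astype(np.float64), i)
            sq = 0.0
            for r in range(SIZE):
                for c in range(SIZE):
                    sq += (pred[r, c] - tiny_measurements.images[i, r, c]) ** 2
            total += sq / SIZE**2 / 4
            reg += 1e-4 * np.mean(scene.astype(np.float64) ** 2) / 4
        assert loss == pytest.approx(total + reg, rel=1e-5)


class TestFit:
    def test_same_seed_identical_final_loss(self, tiny_system, tiny_measurements):
        model = tiny_model(tiny_measurements, tiny_system)
        r1 = model.fit()
        r2 = model.fit()
        assert r1.loss_report["loss"].iloc[-1] == r2.loss_report["loss"].iloc[-1]

    def test_loss_decreases(self, tiny_system, tiny_measurements):
        res = tiny_model(tiny_measurements, tiny_system, epochs=40).fit()
        rep = res.loss_report
        assert rep["data"].iloc[-1] < rep["data"].iloc[0]

    def test_alpha_column_nondecreasing_and_saturates(self, tiny_system, tiny_measurements):
        res = tiny_model(tiny_measurements, tiny_system, epochs=30).fit()
        alphas = res.loss_report["alpha"].to_numpy()
        assert np.all(np.diff(alphas) >= 0)
        assert alphas[int(0.8 * 30)] == 1.0

    def test_divergence_aborts_with_diagnostic(self, tiny_system, tiny_measurements):
        model = tiny_model(
            tiny_measurements,
            tiny_system,
            epochs=100,
            lr_scene=500.0,
            lr_motion=500.0,
            divergence_patience=5,
        )
        with pytest.raises((RuntimeError, FloatingPointError)):
            model.fit()

    def test_measurement_count_mismatch_rejected(self, tiny_system):
        bad = MeasurementSet(np.zeros((3, SIZE, SIZE)), np.linspace(0, 1, 3), "dpc")
        with pytest.raises(ValueError, match="expected 4"):
            NSTMModel(bad, tiny_system)


class TestStaticBaseline:
    def test_motion_network_untouched(self, tiny_system, tiny_measurements):
        model = tiny_model(tiny_measurements, tiny_system)
        res = model.fit_static()
        fresh = model._build(seed=model.optimizer.seed)
        for name, val in res.nstm.motion.params().items():
            assert np.array_equal(val, fresh.motion.params()[name]), name

    def test_static_render_time_independent(self, tiny_system, tiny_measurements):
        res = tiny_model(tiny_measurements, tiny_system).fit_static()
        assert np.array_equal(res.render(0.0), res.render(0.77))

    def test_static_flag_recorded(self, tiny_system, tiny_measurements):
        res = tiny_model(tiny_measurements, tiny_system).fit_static()
        assert res.static
        assert "static" in res.summary()


@pytest.fixture(scope="module")
def fitted(tiny_system, tiny_measurements):
    return tiny_model(tiny_measurements, tiny_system, epochs=15).fit()


class TestPostHocQueries:

    def test_interpolation_frame_count_and_consistency(self, fitted, tiny_system):
        times = [0.0, 0.4, 1.0]
        frames = fitted.interpolate(times)
        assert frames.shape[0] == 3
        # at a measurement time the frame equals the rendered scene exactly
        assert np.array_equal(frames[0], fitted.render(0.0))
        assert np.all(np.isfinite(frames))

    def test_zero_motion_trajectory_constant(self, tiny_system, tiny_measurements):
        res = tiny_model(tiny_measurements, tiny_system).fit_static()
        traj = res.motion_trajectory([5.0, 8.0], np.linspace(0, 1, 7))
        assert np.allclose(traj, traj[0])

    def test_constant_bias_motion_gives_uniform_kernel(self, fitted):
        nstm = fitted.nstm
        saved = [b.copy() for b in nstm.motion.mlp.biases]
        for w in nstm.motion.mlp.weights:
            w[:] = 0.0
        nstm.motion.mlp.biases[-1][:] = np.arctanh(
            np.array([0.3, -0.2], dtype=np.float32)
        )
        try:
            kernel = fitted.motion_kernel(0.5)
            assert np.allclose(kernel[0], kernel[0].flat[0], atol=1e-6)
            assert np.allclose(kernel[1], kernel[1].flat[0], atol=1e-6)
            # displacement since the same time point vanishes identically
            assert np.allclose(fitted.motion_kernel(0.5, 0.5), 0.0)
        finally:
            for b, s in zip(nstm.motion.mlp.biases, saved):
                b[:] = s

    def test_summary_reports_final_loss(self, fitted):
        text = fitted.summary()
        assert "final loss" in text
        assert "dpc" in text
        assert f"{len(fitted.loss_report)}" in text

    def test_loss_report_is_dataframe_with_epoch_rows(self, fitted):
        assert isinstance(fitted.loss_report, pd.DataFrame)
        assert len(fitted.loss_report) == 15
        assert set(["epoch", "loss", "data", "reg", "alpha"]) <= set(
            fitted.loss_report.columns
        )
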