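"""Motion/scene network contracts: zero initialisation, granularity
behaviour, time independence of the scene network, and gradient exactness
of the composed model."""

import numpy as np
import pytest

from nstm.fields import MLP, MLPConfig, MotionField, NSTM, SceneField, raster_coordinates
from nstm.hashgrid import HashGridConfig


def small_hash(dims, levels=3):
    return HashGridConfig(
        num_levels=levels,
        base_resolution=4,
        level_scale=1.8,
        features_per_level=2,
        table_size=2**12,
        spatial_dims=dims,
        init_scale=0.5,
    )


@pytest.fixture
def motion2d(rng):
    return MotionField(
        2,
        hash_config=small_hash(3),
        mlp_config=MLPConfig(hidden_layers=2, width=16, out_channels=2, zero_init_final=True),
        rng=rng,
    )


@pytest.fixture
def scene2d(rng):
    return SceneField(
        2,
        out_channels=2,
        hash_config=small_hash(2),
        mlp_config=MLPConfig(hidden_layers=2, width=16, out_channels=2),
        rng=rng,
    )


class TestMotionField:
    def test_zero_initialised_final_layer_gives_zero_displacement(self, motion2d, rng):
        x = rng.uniform(0, 1, (30, 2))
        dx, _ = motion2d.displacement(x, 0.7)
        assert np.all(dx == 0.0)

    def test_alpha_zero_displacement_constant(self, motion2d, rng):
        # all embedding features silenced: only the MLP bias path remains
        motion2d.mlp.weights[-1] = rng.normal(0, 0.5, motion2d.mlp.weights[-1].shape)
        motion2d.mlp.biases[0][:] = rng.normal(0, 0.5, motion2d.mlp.biases[0].shape)
        dx_a, _ = motion2d.displacement(rng.uniform(0, 1, (9, 2)), 0.1, alpha=0.0)
        dx_b, _ = motion2d.displacement(rng.uniform(0, 1, (9, 2)), 0.9, alpha=0.0)
        assert np.allclose(dx_a, dx_a[0])
        assert np.allclose(dx_a, dx_b)

    def test_displacement_bounded(self, motion2d, rng):
        motion2d.mlp.weights[-1] = rng.normal(0, 50.0, motion2d.mlp.weights[-1].shape)
        dx, _ = motion2d.displacement(rng.uniform(0, 1, (50, 2)), 0.3)
        assert np.all(np.abs(dx) <= motion2d.max_displacement)

    def test_spatial_jacobian_matches_finite_differences(self, motion2d, rng):
        motion2d.mlp.weights[-1] = rng.normal(0, 0.3, motion2d.mlp.weights[-1].shape)
        x = rng.uniform(0.1, 0.9, (5, 2))
        dx, cache = motion2d.displacement(x, 0.4)
        gdx = rng.normal(size=dx.shape)
        _, gx = motion2d.displacement_vjp(cache, gdx, want_coord_grad=True)
        eps = 1e-6
        for p in range(5):
            for k in range(2):
                xp, xm = x.copy(), x.copy()
                xp[p, k] += eps
                xm[p, k] -= eps
                fp, _ = motion2d.displacement(xp, 0.4)
                fm, _ = motion2d.displacement(xm, 0.4)
                num = ((fp - fm) / (2 * eps) * gdx).sum(axis=1)[p]
                assert num == pytest.approx(gx[p, k], rel=1e-4, abs=1e-8)

    def test_dimension_mismatch_rejected(self, motion2d, rng):
        with pytest.raises(ValueError):
            motion2d.displacement(rng.uniform(0, 1, (5, 3)), 0.1)


class TestSceneField:
    def test_alpha_zero_spatially_constant(self, scene2d, rng):
        out, _ = scene2d.values(rng.uniform(0, 1, (25, 2)), alpha=0.0)
        assert np.allclose(out, out[0])

    def test_function_of_adjusted_coordinate_only(self, scene2d, rng):
        # two raster points displaced onto the same location agree exactly
        x_adj = np.array([[0.3, 0.6]])
        a, _ = scene2d.values(x_adj)
        b, _ = scene2d.values(x_adj.copy())
        assert np.array_equal(a, b)

    def test_batching_is_semantics_free(self, scene2d, rng):
        x = rng.uniform(0, 1, (33, 2))
        full, _ = scene2d.values(x, 0.8)
        looped = np.concatenate(
            [scene2d.values(x[i : i + 1], 0.8)[0] for i in range(33)]
        )
        assert np.allclose(full, looped, atol=1e-12)

    def test_softplus_output_nonnegative(self, rng):
        sf = SceneField(
            2,
            out_channels=1,
            hash_config=small_hash(2),
            mlp_config=MLPConfig(width=16, out_channels=1, out_activation="softplus"),
            rng=rng,
        )
        out, _ = sf.values(rng.uniform(0, 1, (40, 2)))
        assert np.all(out >= 0.0)

    def test_parameter_gradients_match_finite_differences(self, scene2d, rng):
        x = rng.uniform(0.1, 0.9, (12, 2))
        out, cache = scene2d.values(x, 0.9)
        gout = rng.normal(size=out.shape)
        grads, _ = scene2d.values_vjp(cache, gout)
        params = scene2d.params()
        eps = 1e-6
        for name in ["scene.W0", "scene.b1", "scene.table0", "scene.W2"]:
            arr = params[name]
            idx = (0,) * arr.ndim
            orig = arr[idx]
            arr[idx] = orig + eps
            op, _ = scene2d.values(x, 0.9)
            arr[idx] = orig - eps
            om, _ = scene2d.values(x, 0.9)
            arr[idx] = orig
            num = ((op - om) / (2 * eps) * gout).sum()
            assert num == pytest.approx(grads[name][idx], rel=1e-5, abs=1e-9)


class TestNSTM:
    def make_model(self, rng, nonzero_motion=False):
        motion = MotionField(
            2,
            hash_config=small_hash(3),
            mlp_config=MLPConfig(width=16, out_channels=2, zero_init_final=True),
            rng=rng,
        )
        scene = SceneField(
            2,
            out_channels=1,
            hash_config=small_hash(2),
            mlp_config=MLPConfig(width=16, out_channels=1),
            rng=rng,
        )
        if nonzero_motion:
            motion.mlp.weights[-1] = rng.normal(0, 0.2, motion.mlp.weights[-1].shape)
        return NSTM(motion, scene)

    def test_static_motion_renders_time_independent(self, rng):
        model = self.make_model(rng)  # motion identically zero
        a = model.render_scene(0.1, (12, 12))
        b = model.render_scene(0.9, (12, 12))
        assert np.array_equal(a, b)
        assert a.shape == (1, 12, 12)

    def test_constant_shift_equals_shifted_evaluation(self, rng):
        model = self.make_model(rng)
        shift = 0.07
        base = model.render_scene(0.0, (20, 20))
        # impose a constant displacement through the motion bias path
        coords = raster_coordinates((20, 20))
        shifted, _ = model.scene.values(coords + np.array([shift, 0.0]), 1.0)
        shifted = shifted.T.reshape(1, 20, 20)
        model.motion.mlp.biases[-1][:] = np.arctanh(
            np.array([shift, 0.0]) / model.motion.max_displacement
        )
        rendered = model.render_scene(0.5, (20, 20))
        assert np.allclose(rendered, shifted, atol=1e-10)
        # and the render differs from the unshifted one
        assert not np.allclose(rendered, base)

    def test_intermediate_times_finite(self, rng):
        model = self.make_model(rng, nonzero_motion=True)
        out = model.render_scene(0.377, (15, 15))
        assert np.all(np.isfinite(out))

    def test_chunked_rendering_identical(self, rng):
        model = self.make_model(rng, nonzero_motion=True)
        model.chunk_size = 17
        chunked = model.render_scene(0.3, (16, 16))
        model.chunk_size = 10**6
        whole = model.render_scene(0.3, (16, 16))
        # identical up to BLAS summation order inside the matmuls
        assert np.allclose(chunked, whole, atol=1e-12)

    def test_joint_gradients_match_finite_differences(self, rng):
        model = self.make_model(rng, nonzero_motion=True)
        x = rng.uniform(0.1, 0.9, (10, 2))
        out, cache = model.forward_points(x, 0.6, alpha=0.9)
        gout = rng.normal(size=out.shape)
        grads = model.forward_points_vjp(cache, gout)
        params = model.params()
        eps = 1e-6
        for name in ["motion.W2", "motion.table1", "scene.table0", "scene.W1"]:
            arr = params[name]
            idx = (0,) * arr.ndim
            orig = arr[idx]
            arr[idx] = orig + eps
            op, _ = model.forward_points(x, 0.6, alpha=0.9)
            arr[idx] = orig - eps
            om, _ = model.forward_points(x, 0.6, alpha=0.9)
            arr[idx] = orig
            num = ((op - om) / (2 * eps) * gout).sum()
            assert num == pytest.approx(grads[name][idx], rel=1e-4, abs=1e-9)

    def test_dimensionality_mismatch_rejected(self, rng):
        motion = MotionField(2, hash_config=small_hash(3), rng=rng)
        scene = SceneField(3, hash_config=small_hash(3), rng=rng)
        with pytest.raises(ValueError):
            NSTM(motion, scene)


class TestRasterCoordinates:
    def test_pixel_centre_convention(self):
        coords = raster_coordinates((2, 4))
        assert coords.shape == (8, 2)
        assert coords[0] == pytest.approx([0.25, 0.125])
        assert coords[-1] == pytest.approx([0.75, 0.875])


class TestMLP:
    def test_invalid_activation_rejected(self):
        with pytest.raises(ValueError):
            MLPConfig(out_activation="swish")

    def test_zero_final_layer_maps_to_activation_of_zero(self, rng):
        mlp = MLP(4, MLPConfig(width=8, out_channels=3, zero_init_final=True), rng)
        out, _ = mlp.forward(rng.normal(size=(5, 4)))
        assert np.all(out == 0.0)
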