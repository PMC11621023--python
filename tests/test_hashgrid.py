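"""Hash-embedding contract: interpolation, hashing, granularity weighting,
and exactness of the hand-derived gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nstm.hashgrid import HashGrid, HashGridConfig, granularity_weights

from conftest import dense_embed_oracle


class TestGranularityWeights:
    @pytest.mark.parametrize("n", [1, 4, 8])
    def test_alpha_one_all_active(self, n):
        assert np.allclose(granularity_weights(1.0, n), 1.0)

    @pytest.mark.parametrize("n", [1, 4, 8])
    def test_alpha_zero_all_silent(self, n):
        assert np.allclose(granularity_weights(0.0, n), 0.0)

    def test_half_alpha_four_levels(self):
        # closed form: coarse half fully on, fine half fully off
        assert np.allclose(granularity_weights(0.5, 4), [1.0, 1.0, 0.0, 0.0])

    def test_out_of_range_alpha_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            w = granularity_weights(1.5, 4)
        assert np.allclose(w, 1.0)

    @given(
        a1=st.floats(0, 1),
        a2=st.floats(0, 1),
        n=st.integers(1, 12),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_alpha_and_level(self, a1, a2, n):
        lo, hi = sorted([a1, a2])
        w_lo, w_hi = granularity_weights(lo, n), granularity_weights(hi, n)
        assert np.all(w_hi >= w_lo - 1e-12)  # monotone in alpha
        assert np.all(np.diff(w_hi) <= 1e-12)  # nonincreasing in level
        assert np.all((w_hi >= 0) & (w_hi <= 1))


class TestConfig:
    def test_resolutions_nondecreasing(self):
        cfg = HashGridConfig(num_levels=6, base_resolution=5, level_scale=1.4)
        assert np.all(np.diff(cfg.resolutions) >= 0)

    def test_output_length(self):
        cfg = HashGridConfig(num_levels=3, features_per_level=4)
        assert cfg.out_features == 12

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(num_levels=0),
            dict(level_scale=1.0),
            dict(table_size=100),
            dict(spatial_dims=5),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HashGridConfig(**kwargs)


class TestEmbed:
    def test_vertex_feature_exact(self, small_grid):
        # on a vertex of a collision-free level the stored feature returns
        res = small_grid.config.resolutions[0]
        coord = np.array([[2 / res, 3 / res]])
        feats, _ = small_grid.embed(coord)
        verts = res + 1
        dense = small_grid.tables[0].reshape(verts, verts, -1)
        assert np.allclose(feats[0, :2], dense[2, 3])

    def test_edge_midpoint_is_mean(self, small_grid):
        res = small_grid.config.resolutions[0]
        coord = np.array([[2.5 / res, 3 / res]])
        feats, _ = small_grid.embed(coord)
        verts = res + 1
        dense = small_grid.tables[0].reshape(verts, verts, -1)
        assert np.allclose(feats[0, :2], 0.5 * (dense[2, 3] + dense[3, 3]))

    @pytest.mark.parametrize("alpha", [None, 1.0, 0.6, 0.3])
    def test_matches_dense_oracle(self, small_grid, rng, alpha):
        coords = rng.uniform(0, 1, (40, 2))
        feats, _ = small_grid.embed(coords, alpha)
        assert np.allclose(feats, dense_embed_oracle(small_grid, coords, alpha))

    def test_out_of_range_clamped(self, small_grid):
        inside, _ = small_grid.embed(np.array([[0.0, 1.0]]))
        outside, _ = small_grid.embed(np.array([[-0.3, 1.7]]))
        assert np.allclose(inside, outside)

    def test_nonfinite_coordinate_raises(self, small_grid):
        with pytest.raises(ValueError, match="finite"):
            small_grid.embed(np.array([[0.5, np.nan]]))

    def test_hashed_level_in_table_bounds(self, rng):
        cfg = HashGridConfig(
            num_levels=3,
            base_resolution=16,
            level_scale=2.0,
            spatial_dims=3,
            table_size=64,
            init_scale=1.0,
        )
        grid = HashGrid(cfg, rng)
        assert not grid.is_dense(2)
        feats, _ = grid.embed(rng.uniform(0, 1, (50, 3)))
        assert np.all(np.isfinite(feats))

    def test_continuity_across_cell_boundary(self, small_grid):
        res = small_grid.config.resolutions[1]
        eps = 1e-9
        left, _ = small_grid.embed(np.array([[3 / res - eps, 0.4]]))
        right, _ = small_grid.embed(np.array([[3 / res + eps, 0.4]]))
        assert np.allclose(left, right, atol=1e-6)


class TestWeightedEmbed:
    def test_alpha_one_identical_to_plain(self, small_grid, rng):
        coords = rng.uniform(0, 1, (10, 2))
        plain, _ = small_grid.embed(coords)
        weighted, _ = small_grid.embed(coords, alpha=1.0)
        assert np.array_equal(plain, weighted)

    def test_fine_levels_exactly_zero(self, small_grid, rng):
        # alpha = 0.5 with N = 2 gives weights (1, 0): level 1 block silent
        coords = rng.uniform(0, 1, (10, 2))
        feats, _ = small_grid.embed(coords, alpha=0.5)
        plain, _ = small_grid.embed(coords)
        assert np.allclose(feats[:, :2], plain[:, :2])
        assert np.all(feats[:, 2:] == 0.0)

    def test_zero_weight_level_gets_zero_table_grad(self, small_grid, rng):
        coords = rng.uniform(0, 1, (10, 2))
        feats, cache = small_grid.embed(coords, alpha=0.5)
        gtables, _ = small_grid.embed_vjp(cache, np.ones_like(feats))
        assert np.all(gtables[1] == 0.0)
        assert np.any(gtables[0] != 0.0)


class TestGradients:
    @pytest.mark.parametrize("dims,table_size", [(2, 2**10), (3, 256), (4, 128)])
    def test_coordinate_gradient_matches_finite_differences(self, rng, dims, table_size):
        cfg = HashGridConfig(
            num_levels=3,
            base_resolution=4,
            level_scale=1.8,
            spatial_dims=dims,
            table_size=table_size,
            init_scale=1.0,
        )
        grid = HashGrid(cfg, rng)
        coords = rng.uniform(0.05, 0.95, (6, dims))
        feats, cache = grid.embed(coords, alpha=0.9)
        gf = rng.normal(size=feats.shape)
        _, gcoords = grid.embed_vjp(cache, gf)
        eps = 1e-6
        for p in range(coords.shape[0]):
            for k in range(dims):
                cp, cm = coords.copy(), coords.copy()
                cp[p, k] += eps
                cm[p, k] -= eps
                fp, _ = grid.embed(cp, alpha=0.9)
                fm, _ = grid.embed(cm, alpha=0.9)
                num = ((fp - fm) / (2 * eps) * gf).sum(axis=1)[p]
                assert num == pytest.approx(gcoords[p, k], rel=1e-4, abs=1e-7)

    def test_table_gradient_matches_finite_differences(self, small_grid, rng):
        coords = rng.uniform(0, 1, (15, 2))
        feats, cache = small_grid.embed(coords, alpha=0.8)
        gf = rng.normal(size=feats.shape)
        gtables, _ = small_grid.embed_vjp(cache, gf)
        eps = 1e-6
        for lvl in range(2):
            for row in [0, 7]:
                orig = small_grid.tables[lvl][row, 0]
                small_grid.tables[lvl][row, 0] = orig + eps
                fp, _ = small_grid.embed(coords, alpha=0.8)
                small_grid.tables[lvl][row, 0] = orig - eps
                fm, _ = small_grid.embed(coords, alpha=0.8)
                small_grid.tables[lvl][row, 0] = orig
                num = ((fp - fm) / (2 * eps) * gf).sum()
                assert num == pytest.approx(gtables[lvl][row, 0], abs=1e-7)

    def test_clamped_coordinates_have_zero_gradient(self, small_grid):
        coords = np.array([[-0.5, 0.5], [0.5, 1.5]])
        feats, cache = small_grid.embed(coords)
        _, gcoords = small_grid.embed_vjp(cache, np.ones_like(feats))
        assert gcoords[0, 0] == 0.0
        assert gcoords[1, 1] == 0.0


class TestTimeResolutionCap:
    def test_axis_resolutions_capped_on_last_axis(self):
        cfg = HashGridConfig(
            num_levels=4, base_resolution=8, level_scale=2.0,
            spatial_dims=3, time_resolution=3,
        )
        for lvl in range(4):
            res = cfg.axis_resolutions(lvl)
            assert res[0] == res[1] == cfg.resolutions[lvl]
            assert res[2] == min(cfg.resolutions[lvl], 3)

    def test_temporal_interpolation_linear_between_sample_vertices(self, rng):
        # with the time axis capped at 3 cells, t = 0, 1/3, 2/3, 1 are grid
        # vertices at every level, so features between two samples are the
        # linear blend of the features at those samples
        cfg = HashGridConfig(
            num_levels=3, base_resolution=6, level_scale=2.0,
            spatial_dims=2, time_resolution=3, init_scale=1.0,
        )
        grid = HashGrid(cfg, rng)
        x = 0.25  # fixed spatial coordinate on a vertex (0.25 * 6 = 1.5? no)
        x = 3.0 / 6.0  # exact spatial vertex at every level (3/6 = 6/12 = 12/24)
        f_a, _ = grid.embed(np.array([[x, 1 / 3]]))
        f_b, _ = grid.embed(np.array([[x, 2 / 3]]))
        f_mid, _ = grid.embed(np.array([[x, 0.5]]))
        assert np.allclose(f_mid, 0.5 * (f_a + f_b), atol=1e-12)

    def test_uncapped_grid_unchanged(self, rng):
        cfg = HashGridConfig(num_levels=2, base_resolution=4, spatial_dims=2)
        for lvl in range(2):
            assert np.all(cfg.axis_resolutions(lvl) == cfg.resolutions[lvl])


class TestSerialization:
    def test_hdf5_roundtrip(self, small_grid, rng, tmp_path):
        import h5py

        coords = rng.uniform(0, 1, (20, 2))
        before, _ = small_grid.embed(coords, 0.7)
        with h5py.File(tmp_path / "grid.h5", "w") as fh:
            small_grid.to_hdf5(fh.create_group("grid"))
        with h5py.File(tmp_path / "grid.h5", "r") as fh:
            loaded = HashGrid.from_hdf5(fh["grid"])
        after, _ = loaded.embed(coords, 0.7)
        assert np.array_equal(before, after)
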