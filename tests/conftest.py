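import numpy as np
import pytest

from nstm import DPCSystem, MotionSpec, make_phantom, render_dataset
from nstm.fields import MLPConfig
from nstm.hashgrid import HashGrid, HashGridConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid(rng):
    """2-level 2D grid, dense at every level, O(1) init scale."""
    cfg = HashGridConfig(
        num_levels=2,
        base_resolution=4,
        level_scale=2.0,
        features_per_level=2,
        table_size=2**10,
        spatial_dims=2,
        init_scale=1.0,
    )
    return HashGrid(cfg, rng)


@pytest.fixture(scope="session")
def dpc_toy():
    """48x48 DPC bead acquisition with 3 px rigid motion + ground truth."""
    system = DPCSystem.from_optics((48, 48))
    phantom = make_phantom(
        "beads",
        (48, 48),
        channels=2,
        channel_scales=(0.1, 1.0),
        n_objects=6,
        radius=2.5,
        seed=7,
    )
    spec = MotionSpec(kind="rigid", magnitude=3.0, seed=7)
    measurements, truth = render_dataset(phantom, spec, system, seed=7)
    return system, phantom, measurements, truth


def dense_embed_oracle(grid: HashGrid, coords: np.ndarray, alpha=None) -> np.ndarray:
    """Brute-force reference: materialise each level's dense vertex grid and
    interpolate with explicit loops.  Only valid when every level is dense."""
    from nstm.hashgrid import granularity_weights

    cfg = grid.config
    d = cfg.spatial_dims
    w_levels = (
        np.ones(cfg.num_levels)
        if alpha is None
        else granularity_weights(alpha, cfg.num_levels)
    )
    out = np.zeros((coords.shape[0], cfg.num_levels * cfg.features_per_level))
    for lvl, res in enumerate(cfg.resolutions):
        assert grid.is_dense(lvl)
        verts = res + 1
        dense = grid.tables[lvl].reshape((verts,) * d + (cfg.features_per_level,))
        for p, c in enumerate(np.clip(coords, 0.0, 1.0)):
            u = c * res
            j = np.minimum(u.astype(int), res - 1)
            f = u - j
            acc = np.zeros(cfg.features_per_level)
            for corner in range(2**d):
                bits = [(corner >> k) & 1 for k in range(d)]
                w = 1.0
                for k, b in enumerate(bits):
                    w *= f[k] if b else 1.0 - f[k]
                acc += w * dense[tuple(j[k] + bits[k] for k in range(d))]
            sl = slice(lvl * cfg.features_per_level, (lvl + 1) * cfg.features_per_level)
            out[p, sl] = w_levels[lvl] * acc
    return out


@pytest.fixture
def tiny_mlp_configs():
    return dict(
        motion=MLPConfig(hidden_layers=1, width=8, out_channels=2, zero_init_final=True),
        scene=MLPConfig(hidden_layers=1, width=16, out_channels=2),
    )
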