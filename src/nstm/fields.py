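"""Coordinate-network fields: the motion MLP, the scene MLP and their pairing.

The model stores a dynamic scene in two small multilayer perceptrons fed by
hash-embedded coordinates.  The *motion* network maps a spatiotemporal
coordinate (x, t) to a displacement vector dx; the *scene* network maps the
motion-adjusted spatial coordinate x + dx to the per-channel scene value.
Because the scene network never sees time, every frame of the dynamic scene
is a deformation of one static reconstruction — the central structural
assumption of the model.

Every forward method returns a cache for the matching ``*_vjp`` method; the
pair gives exact reverse-mode gradients with respect to all learnable
parameters (hash tables, weight matrices, biases) and, where needed, the
query coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hashgrid import HashGrid, HashGridConfig

__all__ = ["MLPConfig", "MLP", "MotionField", "SceneField", "NSTM"]


@dataclass(frozen=True)
class MLPConfig:
    """Architecture of a small fully connected network."""

    hidden_layers: int = 2
    width: int = 32
    out_channels: int = 1
    out_activation: str = "identity"  # identity | softplus | sigmoid | tanh
    zero_init_final: bool = False

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.width < 1 or self.out_channels < 1:
            raise ValueError("hidden_layers, width and out_channels must be >= 1")
        if self.out_activation not in ("identity", "softplus", "sigmoid", "tanh"):
            raise ValueError(f"unknown out_activation {self.out_activation!r}")


def _out_act(name: str, z: np.ndarray):
    """Output nonlinearity value and its elementwise derivative."""
    if name == "identity":
        return z, np.ones_like(z)
    if name == "softplus":
        # numerically stable softplus
        y = np.logaddexp(0.0, z)
        return y, 1.0 / (1.0 + np.exp(-z))
    if name == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-z))
        return s, s * (1.0 - s)
    if name == "tanh":
        y = np.tanh(z)
        return y, 1.0 - y**2
    raise ValueError(name)


class MLP:
    """ReLU MLP with explicit forward/backward passes.

    Weights are He-initialised; the final layer can be zero-initialised so
    the network starts as the constant zero map (used by the motion field so
    training starts from the static model).
    """

    def __init__(
        self,
        in_features: int,
        config: MLPConfig,
        rng: np.random.Generator,
        dtype=np.float64,
    ):
        self.config = config
        self.dtype = np.dtype(dtype)
        widths = [in_features] + [config.width] * config.hidden_layers + [config.out_channels]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for li, (n_in, n_out) in enumerate(zip(widths[:-1], widths[1:])):
            last = li == len(widths) - 2
            if last and config.zero_init_final:
                w = np.zeros((n_in, n_out))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
            self.weights.append(w.astype(self.dtype))
            self.biases.append(np.zeros(n_out, dtype=self.dtype))

    def forward(self, x: np.ndarray):
        h = np.asarray(x, dtype=self.dtype)
        pre = []  # pre-activation of hidden layers
        acts = [h]  # inputs to each layer
        n_layers = len(self.weights)
        for li in range(n_layers):
            z = h @ self.weights[li] + self.biases[li]
            if li < n_layers - 1:
                pre.append(z)
                h = np.maximum(z, 0.0)
                acts.append(h)
            else:
                out, dact = _out_act(self.config.out_activation, z)
        return out, (acts, pre, dact)

    def vjp(self, cache, gy: np.ndarray):
        """Gradients of all weights/biases and of the input."""
        acts, pre, dact = cache
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        g = gy * dact
        for li in range(len(self.weights) - 1, -1, -1):
            gW[li] = acts[li].T @ g
            gb[li] = g.sum(axis=0)
            g = g @ self.weights[li].T
            if li > 0:
                g = g * (pre[li - 1] > 0.0)
        return gW, gb, g


class MotionField:
    """Displacement network over joint (space, time) coordinates.

    Outputs displacement in normalised coordinate units, bounded to
    ``(-max_displacement, max_displacement)`` through a tanh so early
    training cannot throw coordinates far out of the scene.  The final
    linear layer is zero-initialised: the model starts exactly static.
    """

    prefix = "motion"

    def __init__(
        self,
        spatial_dims: int,
        hash_config: HashGridConfig | None = None,
        mlp_config: MLPConfig | None = None,
        max_displacement: float = 0.1,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        if hash_config is None:
            hash_config = HashGridConfig(spatial_dims=spatial_dims + 1)
        if hash_config.spatial_dims != spatial_dims + 1:
            raise ValueError("motion hash grid must embed (x, t) jointly")
        if mlp_config is None:
            mlp_config = MLPConfig(width=32, out_channels=spatial_dims, zero_init_final=True)
        if mlp_config.out_channels != spatial_dims:
            raise ValueError("motion MLP out_channels must equal spatial_dims")
        self.spatial_dims = spatial_dims
        self.max_displacement = max_displacement
        self.dtype = np.dtype(dtype)
        self.grid = HashGrid(hash_config, rng, dtype=dtype)
        self.mlp = MLP(hash_config.out_features, mlp_config, rng, dtype=dtype)

    def displacement(self, x: np.ndarray, t, alpha: float = 1.0):
        """dx(x, t): displacement for each spatial coordinate at time t."""
        x = np.atleast_2d(np.asarray(x, dtype=self.dtype))
        if x.shape[1] != self.spatial_dims:
            raise ValueError(
                f"expected {self.spatial_dims}-dim spatial coords, got {x.shape[1]}"
            )
        t_col = np.broadcast_to(np.asarray(t, dtype=self.dtype), (x.shape[0],))
        coords = np.concatenate([x, t_col[:, None]], axis=1)
        feats, ecache = self.grid.embed(coords, alpha)
        raw, mcache = self.mlp.forward(feats)
        th = np.tanh(raw)
        dx = self.max_displacement * th
        return dx, (ecache, mcache, th)

    def displacement_vjp(self, cache, gdx: np.ndarray, *, want_coord_grad=False):
        ecache, mcache, th = cache
        graw = gdx * self.max_displacement * (1.0 - th**2)
        gW, gb, gfeats = self.mlp.vjp(mcache, graw)
        gtables, gcoords = self.grid.embed_vjp(
            ecache, gfeats, want_coord_grad=want_coord_grad
        )
        grads = _pack_grads(self.prefix, gtables, gW, gb)
        gx = gcoords[:, : self.spatial_dims] if gcoords is not None else None
        return grads, gx

    def params(self) -> dict[str, np.ndarray]:
        return _pack_params(self.prefix, self.grid, self.mlp)


class SceneField:
    """Time-independent scene network over spatial coordinates.

    ``out_activation`` fixes the physical range of the channels: softplus
    for a nonnegative fluorescent density, identity for phase/absorption
    pairs, sigmoid for RGB intensity.
    """

    prefix = "scene"

    def __init__(
        self,
        spatial_dims: int,
        out_channels: int = 1,
        hash_config: HashGridConfig | None = None,
        mlp_config: MLPConfig | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        if hash_config is None:
            hash_config = HashGridConfig(spatial_dims=spatial_dims)
        if hash_config.spatial_dims != spatial_dims:
            raise ValueError("scene hash grid dimensionality mismatch")
        if mlp_config is None:
            mlp_config = MLPConfig(width=128, out_channels=out_channels)
        if mlp_config.out_channels != out_channels:
            raise ValueError("scene MLP out_channels mismatch")
        self.spatial_dims = spatial_dims
        self.out_channels = out_channels
        self.dtype = np.dtype(dtype)
        self.grid = HashGrid(hash_config, rng, dtype=dtype)
        self.mlp = MLP(hash_config.out_features, mlp_config, rng, dtype=dtype)

    def values(self, x_adj: np.ndarray, alpha: float = 1.0):
        """Scene value o at (motion-adjusted) spatial coordinates."""
        x_adj = np.atleast_2d(np.asarray(x_adj, dtype=self.dtype))
        feats, ecache = self.grid.embed(x_adj, alpha)
        out, mcache = self.mlp.forward(feats)
        return out, (ecache, mcache)

    def values_vjp(self, cache, gout: np.ndarray, *, want_coord_grad=True):
        ecache, mcache = cache
        gW, gb, gfeats = self.mlp.vjp(mcache, gout)
        gtables, gcoords = self.grid.embed_vjp(
            ecache, gfeats, want_coord_grad=want_coord_grad
        )
        return _pack_grads(self.prefix, gtables, gW, gb), gcoords

    def params(self) -> dict[str, np.ndarray]:
        return _pack_params(self.prefix, self.grid, self.mlp)


def _pack_params(prefix: str, grid: HashGrid, mlp: MLP) -> dict[str, np.ndarray]:
    out = {f"{prefix}.table{i}": t for i, t in enumerate(grid.tables)}
    for i, (w, b) in enumerate(zip(mlp.weights, mlp.biases)):
        out[f"{prefix}.W{i}"] = w
        out[f"{prefix}.b{i}"] = b
    return out


def _pack_grads(prefix: str, gtables, gW, gb) -> dict[str, np.ndarray]:
    out = {f"{prefix}.table{i}": g for i, g in enumerate(gtables)}
    for i, (w, b) in enumerate(zip(gW, gb)):
        out[f"{prefix}.W{i}"] = w
        out[f"{prefix}.b{i}"] = b
    return out


class NSTM:
    """The paired motion and scene fields plus a shared granularity value.

    Rendering a frame at time ``t`` evaluates, for every raster coordinate
    x: dx = motion(x, t) and o = scene(x + dx).  ``alpha_motion`` /
    ``alpha_scene`` default to the shared ``alpha`` but can be overridden
    per network.
    """

    def __init__(
        self,
        motion: MotionField | None,
        scene: SceneField,
        chunk_size: int = 65536,
    ):
        if motion is not None and motion.spatial_dims != scene.spatial_dims:
            raise ValueError("motion and scene spatial dimensionality disagree")
        self.motion = motion
        self.scene = scene
        self.chunk_size = chunk_size
        self.alpha = 1.0

    @property
    def spatial_dims(self) -> int:
        return self.scene.spatial_dims

    # -------------------------------------------------------------- #
    def forward_points(
        self,
        x: np.ndarray,
        t,
        alpha: float | None = None,
        *,
        static: bool = False,
        alpha_motion: float | None = None,
        alpha_scene: float | None = None,
    ):
        """Evaluate o(x, t) with caches for the backward pass.

        ``static=True`` bypasses the motion network entirely (dx = 0),
        which is the motion-blind baseline's evaluation path.
        """
        alpha = self.alpha if alpha is None else alpha
        a_m = alpha if alpha_motion is None else alpha_motion
        a_s = alpha if alpha_scene is None else alpha_scene
        x = np.atleast_2d(np.asarray(x, dtype=self.scene.dtype))
        if static or self.motion is None:
            out, scache = self.scene.values(x, a_s)
            return out, ("static", scache)
        dx, mcache = self.motion.displacement(x, t, a_m)
        out, scache = self.scene.values(x + dx, a_s)
        return out, ("joint", scache, mcache)

    def forward_points_vjp(self, cache, gout: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of all parameters from the upstream scene-value grad."""
        gout = np.asarray(gout, dtype=self.scene.dtype)
        if cache[0] == "static":
            grads, _ = self.scene.values_vjp(cache[1], gout, want_coord_grad=False)
            return grads
        _, scache, mcache = cache
        sgrads, gx_adj = self.scene.values_vjp(scache, gout, want_coord_grad=True)
        mgrads, _ = self.motion.displacement_vjp(mcache, gx_adj)
        sgrads.update(mgrads)
        return sgrads

    # -------------------------------------------------------------- #
    def render_scene(
        self,
        t,
        raster_shape: tuple[int, ...],
        alpha: float | None = None,
        *,
        static: bool = False,
    ) -> np.ndarray:
        """Reconstructed scene at time t, shaped (channels, *raster).

        Chunked evaluation; chunking is semantics-free (pure function of
        the inputs).
        """
        coords = raster_coordinates(raster_shape)
        outs = []
        for start in range(0, coords.shape[0], self.chunk_size):
            o, _ = self.forward_points(
                coords[start : start + self.chunk_size], t, alpha, static=static
            )
            outs.append(o)
        flat = np.concatenate(outs, axis=0)
        return flat.T.reshape((self.scene.out_channels, *raster_shape))

    def params(self) -> dict[str, np.ndarray]:
        out = dict(self.scene.params())
        if self.motion is not None:
            out.update(self.motion.params())
        return out


def raster_coordinates(shape: tuple[int, ...]) -> np.ndarray:
    """Pixel-centre normalised coordinates of a raster, shape (prod, d).

    Pixel index ``j`` along an axis of length ``n`` maps to ``(j + 0.5)/n``,
    avoiding edge bias; axes are ordered as in the array shape.
    """
    axes = [(np.arange(n) + 0.5) / n for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)
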