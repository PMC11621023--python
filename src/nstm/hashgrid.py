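"""Multiresolution hash-encoded feature grids for coordinate networks.

A :class:`HashGrid` stores one learnable feature table per resolution level.
A continuous coordinate in the unit hypercube is embedded by multilinearly
interpolating the features at the surrounding grid vertices of every level
and concatenating the per-level results coarse to fine.  At coarse levels the
dense vertex grid fits in the table and vertices are indexed directly; finer
levels fall back to spatial hashing (XOR of per-axis primes), accepting
collisions.

The grid supports coarse-to-fine training through a granularity value
``alpha`` in [0, 1]: level ``i`` of ``N`` is scaled by

    w_i = 1/2 - 1/2 cos(pi * trunc(alpha * N - i)),      trunc to [0, 1]

so fine levels are exactly zeroed early on and fade in smoothly as ``alpha``
ramps to 1.

All operations provide explicit vector-Jacobian products (reverse-mode
gradients with respect to both the table entries and the query coordinates),
so the grid can sit inside a hand-differentiated training loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HashGridConfig", "HashGrid", "granularity_weights"]

# XOR spatial-hashing primes; first axis left unmultiplied as is conventional.
_PRIMES = np.array([1, 2654435761, 805459861, 3674653429], dtype=np.uint64)


@dataclass(frozen=True)
class HashGridConfig:
    """Hyperparameters of a multiresolution hash grid.

    Parameters
    ----------
    num_levels : int
        Number of resolution levels ``N`` (>= 1).
    base_resolution : int
        Cells per axis at the coarsest level.
    level_scale : float
        Per-level geometric growth factor of the resolution (> 1).
    features_per_level : int
        Feature-vector length stored at each vertex.
    table_size : int
        Maximum number of feature rows per level; power of two.
    spatial_dims : int
        Number of jointly encoded axes (2, 3 or 4; time counts as an axis).
    time_resolution : int, optional
        Cap on the resolution of the last axis at every level.  For a
        spatiotemporal grid whose last axis is time, matching this cap to
        the number of measurement time points keeps every temporal vertex
        constrained by data, so querying between measurement times
        interpolates rather than falling back to untrained features.
    """

    num_levels: int = 8
    base_resolution: int = 8
    level_scale: float = 1.5
    features_per_level: int = 2
    table_size: int = 2**16
    spatial_dims: int = 2
    init_scale: float = 1e-4
    time_resolution: int | None = None

    def __post_init__(self) -> None:
        if self.num_levels < 1:
            raise ValueError("num_levels must be >= 1")
        if self.level_scale <= 1.0:
            raise ValueError("level_scale must be > 1")
        if self.features_per_level < 1:
            raise ValueError("features_per_level must be >= 1")
        if self.spatial_dims not in (2, 3, 4):
            raise ValueError("spatial_dims must be 2, 3 or 4")
        if self.table_size & (self.table_size - 1):
            raise ValueError("table_size must be a power of two")

    @property
    def resolutions(self) -> np.ndarray:
        """Cells per axis at each level (nondecreasing)."""
        i = np.arange(self.num_levels)
        return np.floor(self.base_resolution * self.level_scale**i).astype(np.int64)

    def axis_resolutions(self, level: int) -> np.ndarray:
        """Per-axis cells at ``level``; the last axis honours the time cap."""
        res = np.full(self.spatial_dims, self.resolutions[level], dtype=np.int64)
        if self.time_resolution is not None:
            res[-1] = min(res[-1], self.time_resolution)
        return res

    @property
    def out_features(self) -> int:
        return self.num_levels * self.features_per_level


def granularity_weights(alpha: float, num_levels: int) -> np.ndarray:
    """Per-level coarse-to-fine weights for granularity ``alpha``.

    ``w_i = 1/2 - 1/2 cos(pi * clamp(alpha*N - i, 0, 1))``; nonincreasing in
    the level index ``i`` and nondecreasing in ``alpha``.  ``alpha`` outside
    [0, 1] is clamped with a warning (a well-formed schedule never produces
    it).
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if alpha < 0.0 or alpha > 1.0:
        warnings.warn(
            f"granularity alpha={alpha} outside [0, 1]; clamping", stacklevel=2
        )
        alpha = float(np.clip(alpha, 0.0, 1.0))
    i = np.arange(num_levels)
    t = np.clip(alpha * num_levels - i, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * t)


@dataclass
class _EmbedCache:
    """Saved forward state needed for the backward pass."""

    num_points: int
    level_weights: np.ndarray  # (N,) granularity weights applied
    pass_through: np.ndarray  # (P, d) 1 where coord not clamped
    # per level: (indices (2^d, P), interp weights (2^d, P), fracs (P, d))
    levels: list = field(default_factory=list)


def _corner_bit(corner: int, axis: int) -> int:
    """Which vertex (low/high) corner ``corner`` takes along ``axis``.

    Corners are enumerated by the doubling recursion in ``embed``: the bit
    for axis k sits at position k of the corner index.
    """
    return (corner >> axis) & 1


class HashGrid:
    """Learnable multiresolution feature tables over the unit hypercube.

    Parameters
    ----------
    config : HashGridConfig
    rng : numpy Generator, optional
        Source for the (small, uniform) table initialisation.
    """

    def __init__(
        self,
        config: HashGridConfig,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.tables: list[np.ndarray] = []
        self._dense_shapes: list[tuple[int, ...] | None] = []
        for lvl in range(config.num_levels):
            verts = config.axis_resolutions(lvl) + 1
            dense = int(np.prod(verts))
            if dense <= config.table_size:
                n_rows = dense
                self._dense_shapes.append(tuple(int(v) for v in verts))
            else:
                n_rows = config.table_size
                self._dense_shapes.append(None)
            self.tables.append(
                rng.uniform(
                    -config.init_scale,
                    config.init_scale,
                    size=(n_rows, config.features_per_level),
                ).astype(self.dtype)
            )

    # ------------------------------------------------------------------ #
    def is_dense(self, level: int) -> bool:
        """True when the level's full vertex grid fits in the table."""
        return self._dense_shapes[level] is not None

    def _vertex_index(self, level: int, verts: np.ndarray) -> np.ndarray:
        """Map integer vertex coordinates (P, d) to table rows (P,)."""
        shape = self._dense_shapes[level]
        if shape is not None:
            return np.ravel_multi_index(tuple(verts.T), shape)
        h = np.zeros(verts.shape[0], dtype=np.uint64)
        for k in range(verts.shape[1]):
            h ^= verts[:, k].astype(np.uint64) * _PRIMES[k]
        return (h & np.uint64(self.config.table_size - 1)).astype(np.int64)

    # ------------------------------------------------------------------ #
    def embed(self, coords: np.ndarray, alpha: float | None = None):
        """Embed normalised coordinates into concatenated level features.

        Parameters
        ----------
        coords : (P, d) array
            Query points; components outside [0, 1] are clamped (their
            coordinate gradient is zeroed).  Non-finite input raises.
        alpha : float, optional
            Granularity in [0, 1]; ``None`` means no re-weighting (all 1).

        Returns
        -------
        feats : (P, N * features_per_level) array, levels coarse -> fine.
        cache : opaque state for :meth:`embed_vjp`.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=self.dtype))
        cfg = self.config
        if coords.shape[1] != cfg.spatial_dims:
            raise ValueError(
                f"expected {cfg.spatial_dims}-dim coordinates, got {coords.shape[1]}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinate passed to hash embedding")
        clipped = np.clip(coords, 0.0, 1.0)
        pass_through = ((coords >= 0.0) & (coords <= 1.0)).astype(self.dtype)

        if alpha is None:
            w_levels = np.ones(cfg.num_levels)
        else:
            w_levels = granularity_weights(alpha, cfg.num_levels)
        w_levels = w_levels.astype(self.dtype)

        P = coords.shape[0]
        F = cfg.features_per_level
        d = cfg.spatial_dims
        feats = np.empty((P, cfg.num_levels * F), dtype=self.dtype)
        cache = _EmbedCache(P, w_levels, pass_through)
        for lvl in range(cfg.num_levels):
            res_ax = cfg.axis_resolutions(lvl)
            u = clipped * res_ax.astype(self.dtype)
            base = np.minimum(u.astype(np.int64), res_ax - 1)
            frac = u - base  # in [0, 1]
            # doubling recursion over axes: after axis k the corner bit for
            # axis k is at position k of the row index
            w_c = np.ones((1, P), dtype=self.dtype)
            dense_shape = self._dense_shapes[lvl]
            if dense_shape is not None:
                strides = np.ones(d, dtype=np.int64)
                for k in range(d - 2, -1, -1):
                    strides[k] = strides[k + 1] * dense_shape[k + 1]
                idx_c = np.zeros((1, P), dtype=np.int64)
                for k in range(d):
                    lo = base[:, k] * strides[k]
                    hi = (base[:, k] + 1) * strides[k]
                    idx_c = np.vstack([idx_c + lo, idx_c + hi])
                    w_c = np.vstack([w_c * (1.0 - frac[:, k]), w_c * frac[:, k]])
            else:
                idx_h = np.zeros((1, P), dtype=np.uint64)
                for k in range(d):
                    lo = base[:, k].astype(np.uint64) * _PRIMES[k]
                    hi = (base[:, k] + 1).astype(np.uint64) * _PRIMES[k]
                    idx_h = np.vstack([idx_h ^ lo, idx_h ^ hi])
                    w_c = np.vstack([w_c * (1.0 - frac[:, k]), w_c * frac[:, k]])
                idx_c = (idx_h & np.uint64(cfg.table_size - 1)).astype(np.int64)
            block = np.einsum("cp,cpf->pf", w_c, self.tables[lvl][idx_c])
            feats[:, lvl * F : (lvl + 1) * F] = w_levels[lvl] * block
            cache.levels.append((idx_c, w_c, frac))
        return feats, cache

    def embed_vjp(self, cache: _EmbedCache, gfeats: np.ndarray, *, want_coord_grad=True):
        """Backward pass of :meth:`embed`.

        Parameters
        ----------
        cache : state returned by :meth:`embed`.
        gfeats : (P, N * features_per_level) upstream gradient.
        want_coord_grad : bool
            Skip the coordinate gradient when the query points are fixed.

        Returns
        -------
        gtables : list of per-level arrays matching :attr:`tables`.
        gcoords : (P, d) array or ``None``.
        """
        cfg = self.config
        F = cfg.features_per_level
        d = cfg.spatial_dims
        n_corners = 1 << d
        gtables = [np.zeros_like(t) for t in self.tables]
        gcoords = (
            np.zeros((cache.num_points, d), dtype=self.dtype)
            if want_coord_grad
            else None
        )
        for lvl in range(cfg.num_levels):
            res_ax = cfg.axis_resolutions(lvl)
            w_lvl = cache.level_weights[lvl]
            if w_lvl == 0.0:
                continue
            idx_c, w_c, frac = cache.levels[lvl]
            g_block = w_lvl * gfeats[:, lvl * F : (lvl + 1) * F]  # (P, F)
            # table scatter: one bincount per feature column
            flat_idx = idx_c.ravel()
            n_rows = self.tables[lvl].shape[0]
            for f in range(F):
                gtables[lvl][:, f] += np.bincount(
                    flat_idx,
                    weights=(w_c * g_block[:, f]).ravel(),
                    minlength=n_rows,
                )
            if gcoords is None:
                continue
            # d w_c / d frac_k = sign_k * prod_{m != k} factor_m
            fac01 = np.stack([1.0 - frac, frac])  # (2, P, d)
            gathered = self.tables[lvl][idx_c]  # (2^d, P, F)
            dots = np.einsum("cpf,pf->cp", gathered, g_block)
            for c in range(n_corners):
                dot = dots[c]
                for k in range(d):
                    others = None
                    for m in range(d):
                        if m == k:
                            continue
                        fm = fac01[_corner_bit(c, m), :, m]
                        others = fm if others is None else others * fm
                    if others is None:
                        others = 1.0
                    sign = 1.0 if _corner_bit(c, k) else -1.0
                    gcoords[:, k] += sign * res_ax[k] * others * dot
        if gcoords is not None:
            gcoords *= cache.pass_through
        return gtables, gcoords

    # ------------------------------------------------------------------ #
    def to_hdf5(self, group) -> None:
        """Serialise tables + config into an open ``h5py`` group."""
        cfg = self.config
        for name in (
            "num_levels",
            "base_resolution",
            "level_scale",
            "features_per_level",
            "table_size",
            "spatial_dims",
            "init_scale",
        ):
            group.attrs[name] = getattr(cfg, name)
        if cfg.time_resolution is not None:
            group.attrs["time_resolution"] = cfg.time_resolution
        for lvl, table in enumerate(self.tables):
            group.create_dataset(f"level{lvl}", data=table)

    @classmethod
    def from_hdf5(cls, group) -> "HashGrid":
        cfg = HashGridConfig(
            num_levels=int(group.attrs["num_levels"]),
            base_resolution=int(group.attrs["base_resolution"]),
            level_scale=float(group.attrs["level_scale"]),
            features_per_level=int(group.attrs["features_per_level"]),
            table_size=int(group.attrs["table_size"]),
            spatial_dims=int(group.attrs["spatial_dims"]),
            init_scale=float(group.attrs["init_scale"]),
            time_resolution=(
                int(group.attrs["time_resolution"])
                if "time_resolution" in group.attrs
                else None
            ),
        )
        grid = cls(cfg, dtype=group["level0"].dtype)
        for lvl in range(cfg.num_levels):
            grid.tables[lvl] = np.asarray(group[f"level{lvl}"])
        return grid
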