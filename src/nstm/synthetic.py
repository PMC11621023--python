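"""Synthetic phantoms, ground-truth motion fields and simulated acquisitions.

Stand-ins for the bead and live-cell samples: every stage of the pipeline is
testable against a known scene and a known displacement field.  Motion kinds
mirror the simulation studies of the method's failure modes — rigid-body
(global) shifts, linear drift, local deformable motion of controlled
magnitude, and periodic (vibrating) deformable motion of controlled
frequency — and measurements can carry additive Gaussian noise.

Ground truth is warped with the *pull* convention, sampling the phantom at
``x + dx*(x, t)`` with bilinear interpolation and clamped (zero-flux)
borders, which matches the model's own coordinate-adjustment convention so
simulation and reconstruction agree on what a displacement means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .forward.base import ForwardModel, MeasurementSet

__all__ = [
    "Phantom",
    "MotionSpec",
    "TruthBundle",
    "make_phantom",
    "make_motion",
    "warp",
    "render_dataset",
    "score_recovery",
]


@dataclass
class Phantom:
    """Ground-truth scene: (channels, *raster) array plus provenance."""

    values: np.ndarray
    content: str
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def raster_shape(self) -> tuple:
        return self.values.shape[1:]


@dataclass(frozen=True)
class MotionSpec:
    """Ground-truth motion description.

    kind : 'rigid' | 'linear' | 'deformable' | 'periodic'
    magnitude : peak displacement in pixels.
    frequency : cycles per acquisition (periodic only).
    smoothness : Gaussian smoothing scale in pixels of the deformable field.
    """

    kind: str = "rigid"
    magnitude: float = 3.0
    frequency: float = 1.0
    smoothness: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rigid", "linear", "deformable", "periodic"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass
class TruthBundle:
    """Everything needed to score a recovery against ground truth."""

    phantom: Phantom
    motion: MotionSpec
    fields_px: np.ndarray  # (T, d, *raster) displacement in pixels
    times: np.ndarray  # (T,)
    noise_sigma: float = 0.0


# --------------------------------------------------------------------- #
# phantoms
# --------------------------------------------------------------------- #
def make_phantom(
    content: str,
    raster_shape: tuple,
    *,
    channels: int = 1,
    channel_scales=None,
    n_objects: int = 8,
    radius: float = 3.0,
    min_separation: float | None = None,
    margin: float | None = None,
    seed: int = 0,
) -> Phantom:
    """Deterministic test scene.

    content : 'beads' (hard disks at non-overlapping random centres),
        'tubules' (smooth random curves dilated to tubes), or
        'resolution-target' (bar groups of increasing spatial frequency).
    channel_scales : per-channel multiplier of the base pattern (defaults
        to all ones), e.g. (0.1, 1.0) for a weak-absorption phase sample.
    margin : minimum object distance from the border (beads only).  A
        moving sample must stay inside the field of view — content
        entering or leaving at a clamped border is appearing/disappearing
        structure, which the space-time model excludes by construction —
        so pass at least radius + peak displacement when simulating
        motion.
    """
    # lateral axes need room for structure; a 3D stack may have few planes
    if any(n < 16 for n in raster_shape[-2:]) or any(n < 4 for n in raster_shape):
        raise ValueError("raster must be at least 16 per lateral axis (4 axially)")
    rng = np.random.default_rng(seed)
    if content == "beads":
        base = _beads(raster_shape, n_objects, radius, min_separation, margin, rng)
    elif content == "tubules":
        base = _tubules(raster_shape, n_objects, radius, rng)
    elif content == "resolution-target":
        base = _resolution_target(raster_shape)
    else:
        raise ValueError(f"unknown phantom content {content!r}")
    scales = np.ones(channels) if channel_scales is None else np.asarray(channel_scales)
    if scales.shape != (channels,):
        raise ValueError("channel_scales length must equal channels")
    values = scales[(slice(None),) + (None,) * len(raster_shape)] * base[None]
    return Phantom(
        values,
        content,
        seed,
        {"n_objects": n_objects, "radius": radius},
    )


def _beads(shape, n, radius, min_sep, margin, rng) -> np.ndarray:
    if n == 0:
        return np.zeros(shape)
    min_sep = 2.0 * radius + 2.0 if min_sep is None else min_sep
    margin = radius + 1.0 if margin is None else margin
    # thin axial stacks cannot afford the full lateral margin
    margins = [min(margin, (s - 1.0) / 2.0) for s in shape]
    centers: list[np.ndarray] = []
    for _ in range(20000):
        if len(centers) == n:
            break
        cand = np.array([rng.uniform(m, s - m) for m, s in zip(margins, shape)])
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    else:
        raise ValueError(
            f"could not place {n} beads of radius {radius} with separation "
            f"{min_sep} in raster {shape}"
        )
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    out = np.zeros(shape)
    for c in centers:
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        out[d2 <= radius**2] = 1.0
    return out


def _tubules(shape, n, width, rng) -> np.ndarray:
    d = len(shape)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(max(n // 2, 1)):
        k = 5
        ctrl = np.stack(
            [rng.uniform(0.15 * s, 0.85 * s, size=k) for s in shape], axis=1
        )
        s_par = np.linspace(0.0, 1.0, k)
        spline = CubicSpline(s_par, ctrl, axis=0)
        pts = spline(np.linspace(0.0, 1.0, 40 * max(shape)))
        idx = np.round(pts).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        mask[tuple(idx[ok].T)] = True
    dist = ndimage.distance_transform_edt(~mask)
    return (dist <= width / 2.0).astype(float)


def _resolution_target(shape) -> np.ndarray:
    # bar groups of doubling frequency along the last axis, extruded
    n = shape[-1]
    x = np.arange(n)
    pattern = np.zeros(n)
    period = max(n // 4, 4)
    start = 0
    while start < n and period >= 2:
        seg = slice(start, min(start + n // 4, n))
        pattern[seg] = (x[seg] // (period // 2)) % 2
        start += n // 4
        period //= 2
    out = np.broadcast_to(pattern, shape).copy()
    return out


# --------------------------------------------------------------------- #
# motion
# --------------------------------------------------------------------- #
def make_motion(spec: MotionSpec, raster_shape: tuple, times) -> np.ndarray:
    """Ground-truth displacement fields, shape (T, d, *raster), in pixels.

    rigid : spatially constant shift following a smooth ramp in t, zero at
        the first time point, reaching ``magnitude`` at the last.
    linear : shift = magnitude * t * direction (proportional to absolute t).
    deformable : Gaussian-smoothed random field per axis, cubic-smooth in t,
        zeroed at the first time point and scaled so the peak magnitude
        over (x, t) equals ``magnitude``.
    periodic : one deformable field modulated by sin(2 pi frequency t).
    """
    times = np.asarray(times, dtype=np.float64)
    d = len(raster_shape)
    T = times.shape[0]
    rng = np.random.default_rng(spec.seed)
    out = np.zeros((T, d, *raster_shape))
    if spec.magnitude == 0.0:
        return out

    if spec.kind in ("rigid", "linear"):
        direction = rng.normal(size=d)
        direction /= np.linalg.norm(direction)
        if spec.kind == "linear":
            profile = times
        else:
            span = times[-1] - times[0]
            s = (times - times[0]) / span if span > 0 else np.zeros_like(times)
            profile = 3.0 * s**2 - 2.0 * s**3  # smoothstep, 0 -> 1
        shift = spec.magnitude * profile[:, None] * direction[None, :]
        out = np.broadcast_to(
            shift[(...,) + (None,) * d], (T, d, *raster_shape)
        ).copy()
        return out

    if spec.kind == "deformable":
        k_ctrl = 4
        ctrl_t = np.linspace(times.min(), times.max(), k_ctrl)
        ctrl_fields = np.stack(
            [_smooth_field(raster_shape, d, spec.smoothness, rng) for _ in range(k_ctrl)]
        )
        spline = CubicSpline(ctrl_t, ctrl_fields, axis=0)
        fields = spline(times)
        fields -= fields[0]
    else:  # periodic
        base = _smooth_field(raster_shape, d, spec.smoothness, rng)
        mod = np.sin(2.0 * np.pi * spec.frequency * times)
        fields = mod[(slice(None),) + (None,) * (d + 1)] * base[None]
    peak = np.max(np.sqrt(np.sum(fields**2, axis=1)))
    if peak > 0:
        fields *= spec.magnitude / peak
    return fields


def _smooth_field(raster_shape, d, smoothness, rng) -> np.ndarray:
    field = rng.normal(size=(d, *raster_shape))
    field = ndimage.gaussian_filter(
        field, sigma=(0,) + (smoothness,) * d, mode="reflect"
    )
    rms = np.sqrt(np.mean(field**2))
    return field / max(rms, 1e-12)


# --------------------------------------------------------------------- #
# rendering and scoring
# --------------------------------------------------------------------- #
def warp(scene: np.ndarray, disp_px: np.ndarray) -> np.ndarray:
    """Pull-warp a (channels, *raster) scene by a pixel displacement field.

    out(x) = scene(x + dx(x)); bilinear sampling, clamped at the borders.
    Integer global shifts therefore match an array roll on the interior.
    """
    scene = np.asarray(scene, dtype=np.float64)
    d = scene.ndim - 1
    grids = np.meshgrid(
        *[np.arange(s, dtype=float) for s in scene.shape[1:]], indexing="ij"
    )
    sample = [g + disp_px[k] for k, g in enumerate(grids)]
    return np.stack(
        [
            ndimage.map_coordinates(ch, sample, order=1, mode="nearest")
            for ch in scene
        ]
    )


def render_dataset(
    phantom: Phantom,
    spec: MotionSpec,
    system: ForwardModel,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[MeasurementSet, TruthBundle]:
    """Simulate an acquisition of a moving phantom.

    Measurement i = forward_i(warp(phantom, dx*(., t_i))) + N(0, sigma^2);
    the returned bundle keeps the phantom and the displacement fields at
    the scene-evaluation times for recovery scoring.
    """
    if phantom.raster_shape != system.scene_shape:
        raise ValueError(
            f"phantom raster {phantom.raster_shape} != system scene "
            f"{system.scene_shape}"
        )
    scene_times = np.asarray(system.times, dtype=np.float64)
    fields = make_motion(spec, phantom.raster_shape, scene_times)
    lookup = {float(t): k for k, t in enumerate(scene_times)}

    def scene_at(t: float) -> np.ndarray:
        k = lookup.get(float(t))
        if k is None:  # e.g. SIM group times between raw times
            f = _interp_fields(fields, scene_times, t)
        else:
            f = fields[k]
        return warp(phantom.values, f)

    raw = system.simulate(scene_at)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0.0:
        raw = raw + rng.normal(0.0, noise_sigma, size=raw.shape)
    # the single-raw-image camera has scene times but only one measurement
    meas_times = (
        system.times if raw.shape[0] == len(system.times) else np.zeros(raw.shape[0])
    )
    measurements = MeasurementSet(
        raw,
        meas_times,
        system.modality,
        meta={"noise_sigma": noise_sigma, "seed": seed},
    )
    truth = TruthBundle(phantom, spec, fields, scene_times, noise_sigma)
    return measurements, truth


def _interp_fields(fields, times, t) -> np.ndarray:
    k = np.searchsorted(times, t)
    if k <= 0:
        return fields[0]
    if k >= len(times):
        return fields[-1]
    w = (t - times[k - 1]) / (times[k] - times[k - 1])
    return (1.0 - w) * fields[k - 1] + w * fields[k]


def score_recovery(results, truth: TruthBundle, *, channel: int | None = None) -> dict:
    """Compare a fitted reconstruction against its ground truth.

    Returns
    -------
    dict with
      scene_psnr_db : PSNR of the scene rendered at the first time point
          against the phantom, over an interior region excluding a border
          of the maximum true displacement (capped at 100 dB).
      motion_endpoint_error_px : structure-weighted mean Euclidean error of
          the recovered displacement relative to the first frame, over
          interior pixels and all times.
      frame_displacement_error_px : per-frame error of the structure-
          weighted mean displacement (length T array) and its maximum.

    Motion metrics are weighted by the phantom structure (dilated support
    of the scored channel): displacement carries no information — and is
    left at zero by the model — where the scene is empty.
    """
    phantom = truth.phantom
    shape = phantom.raster_shape
    d = len(shape)
    max_disp = float(np.max(np.sqrt(np.sum(truth.fields_px**2, axis=1))))
    margin = int(np.ceil(max_disp)) + 1
    interior = tuple(slice(margin, s - margin) for s in shape)

    ch = phantom.values.shape[0] - 1 if channel is None else channel
    rec = results.render(float(truth.times[0]))[ch][interior]
    ref = phantom.values[ch][interior]
    peak = float(ref.max() - ref.min()) or 1.0
    mse = float(np.mean((rec - ref) ** 2))
    psnr = 100.0 if mse == 0.0 else min(10.0 * np.log10(peak**2 / mse), 100.0)

    # structure mask: dilated support of the scored channel, interior only
    support = np.abs(phantom.values[ch]) > 0.1 * np.abs(phantom.values[ch]).max()
    support = ndimage.binary_dilation(support, iterations=max(margin, 1))
    weights = np.zeros(shape)
    weights[interior] = support[interior]
    w_sum = weights.sum() or 1.0

    t0 = float(truth.times[0])
    n_t = len(truth.times)
    frame_err = np.zeros(n_t)
    mean_model = np.zeros((n_t, d))
    mean_true = np.zeros((n_t, d))
    endpoint_errs = []
    for k, t in enumerate(truth.times):
        rel_true = truth.fields_px[k] - truth.fields_px[0]
        kernel = results.motion_kernel(float(t), t0)  # (d, *raster)
        diff = kernel - rel_true
        err_map = np.sqrt(np.sum(diff**2, axis=0))
        endpoint_errs.append(np.sum(err_map * weights) / w_sum)
        axes = tuple(range(1, d + 1))
        mean_model[k] = np.sum(kernel * weights, axis=axes) / w_sum
        mean_true[k] = np.sum(rel_true * weights, axis=axes) / w_sum
        frame_err[k] = np.linalg.norm(mean_model[k] - mean_true[k])
    return {
        "scene_psnr_db": float(psnr),
        "motion_endpoint_error_px": float(np.mean(endpoint_errs)),
        "frame_displacement_error_px": frame_err,
        "max_frame_displacement_error_px": float(frame_err.max()),
        "frame_mean_displacement_model_px": mean_model,
        "frame_mean_displacement_true_px": mean_true,
    }
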