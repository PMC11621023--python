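"""Self-contained recovery benchmarks on synthetic phase-contrast toys.

Each function simulates a moving-phantom acquisition, reconstructs it with
the joint space-time model, and scores the result against the known ground
truth.  They are the package's desk-scale counterparts of the full-scale
GPU studies: small rasters, a reduced scene width (64 instead of 128) and
learning rates sized for short runs, so each experiment completes in tens
of seconds on one CPU.  All randomness is controlled by the ``seed``
argument.
"""

from __future__ import annotations

import numpy as np

from .forward.dpc import DPCSystem
from .fields import MLPConfig
from .model import NSTMModel, OptimizerConfig
from .synthetic import MotionSpec, make_phantom, render_dataset, score_recovery

__all__ = [
    "fit_dpc_toy",
    "rigid_recovery",
    "c2f_comparison",
    "degradation_ladder",
    "interpolation_midpoint",
]

# toy-scale reconstruction settings (see docs/methods.md).  The joint
# studies keep the published motion:scene learning-rate ratio (motion ten
# times slower than scene): a faster motion rate lets the scene overfit
# the measurements before the motion is found.
_TOY_LR = dict(lr_motion=3e-3, lr_scene=3e-3, tikhonov_weight=1e-4)
_RATIO_LR = dict(lr_motion=1e-3, lr_scene=1e-2, tikhonov_weight=1e-4)


def fit_dpc_toy(
    size: int,
    spec: MotionSpec,
    *,
    noise_sigma: float = 0.0,
    seed: int = 0,
    epochs: int = 400,
    scene_width: int = 64,
    n_objects: int | None = None,
    radius: float = 2.5,
    margin: float | None = None,
    fixed_alpha: float | None = None,
    static: bool = False,
    pattern_repeats: int = 1,
    lr: dict | None = None,
    max_displacement: float = 0.1,
    motion_hash=None,
):
    """Simulate-and-reconstruct one DPC bead toy; returns (results, truth).

    The phantom is a weak-absorption phase sample (absorption 0.1x the
    phase pattern); the acquisition is the standard four half-circle
    pattern sequence, optionally cycled ``pattern_repeats`` times into a
    time series (used by the vibration study, which needs more time
    samples than a single four-shot capture provides).
    """
    system = DPCSystem.from_optics((size, size))
    if pattern_repeats > 1:
        system = DPCSystem(
            np.tile(system.h_u, (pattern_repeats, 1, 1)),
            np.tile(system.h_p, (pattern_repeats, 1, 1)),
        )
    phantom = make_phantom(
        "beads",
        (size, size),
        channels=2,
        channel_scales=(0.1, 1.0),
        n_objects=max(4, size // 10) if n_objects is None else n_objects,
        radius=radius,
        margin=margin,
        seed=seed,
    )
    measurements, truth = render_dataset(
        phantom, spec, system, noise_sigma=noise_sigma, seed=seed
    )
    model = NSTMModel(
        measurements,
        system,
        motion_hash=motion_hash,
        scene_mlp=MLPConfig(width=scene_width, out_channels=2),
        max_displacement=max_displacement,
        optimizer=OptimizerConfig(epochs=epochs, seed=seed, **(_TOY_LR if lr is None else lr)),
    )
    if static:
        results = model.fit_static()
    else:
        results = model.fit(fixed_alpha=fixed_alpha)
    return results, truth


def rigid_recovery(
    seed: int = 0,
    *,
    size: int = 64,
    magnitude: float = 3.0,
    epochs: int = 1000,
    with_static: bool = True,
) -> dict:
    """Rigid-motion parameter recovery on a size x size, T=4 DPC toy.

    Fits the joint model (and optionally the motion-blind static baseline)
    to a bead phantom translated by ``magnitude`` pixels over the
    acquisition, and reports the per-frame mean-displacement error, the
    signed magnitude error along the true direction, and both scene PSNRs.
    """
    spec = MotionSpec(kind="rigid", magnitude=magnitude, seed=seed)
    kwargs = dict(
        seed=seed, epochs=epochs, n_objects=8, radius=3.0,
        lr=_RATIO_LR, max_displacement=0.2,
    )
    results, truth = fit_dpc_toy(size, spec, **kwargs)
    scores = score_recovery(results, truth)
    out = {
        "psnr_db": scores["scene_psnr_db"],
        "max_frame_displacement_error_px": scores["max_frame_displacement_error_px"],
        "motion_endpoint_error_px": scores["motion_endpoint_error_px"],
    }
    # signed error of the recovered last-frame shift along the true direction
    rel_true = scores["frame_mean_displacement_true_px"][-1]
    rel_model = scores["frame_mean_displacement_model_px"][-1]
    direction = rel_true / np.linalg.norm(rel_true)
    out["signed_displacement_error_px"] = float((rel_model - rel_true) @ direction)
    if with_static:
        static, _ = fit_dpc_toy(size, spec, static=True, **kwargs)
        out["static_psnr_db"] = score_recovery(static, truth)["scene_psnr_db"]
        out["psnr_gain_db"] = out["psnr_db"] - out["static_psnr_db"]
    return out


def c2f_comparison(
    seed: int = 0, *, size: int = 48, magnitude: float = 3.0, epochs: int = 500
) -> dict:
    """Coarse-to-fine necessity on a deformable-motion phantom.

    Fits once with the granularity schedule and once with alpha pinned at 1
    (full granularity from the start); returns both scene PSNRs.
    """
    spec = MotionSpec(kind="deformable", magnitude=magnitude, smoothness=8.0, seed=seed)
    scheduled, truth = fit_dpc_toy(size, spec, seed=seed, epochs=epochs)
    pinned, _ = fit_dpc_toy(size, spec, seed=seed, epochs=epochs, fixed_alpha=1.0)
    return {
        "psnr_c2f_db": score_recovery(scheduled, truth)["scene_psnr_db"],
        "psnr_full_granularity_db": score_recovery(pinned, truth)["scene_psnr_db"],
    }


def degradation_ladder(
    kind: str,
    values,
    seeds=(0, 1, 2),
    *,
    size: int = 32,
    epochs: int = 400,
) -> list[float]:
    """Mean recovery PSNR along a difficulty ladder.

    kind : 'magnitude' (deformable-motion peak, px), 'frequency'
        (vibration cycles per acquisition at 2.5 px magnitude, on a
        16-sample cycled-illumination series — a single 4-shot capture
        under-samples any vibration, so the frequency study runs on the
        time series), or 'noise' (additive Gaussian sigma on the raw
        measurements, at 2 px deformable motion).
    Returns one seed-averaged PSNR per ladder value.
    """
    psnrs = []
    for value in values:
        per_seed = []
        for seed in seeds:
            fit_kwargs = dict(seed=seed, epochs=epochs)
            if kind == "magnitude":
                spec = MotionSpec("deformable", float(value), smoothness=6.0, seed=seed)
            elif kind == "frequency":
                spec = MotionSpec(
                    "periodic", 2.5, frequency=float(value), smoothness=6.0, seed=seed
                )
                fit_kwargs.update(
                    pattern_repeats=4, size=24, epochs=350, n_objects=4
                )
            elif kind == "noise":
                spec = MotionSpec("deformable", 2.0, smoothness=6.0, seed=seed)
                fit_kwargs["noise_sigma"] = float(value)
            else:
                raise ValueError(f"unknown ladder kind {kind!r}")
            fit_size = fit_kwargs.pop("size", size)
            results, truth = fit_dpc_toy(fit_size, spec, **fit_kwargs)
            per_seed.append(score_recovery(results, truth)["scene_psnr_db"])
        psnrs.append(float(np.mean(per_seed)))
    return psnrs


def interpolation_midpoint(
    seed: int = 0, *, size: int = 32, magnitude: float = 3.0, epochs: int = 500
) -> dict:
    """Temporal-interpolation check on a linear-motion bead toy.

    Fits a 16-sample cycled-illumination series (so the midpoint of the
    acquisition falls *between* measurement times), renders the model
    there, and measures how far the bead centroid lies from the midway
    point between its rendered endpoint positions.  The motion grid's
    time axis is capped at the sampling resolution so every temporal
    vertex is constrained by data and inter-sample queries interpolate
    (an unconstrained finer time axis would fall back to untrained
    features between samples); the beads carry a placement margin of
    radius + magnitude so the sample stays inside the field of view.
    """
    from .hashgrid import HashGridConfig

    spec = MotionSpec(kind="linear", magnitude=magnitude, seed=seed)
    repeats = 4
    results, truth = fit_dpc_toy(
        size,
        spec,
        seed=seed,
        epochs=epochs,
        n_objects=5,
        radius=2.5,
        margin=2.5 + magnitude + 1.0,
        pattern_repeats=repeats,
        max_displacement=0.2,
        motion_hash=HashGridConfig(
            spatial_dims=3, time_resolution=4 * repeats - 1
        ),
    )
    t0, t1 = float(truth.times[0]), float(truth.times[-1])

    def centroid(frame):
        img = np.clip(frame[1], 0.0, None)  # phase channel
        img = np.where(img > 0.5 * img.max(), img, 0.0)
        total = img.sum()
        grids = np.meshgrid(*[np.arange(s) for s in img.shape], indexing="ij")
        return np.array([(g * img).sum() / total for g in grids])

    c_start = centroid(results.render(t0))
    c_end = centroid(results.render(t1))
    c_mid = centroid(results.render(0.5 * (t0 + t1)))
    expected = 0.5 * (c_start + c_end)
    return {
        "centroid_error_px": float(np.linalg.norm(c_mid - expected)),
        "endpoint_travel_px": float(np.linalg.norm(c_end - c_start)),
    }
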