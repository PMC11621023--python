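"""Joint scene + motion reconstruction from a multi-shot acquisition.

:class:`NSTMModel` pairs a measurement set with its imaging system's
differentiable forward model and fits the two coordinate networks by
minimising, over the network weights theta_motion and theta_scene,

    sum_i ( forward_i( f( x + f(x, t_i | theta_motion) | theta_scene ) ) - I_i )^2

with the Adam optimiser, an exponentially decaying learning rate (to one
tenth of its initial value at the end of the run) and a coarse-to-fine
schedule on the granularity value alpha: alpha ramps linearly from 0 to 1
over the first ``c2f_end_fraction`` (default 80%) of the epochs, gating fine
hash-embedding levels out of both networks until the coarse structure and
motion have been found.  ``fit`` returns an :class:`NSTMResults` that holds
the trained fields, the per-epoch loss report, and the post-hoc queries
(rendering, temporal interpolation, motion trajectories, motion kernels).

``fit_static`` is the motion-blind control: identical in every setting
except that the motion network is never updated and all time points are set
to zero — the conventional static reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fields import MLPConfig, MotionField, NSTM, SceneField, raster_coordinates
from .forward.base import ForwardModel, MeasurementSet
from .hashgrid import HashGridConfig

__all__ = [
    "OptimizerConfig",
    "alpha_schedule",
    "nstm_loss",
    "NSTMModel",
    "NSTMResults",
]

_OUT_ACTIVATIONS = {"dpc": "identity", "sim": "softplus", "diffusercam": "sigmoid"}


@dataclass(frozen=True)
class OptimizerConfig:
    """Training schedule and optimiser settings.

    Learning rates follow the published recipe: 1e-5 for the motion network
    (5e-5 for the rolling-shutter camera) and 1e-3 for the scene network,
    each decaying exponentially to a tenth of its initial value; the
    coarse-to-fine ramp ends at 80% of the epochs.  Epoch counts are
    problem-sized: 500 (DPC toy), 1000 (SIM toy), 2000 (DiffuserCam toy)
    by default.
    """

    epochs: int = 500
    lr_motion: float = 1e-5
    lr_scene: float = 1e-3
    lr_decay: float = 0.1
    c2f_end_fraction: float = 0.8
    seed: int = 0
    tikhonov_weight: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    divergence_factor: float = 1e3
    divergence_patience: int = 50

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_motion <= 0 or self.lr_scene <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 < self.c2f_end_fraction <= 1.0:
            raise ValueError("c2f_end_fraction must be in (0, 1]")

    def learning_rate(self, epoch: int, base: float) -> float:
        """lr(e) = lr0 * decay^(e / epochs); one tenth at the end."""
        return base * self.lr_decay ** (epoch / self.epochs)


def alpha_schedule(epoch: int, epochs: int, c2f_end_fraction: float = 0.8) -> float:
    """Granularity at ``epoch``: linear ramp hitting 1 at the ramp's end.

    alpha = min(1, epoch / (c2f_end_fraction * epochs)); it reaches exactly
    1 at the end epoch of the coarse-to-fine process and stays there.
    """
    end = c2f_end_fraction * epochs
    if end <= 0:
        return 1.0
    return min(1.0, epoch / end)


class _Adam:
    """Adam with in-place parameter updates and per-group learning rates."""

    def __init__(self, params: dict[str, np.ndarray], cfg: OptimizerConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], epoch: int) -> None:
        cfg = self.cfg
        self.t += 1
        b1c = 1.0 - cfg.beta1**self.t
        b2c = 1.0 - cfg.beta2**self.t
        for name, g in grads.items():
            base = cfg.lr_motion if name.startswith("motion.") else cfg.lr_scene
            lr = cfg.learning_rate(epoch, base)
            m = self.m[name]
            v = self.v[name]
            m *= cfg.beta1
            m += (1.0 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1.0 - cfg.beta2) * g * g
            self.params[name] -= lr * (m / b1c) / (np.sqrt(v / b2c) + cfg.eps)


def _epoch_pass(
    nstm: NSTM,
    units,
    coords: np.ndarray,
    raster_shape: tuple,
    alpha: float,
    tikhonov_weight: float,
    *,
    static: bool = False,
    want_grads: bool = True,
    alpha_motion: float | None = None,
    alpha_scene: float | None = None,
):
    """One full-batch evaluation of the loss (and optionally its gradients).

    Scenes are rendered once per unique time point and shared between the
    render units that need them; gradients flow back through each scene
    exactly once.
    """
    channels = nstm.scene.out_channels
    time_of_unit = []
    unique_times: list[float] = []
    for unit in units:
        idx = []
        for t in unit.times:
            t_eff = 0.0 if static else float(t)
            try:
                idx.append(unique_times.index(t_eff))
            except ValueError:
                unique_times.append(t_eff)
                idx.append(len(unique_times) - 1)
        time_of_unit.append(idx)

    # all unique times in one batched pass: coordinates tiled, times repeated
    P = coords.shape[0]
    n_t = len(unique_times)
    coords_all = np.tile(coords, (n_t, 1))
    t_all = np.repeat(np.asarray(unique_times, dtype=np.float64), P)
    flat, cache = nstm.forward_points(
        coords_all,
        t_all,
        alpha,
        static=static,
        alpha_motion=alpha_motion,
        alpha_scene=alpha_scene,
    )
    if not np.all(np.isfinite(flat)):
        bad = np.unique(t_all[~np.all(np.isfinite(flat), axis=1)])
        raise FloatingPointError(
            f"non-finite scene render at time(s) {bad}; training diverged"
        )
    scenes = [
        flat[k * P : (k + 1) * P].T.reshape((channels, *raster_shape))
        for k in range(n_t)
    ]

    n_units = len(units)
    sgrads = [np.zeros_like(s) for s in scenes] if want_grads else None
    data_loss = 0.0
    for unit, t_idx in zip(units, time_of_unit):
        pred = unit.apply([scenes[k] for k in t_idx])
        resid = pred - unit.target
        data_loss += float(np.mean(resid**2)) / n_units
        if want_grads:
            for k, g in zip(t_idx, unit.vjp(2.0 * resid / resid.size / n_units)):
                sgrads[k] += g

    reg_loss = 0.0
    if tikhonov_weight > 0.0:
        for k, scene in enumerate(scenes):
            reg_loss += tikhonov_weight * float(np.mean(scene**2)) / len(scenes)
            if want_grads:
                sgrads[k] += 2.0 * tikhonov_weight * scene / (scene.size * len(scenes))

    grads: dict[str, np.ndarray] | None = None
    if want_grads:
        gflat = np.concatenate(
            [g.reshape(channels, -1).T for g in sgrads], axis=0
        )  # (n_t * P, C)
        grads = nstm.forward_points_vjp(cache, gflat)
    return data_loss, reg_loss, grads


def nstm_loss(
    nstm: NSTM,
    system: ForwardModel,
    measurements: MeasurementSet,
    alpha: float = 1.0,
    tikhonov_weight: float = 0.0,
    *,
    static: bool = False,
):
    """Evaluate the training loss of a model state against measurements.

    Returns ``(loss, report)`` with the data and regularisation terms split
    out; the data term is the mean squared residual averaged over render
    units.
    """
    units = system.render_units(measurements)
    coords = raster_coordinates(system.scene_shape)
    data, reg, _ = _epoch_pass(
        nstm,
        units,
        coords,
        system.scene_shape,
        alpha,
        tikhonov_weight,
        static=static,
        want_grads=False,
    )
    return data + reg, {"data": data, "reg": reg, "alpha": alpha}


class NSTMModel:
    """Neural space-time model for one acquisition.

    Parameters
    ----------
    measurements : MeasurementSet
        Raw images with their normalised acquisition times.
    system : ForwardModel
        The imaging system's differentiable renderer.
    motion_hash, scene_hash : HashGridConfig, optional
        Embedding hyperparameters; the motion grid jointly encodes
        (x, t) and so has one more axis than the scene grid.
    motion_mlp, scene_mlp : MLPConfig, optional
        Defaults: motion 2 hidden layers of width 32 (linear,
        zero-initialised output), scene 2 hidden layers of width 128 with
        a modality-appropriate output map (softplus density for SIM,
        identity absorption/phase for DPC, sigmoid RGB for DiffuserCam).
    max_displacement : float
        Bound on |dx| in normalised field-of-view units (tanh-limited).
    optimizer : OptimizerConfig, optional
    """

    def __init__(
        self,
        measurements: MeasurementSet,
        system: ForwardModel,
        *,
        motion_hash: HashGridConfig | None = None,
        scene_hash: HashGridConfig | None = None,
        motion_mlp: MLPConfig | None = None,
        scene_mlp: MLPConfig | None = None,
        max_displacement: float = 0.1,
        optimizer: OptimizerConfig | None = None,
        alpha_motion_override: float | None = None,
        alpha_scene_override: float | None = None,
        dtype="float32",
    ):
        system.check_measurements(measurements)
        self.measurements = measurements
        self.system = system
        d = len(system.scene_shape)
        self.motion_hash = motion_hash or HashGridConfig(spatial_dims=d + 1)
        self.scene_hash = scene_hash or HashGridConfig(spatial_dims=d)
        self.motion_mlp = motion_mlp or MLPConfig(
            width=32, out_channels=d, zero_init_final=True
        )
        self.scene_mlp = scene_mlp or MLPConfig(
            width=128,
            out_channels=system.scene_channels,
            out_activation=_OUT_ACTIVATIONS.get(system.modality, "identity"),
        )
        self.max_displacement = max_displacement
        if optimizer is None:
            tik = 1e-4 if system.modality == "dpc" else 0.0
            lr_m = 5e-5 if system.modality == "diffusercam" else 1e-5
            optimizer = OptimizerConfig(tikhonov_weight=tik, lr_motion=lr_m)
        self.optimizer = optimizer
        self.alpha_motion_override = alpha_motion_override
        self.alpha_scene_override = alpha_scene_override
        self.dtype = np.dtype(dtype)

    # ------------------------------------------------------------------ #
    def _build(self, seed: int) -> NSTM:
        rng = np.random.default_rng(seed)
        d = len(self.system.scene_shape)
        motion = MotionField(
            d,
            hash_config=self.motion_hash,
            mlp_config=self.motion_mlp,
            max_displacement=self.max_displacement,
            rng=rng,
            dtype=self.dtype,
        )
        scene = SceneField(
            d,
            out_channels=self.system.scene_channels,
            hash_config=self.scene_hash,
            mlp_config=self.scene_mlp,
            rng=rng,
            dtype=self.dtype,
        )
        return NSTM(motion, scene)

    def fit(
        self,
        *,
        static: bool = False,
        fixed_alpha: float | None = None,
        callback=None,
        **overrides,
    ) -> "NSTMResults":
        """Train the model; returns an :class:`NSTMResults`.

        ``fixed_alpha`` disables the coarse-to-fine schedule (e.g. 1.0
        trains at full granularity from the start); ``overrides`` replace
        fields of the optimiser config for this run.  Reproducible given
        the seed; raises if the loss diverges.
        """
        cfg = replace(self.optimizer, **overrides) if overrides else self.optimizer
        nstm = self._build(cfg.seed)
        units = self.system.render_units(self.measurements)
        coords = raster_coordinates(self.system.scene_shape)
        params = nstm.params()
        if static:
            params = {k: v for k, v in params.items() if not k.startswith("motion.")}
        adam = _Adam(params, cfg)

        rows = []
        initial_loss = None
        bad_epochs = 0
        for epoch in range(cfg.epochs):
            if fixed_alpha is not None:
                alpha = fixed_alpha
            else:
                alpha = alpha_schedule(epoch, cfg.epochs, cfg.c2f_end_fraction)
            data, reg, grads = _epoch_pass(
                nstm,
                units,
                coords,
                self.system.scene_shape,
                alpha,
                cfg.tikhonov_weight,
                static=static,
                alpha_motion=self.alpha_motion_override,
                alpha_scene=self.alpha_scene_override,
            )
            loss = data + reg
            if initial_loss is None:
                initial_loss = loss if loss > 0 else 1.0
            if loss > cfg.divergence_factor * initial_loss:
                bad_epochs += 1
                if bad_epochs >= cfg.divergence_patience:
                    raise RuntimeError(
                        f"training diverged: loss {loss:.3e} exceeded "
                        f"{cfg.divergence_factor:.0e} x initial "
                        f"({initial_loss:.3e}) for {bad_epochs} consecutive epochs"
                    )
            else:
                bad_epochs = 0
            if static:
                grads = {k: v for k, v in grads.items() if not k.startswith("motion.")}
            adam.step(grads, epoch)
            rows.append(
                {
                    "epoch": epoch,
                    "loss": loss,
                    "data": data,
                    "reg": reg,
                    "alpha": alpha,
                    "lr_motion": cfg.learning_rate(epoch, cfg.lr_motion),
                    "lr_scene": cfg.learning_rate(epoch, cfg.lr_scene),
                }
            )
            if callback is not None:
                callback(epoch, rows[-1], nstm)
        report = pd.DataFrame(rows)
        return NSTMResults(self, nstm, report, cfg, static=static)

    def fit_static(self, **overrides) -> "NSTMResults":
        """Motion-blind baseline: motion frozen at zero, all times zero."""
        return self.fit(static=True, **overrides)


class NSTMResults:
    """Trained model state, diagnostics and post-hoc queries."""

    def __init__(
        self,
        model: NSTMModel,
        nstm: NSTM,
        loss_report: pd.DataFrame,
        optimizer: OptimizerConfig,
        *,
        static: bool = False,
    ):
        self.model = model
        self.nstm = nstm
        self.loss_report = loss_report
        self.optimizer = optimizer
        self.static = static

    # -------------------------- rendering ------------------------------ #
    @property
    def raster_shape(self) -> tuple:
        return self.model.system.scene_shape

    def render(self, t: float, raster_shape: tuple | None = None) -> np.ndarray:
        """Reconstructed scene (channels, *raster) at normalised time t."""
        shape = raster_shape or self.raster_shape
        return self.nstm.render_scene(t, shape, alpha=1.0, static=self.static)

    def interpolate(self, times, raster_shape: tuple | None = None) -> np.ndarray:
        """Video frames at arbitrary times (including non-measurement
        times): shape (len(times), channels, *raster)."""
        return np.stack([self.render(float(t), raster_shape) for t in times])

    # -------------------------- motion queries ------------------------- #
    def displacement(self, points_px: np.ndarray, t: float) -> np.ndarray:
        """dx at pixel-coordinate points, returned in pixels."""
        if self.static or self.nstm.motion is None:
            return np.zeros_like(np.atleast_2d(np.asarray(points_px, float)))
        shape = np.asarray(self.raster_shape, dtype=np.float64)
        pts = np.atleast_2d(np.asarray(points_px, dtype=np.float64))
        x = (pts + 0.5) / shape
        dx, _ = self.nstm.motion.displacement(x, t, 1.0)
        return dx * shape

    def motion_trajectory(self, point_px, times) -> np.ndarray:
        """Trajectory of one point: positions (len(times), d) in pixels."""
        point = np.asarray(point_px, dtype=np.float64)
        return np.stack(
            [point + self.displacement(point, float(t))[0] for t in times]
        )

    def motion_kernel(self, t: float, t_prev: float | None = None) -> np.ndarray:
        """Dense displacement field (d, *raster) in pixels at time t.

        With ``t_prev`` given, the field is the displacement *since*
        ``t_prev`` (the motion-kernel overlay convention); ``t_prev = t``
        gives an exactly zero field.
        """
        shape = self.raster_shape
        coords_px = np.stack(
            np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
        ).reshape(-1, len(shape))
        field = self.displacement(coords_px, t)
        if t_prev is not None:
            field = field - self.displacement(coords_px, t_prev)
        return field.T.reshape((len(shape), *shape))

    # -------------------------- reporting ------------------------------ #
    def summary(self) -> str:
        sys_ = self.model.system
        rep = self.loss_report
        n_params = sum(p.size for p in self.nstm.params().values())
        lines = [
            "Neural space-time model reconstruction",
            "=" * 54,
            f"modality:            {sys_.modality}",
            f"scene raster:        {sys_.scene_shape}  x {sys_.scene_channels} channel(s)",
            f"measurements:        {sys_.num_measurements}",
            f"mode:                {'static baseline' if self.static else 'joint motion + scene'}",
            f"parameters:          {n_params}",
            f"epochs:              {len(rep)}",
            f"initial loss:        {rep['loss'].iloc[0]:.6e}",
            f"final loss:          {rep['loss'].iloc[-1]:.6e}",
            f"final data term:     {rep['data'].iloc[-1]:.6e}",
            f"final reg term:      {rep['reg'].iloc[-1]:.6e}",
            f"final alpha:         {rep['alpha'].iloc[-1]:.3f}",
            f"seed:                {self.optimizer.seed}",
        ]
        return "\n".join(lines)

    # -------------------------- persistence ---------------------------- #
    def save(self, path) -> None:
        from .io import save_checkpoint

        save_checkpoint(path, self)

    @classmethod
    def load(cls, path, measurements: MeasurementSet, system: ForwardModel):
        from .io import load_checkpoint

        return load_checkpoint(path, measurements, system)
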