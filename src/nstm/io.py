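"""Readers, writers, configuration schema and checkpointing.

Raw measurements come in as multi-page TIFF (one page per measurement, in
acquisition order) or HDF5; checkpoints are single HDF5 files holding both
hash grids, all MLP weights and the run configuration; outputs are written
as multi-page TIFF (frames), HDF5 (motion fields), PNG (direction-coded
motion visualisations, hue = direction, saturation = magnitude) and CSV
(per-epoch loss report).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml
from matplotlib.colors import hsv_to_rgb
from pydantic import BaseModel, ConfigDict

from .fields import MLPConfig, MotionField, NSTM, SceneField
from .forward import DPCSystem, DiffuserCamSystem, MeasurementSet, SIMSystem
from .hashgrid import HashGrid, HashGridConfig
from .model import NSTMModel, NSTMResults, OptimizerConfig

__all__ = [
    "RunConfig",
    "load_run_config",
    "build_system",
    "read_measurements",
    "normalize_dpc_background",
    "write_outputs",
    "motion_to_rgb",
    "save_checkpoint",
    "load_checkpoint",
]


# --------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------- #
class RunConfig(BaseModel):
    """Validated YAML run description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    modality: Literal["dpc", "sim", "diffusercam"]
    seed: int = 0
    system: dict = {}
    optimizer: dict = {}
    motion_hash: dict = {}
    scene_hash: dict = {}
    motion_mlp: dict = {}
    scene_mlp: dict = {}
    max_displacement: float = 0.1
    raw_path: str | None = None
    out_path: str | None = None


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def build_system(config: RunConfig, scene_shape: tuple):
    """Instantiate the forward model named by the config.

    ``scene_shape`` comes from the data (or the simulation request);
    system parameters are passed through, so an unknown parameter fails
    loudly with its name.
    """
    params = dict(config.system)
    if config.modality == "dpc":
        return DPCSystem.from_optics(scene_shape, **params)
    if config.modality == "sim":
        return SIMSystem(scene_shape, **params)
    if config.modality == "diffusercam":
        psf = params.pop("psf_path", None)
        if psf is not None:
            psf = _read_array(psf)
        else:
            psf = _default_caustic_psf(scene_shape, seed=config.seed)
        return DiffuserCamSystem(psf, **params)
    raise ValueError(config.modality)


def _default_caustic_psf(shape, seed=0, n_caustics=60) -> np.ndarray:
    """Synthetic caustic-like PSF: many sharp points spread over the frame."""
    rng = np.random.default_rng(seed)
    psf = np.zeros(shape)
    idx = tuple(rng.integers(0, s, size=n_caustics) for s in shape)
    psf[idx] = rng.uniform(0.5, 1.0, size=n_caustics)
    from scipy.ndimage import gaussian_filter

    psf = gaussian_filter(psf, 0.6)
    return psf / psf.sum()


def model_from_config(measurements: MeasurementSet, system, config: RunConfig) -> NSTMModel:
    d = len(system.scene_shape)
    kwargs = {}
    if config.motion_hash:
        kwargs["motion_hash"] = HashGridConfig(spatial_dims=d + 1, **config.motion_hash)
    if config.scene_hash:
        kwargs["scene_hash"] = HashGridConfig(spatial_dims=d, **config.scene_hash)
    if config.motion_mlp:
        kwargs["motion_mlp"] = MLPConfig(
            out_channels=d, zero_init_final=True, **config.motion_mlp
        )
    if config.scene_mlp:
        kwargs["scene_mlp"] = MLPConfig(
            out_channels=system.scene_channels, **config.scene_mlp
        )
    opt = dict(config.optimizer)
    opt.setdefault("seed", config.seed)
    if config.modality == "dpc":
        opt.setdefault("tikhonov_weight", 1e-4)
    if config.modality == "diffusercam":
        opt.setdefault("lr_motion", 5e-5)
    return NSTMModel(
        measurements,
        system,
        max_displacement=config.max_displacement,
        optimizer=OptimizerConfig(**opt),
        **kwargs,
    )


# --------------------------------------------------------------------- #
# measurements
# --------------------------------------------------------------------- #
def _read_array(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=np.float64)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            key = "measurements" if "measurements" in fh else next(iter(fh.keys()))
            return np.asarray(fh[key], dtype=np.float64)
    raise ValueError(f"unsupported measurement container {path.suffix!r}")


def normalize_dpc_background(images: np.ndarray) -> np.ndarray:
    """Background-normalise raw DPC intensities: (I - I_bg) / I_bg.

    The background of each image is estimated as its mean intensity.
    Already background-subtracted data (mean approximately zero) is passed
    through unchanged.
    """
    out = np.empty_like(images)
    for i, img in enumerate(images):
        bg = float(img.mean())
        if abs(bg) < 1e-12:
            out[i] = img
        else:
            out[i] = (img - bg) / bg
    return out


def read_measurements(
    path,
    modality: str,
    *,
    n_z: int | None = None,
    times=None,
    normalize: bool = True,
) -> MeasurementSet:
    """Load a raw measurement stack and attach temporal coordinates.

    DPC expects 4 pages (background-normalised on load); SIM expects
    ``n_z * 15`` pages in acquisition order; DiffuserCam expects a single
    RGB image (H, W, 3) or (3, H, W).  A page count that contradicts the
    declared geometry raises, naming expected vs. found.
    """
    data = _read_array(path)
    if modality == "dpc":
        if data.ndim != 3 or data.shape[0] != 4:
            raise ValueError(
                f"dpc: expected 4 measurement pages, found "
                f"{data.shape[0] if data.ndim == 3 else 'non-stack data'}"
            )
        if normalize:
            data = normalize_dpc_background(data)
        t = np.linspace(0, 1, 4) if times is None else np.asarray(times)
        return MeasurementSet(data, t, "dpc")
    if modality == "sim":
        if n_z is None:
            raise ValueError("sim: n_z must be given")
        expected = n_z * 15
        if data.ndim != 3 or data.shape[0] != expected:
            found = data.shape[0] if data.ndim == 3 else "non-stack data"
            raise ValueError(
                f"sim: expected {expected} pages (n_z={n_z} x 15), found {found}"
            )
        t = (
            np.arange(expected) / (expected - 1) if times is None else np.asarray(times)
        )
        return MeasurementSet(data, t, "sim", meta={"n_z": n_z})
    if modality == "diffusercam":
        if data.ndim == 3 and data.shape[-1] in (1, 3):
            data = np.moveaxis(data, -1, 0)
        if data.ndim != 3:
            raise ValueError(
                f"diffusercam: expected one RGB image, found shape {data.shape}"
            )
        return MeasurementSet(data[None], np.zeros(1), "diffusercam")
    raise ValueError(f"unknown modality {modality!r}")


# --------------------------------------------------------------------- #
# outputs
# --------------------------------------------------------------------- #
def motion_to_rgb(field: np.ndarray) -> np.ndarray:
    """Direction-coded colour image of a 2D displacement field (2, H, W).

    Hue encodes the motion direction (colourwheel convention), saturation
    the relative magnitude; for 3D fields pass one z slice.
    """
    if field.shape[0] != 2:
        raise ValueError("motion_to_rgb expects a 2D field (2, H, W)")
    dy, dx = field
    mag = np.sqrt(dy**2 + dx**2)
    hue = (np.arctan2(dy, dx) + np.pi) / (2.0 * np.pi)
    sat = mag / max(mag.max(), 1e-12)
    hsv = np.stack([hue, sat, np.ones_like(hue)], axis=-1)
    return hsv_to_rgb(hsv)


def write_outputs(
    out_dir,
    *,
    frames: np.ndarray | None = None,
    motion_fields: np.ndarray | None = None,
    report: pd.DataFrame | None = None,
    results: NSTMResults | None = None,
) -> dict:
    """Write reconstruction products; returns the paths written.

    frames -> ``frames.tif`` (multi-page, float32); motion fields ->
    ``motion.h5`` plus one colour-coded ``motion_XXX.png`` per time;
    report -> ``loss.csv`` (one row per epoch); results -> ``ckpt.h5``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    if frames is not None and len(frames):
        p = out_dir / "frames.tif"
        tifffile.imwrite(p, np.asarray(frames, dtype=np.float32), photometric="minisblack")
        written["frames"] = p
    if motion_fields is not None:
        p = out_dir / "motion.h5"
        with h5py.File(p, "w") as fh:
            fh.create_dataset("fields_px", data=np.asarray(motion_fields))
        written["motion"] = p
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for k, field in enumerate(np.asarray(motion_fields)):
            vis = field if field.shape[0] == 2 else field[1:, field.shape[1] // 2]
            png = out_dir / f"motion_{k:03d}.png"
            plt.imsave(png, motion_to_rgb(vis))
            written[f"motion_png_{k}"] = png
    if report is not None:
        p = out_dir / "loss.csv"
        report.to_csv(p, index=False)
        written["report"] = p
    if results is not None:
        p = out_dir / "ckpt.h5"
        save_checkpoint(p, results)
        written["checkpoint"] = p
    return written


# --------------------------------------------------------------------- #
# checkpoints
# --------------------------------------------------------------------- #
def _save_mlp(group, mlp) -> None:
    for i, (w, b) in enumerate(zip(mlp.weights, mlp.biases)):
        group.create_dataset(f"W{i}", data=w)
        group.create_dataset(f"b{i}", data=b)
    cfg = mlp.config
    for name in ("hidden_layers", "width", "out_channels", "out_activation", "zero_init_final"):
        group.attrs[name] = getattr(cfg, name)


def _load_mlp_into(group, mlp) -> None:
    for i in range(len(mlp.weights)):
        mlp.weights[i] = np.asarray(group[f"W{i}"])
        mlp.biases[i] = np.asarray(group[f"b{i}"])


def save_checkpoint(path, results: NSTMResults) -> None:
    """Persist the trained fields, configs and loss report to HDF5."""
    nstm = results.nstm
    with h5py.File(path, "w") as fh:
        fh.attrs["modality"] = results.model.system.modality
        fh.attrs["static"] = results.static
        fh.attrs["max_displacement"] = results.model.max_displacement
        fh.attrs["optimizer"] = yaml.safe_dump(dataclasses.asdict(results.optimizer))
        scene = fh.create_group("scene")
        nstm.scene.grid.to_hdf5(scene.create_group("grid"))
        _save_mlp(scene.create_group("mlp"), nstm.scene.mlp)
        if nstm.motion is not None:
            motion = fh.create_group("motion")
            nstm.motion.grid.to_hdf5(motion.create_group("grid"))
            _save_mlp(motion.create_group("mlp"), nstm.motion.mlp)
        rep = fh.create_group("loss_report")
        for col in results.loss_report.columns:
            rep.create_dataset(col, data=results.loss_report[col].to_numpy())


def load_checkpoint(path, measurements: MeasurementSet, system) -> NSTMResults:
    """Rebuild an :class:`NSTMResults` from a checkpoint for post-hoc
    queries (rendering, interpolation, trajectories)."""
    with h5py.File(path, "r") as fh:
        static = bool(fh.attrs["static"])
        max_disp = float(fh.attrs["max_displacement"])
        opt = OptimizerConfig(**yaml.safe_load(fh.attrs["optimizer"]))
        d = len(system.scene_shape)

        def mlp_config(group, zero_final):
            return MLPConfig(
                hidden_layers=int(group.attrs["hidden_layers"]),
                width=int(group.attrs["width"]),
                out_channels=int(group.attrs["out_channels"]),
                out_activation=str(group.attrs["out_activation"]),
                zero_init_final=bool(group.attrs["zero_init_final"]),
            )

        scene_grid = HashGrid.from_hdf5(fh["scene/grid"])
        dtype = scene_grid.tables[0].dtype
        scene = SceneField(
            d,
            out_channels=system.scene_channels,
            hash_config=scene_grid.config,
            mlp_config=mlp_config(fh["scene/mlp"], False),
            dtype=dtype,
        )
        scene.grid = scene_grid
        _load_mlp_into(fh["scene/mlp"], scene.mlp)

        motion = None
        if "motion" in fh:
            motion_grid = HashGrid.from_hdf5(fh["motion/grid"])
            motion = MotionField(
                d,
                hash_config=motion_grid.config,
                mlp_config=mlp_config(fh["motion/mlp"], True),
                max_displacement=max_disp,
                dtype=dtype,
            )
            motion.grid = motion_grid
            _load_mlp_into(fh["motion/mlp"], motion.mlp)

        report = pd.DataFrame(
            {col: np.asarray(fh["loss_report"][col]) for col in fh["loss_report"]}
        )
    nstm = NSTM(motion, scene)
    model = NSTMModel(
        measurements,
        system,
        motion_hash=motion.grid.config if motion is not None else None,
        scene_hash=scene_grid.config,
        max_displacement=max_disp,
        optimizer=opt,
    )
    return NSTMResults(model, nstm, report, opt, static=static)
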