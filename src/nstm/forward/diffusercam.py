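"""Rolling-shutter DiffuserCam forward model.

A lensless camera with a large caustic point-spread function compressively
encodes a short video into one raw image: every sensor row integrates the
scene convolved with the PSF over that row's own exposure window, so the
rolling shutter turns rows into time samples.  With the dynamic scene
discretised at T time points and a binary shutter map S(row, t),

    forward(o)   = sum_t ( o(t) * PSF ) . S(t)                (full frame)
    forward_i(o) = sum_{t : S(i, t) = 1} ( o(t) * PSF ) . S(t)   (rows i)

where * is 2D (circular) convolution and the row-restricted form renders a
chunk of consecutive rows from only the scenes whose shutter overlapped
those rows.  Chunked rendering assembled over all chunks reproduces the
full-frame sum exactly.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from numpy.fft import fft2, ifft2

from .base import ForwardModel, MeasurementSet, RenderUnit

__all__ = ["DiffuserCamSystem", "build_shutter_map"]


def build_shutter_map(
    n_rows: int,
    num_time_points: int,
    readout_time: float,
    exposure: float,
    dual_shutter: bool = False,
):
    """Binary shutter-state map S (n_rows, T) and normalised time stamps.

    Row ``r`` starts reading at ``d(r) * readout_time`` where ``d`` is the
    row index (single shutter) or the distance from the sensor centre
    (dual shutter: the two halves read outward simultaneously); its shutter
    is open on ``[start, start + exposure]``.  The T discrete time points
    are spread uniformly over the total acquisition and each falls in the
    open window of at least one row.
    """
    r = np.arange(n_rows)
    if dual_shutter:
        d = np.floor(np.abs(r + 0.5 - n_rows / 2.0))
    else:
        d = r.astype(float)
    start = d * readout_time
    total = start.max() + exposure
    stamps = (np.arange(num_time_points) + 0.5) / num_time_points * total
    shutter = (stamps[None, :] >= start[:, None]) & (
        stamps[None, :] <= (start[:, None] + exposure)
    )
    if not shutter.any(axis=1).all():
        raise ValueError(
            "some rows have no open time point; increase num_time_points "
            "or the exposure"
        )
    if not shutter.any(axis=0).all():
        raise ValueError("some time points fall in no row's exposure window")
    times = stamps / total  # normalised to [0, 1]
    return shutter.astype(bool), times


class DiffuserCamSystem(ForwardModel):
    """Single-exposure rolling-shutter lensless acquisition.

    Parameters
    ----------
    psf : (H, W) or (C, H, W) caustic PSF (shared across channels when 2D).
    num_time_points : number of discrete scene time points T.
    readout_time, exposure : row readout period and exposure, same units.
    dual_shutter : top/bottom symmetric readout (centre rows first).
    chunk_rows : consecutive rows rendered per forward pass.
    channels : scene channels (3 for RGB).
    """

    modality = "diffusercam"

    def __init__(
        self,
        psf: np.ndarray,
        num_time_points: int = 16,
        readout_time: float = 27.52,
        exposure: float = 1320.0,
        dual_shutter: bool = False,
        chunk_rows: int = 20,
        channels: int = 3,
    ):
        psf = np.asarray(psf, dtype=np.float64)
        if psf.ndim == 2:
            psf = np.broadcast_to(psf, (channels, *psf.shape)).copy()
        if psf.ndim != 3 or psf.shape[0] != channels:
            raise ValueError("psf must be (H, W) or (channels, H, W)")
        self.psf = psf
        self.scene_channels = channels
        self.scene_shape = psf.shape[1:]
        self.num_time_points = num_time_points
        self.chunk_rows = chunk_rows
        self.shutter, self._scene_times = build_shutter_map(
            self.scene_shape[0], num_time_points, readout_time, exposure, dual_shutter
        )
        self._psf_fft = fft2(self.psf)

    # ------------------------------------------------------------------ #
    @property
    def num_measurements(self) -> int:
        return 1  # a single compressive raw image

    @property
    def times(self) -> np.ndarray:
        """Times of the discrete scene evaluations (not of measurements)."""
        return self._scene_times

    def _convolve(self, scene: np.ndarray) -> np.ndarray:
        return np.real(ifft2(fft2(scene) * self._psf_fft))

    def _correlate(self, g: np.ndarray) -> np.ndarray:
        return np.real(ifft2(fft2(g) * np.conj(self._psf_fft)))

    def _check_time(self, t_index: int) -> None:
        if not 0 <= t_index < self.num_time_points:
            raise ValueError(
                f"time index {t_index} outside [0, {self.num_time_points})"
            )

    def render_full(self, scenes: np.ndarray) -> np.ndarray:
        """Full-frame render from scenes at all T time points (T, C, H, W)."""
        scenes = np.asarray(scenes)
        if scenes.shape != (self.num_time_points, self.scene_channels, *self.scene_shape):
            raise ValueError(f"expected all {self.num_time_points} scene frames")
        out = np.zeros((self.scene_channels, *self.scene_shape))
        for t in range(self.num_time_points):
            out += self._convolve(scenes[t]) * self.shutter[None, :, t : t + 1]
        return out

    def active_times(self, rows: slice) -> np.ndarray:
        """Indices of time points with an open shutter in the row range."""
        return np.nonzero(self.shutter[rows].any(axis=0))[0]

    def render_rows(self, scenes, t_indices, rows: slice) -> np.ndarray:
        """Rows of the raw image from the scenes at the listed time points.

        Equals the same rows of :meth:`render_full`; assembling every chunk
        reproduces the full frame exactly.
        """
        out = np.zeros((self.scene_channels, *self.scene_shape))
        for scene, t in zip(scenes, t_indices):
            self._check_time(int(t))
            out += self._convolve(np.asarray(scene)) * self.shutter[None, :, t : t + 1]
        return out[:, rows, :]

    def adjoint_rows(self, g: np.ndarray, t_indices, rows: slice) -> list[np.ndarray]:
        """Per-scene gradients for :meth:`render_rows`."""
        full = np.zeros((self.scene_channels, *self.scene_shape))
        full[:, rows, :] = g
        grads = []
        for t in t_indices:
            grads.append(self._correlate(full * self.shutter[None, :, t : t + 1]))
        return grads

    # ------------------------------------------------------------------ #
    def row_chunks(self) -> list[slice]:
        n_rows = self.scene_shape[0]
        return [
            slice(start, min(start + self.chunk_rows, n_rows))
            for start in range(0, n_rows, self.chunk_rows)
        ]

    def render_units(self, measurements: MeasurementSet) -> list[RenderUnit]:
        self.check_measurements(measurements)
        raw = measurements.images[0]  # (C, H, W)
        units = []
        for rows in self.row_chunks():
            t_idx = self.active_times(rows)
            units.append(
                RenderUnit(
                    times=tuple(float(self._scene_times[t]) for t in t_idx),
                    target=raw[:, rows, :],
                    apply=lambda scenes, ti=t_idx, rs=rows: self.render_rows(
                        scenes, ti, rs
                    ),
                    vjp=lambda g, ti=t_idx, rs=rows: self.adjoint_rows(g, ti, rs),
                    label=f"rows[{rows.start}:{rows.stop}]",
                )
            )
        return units

    def simulate(self, scene_at: Callable[[float], np.ndarray]) -> np.ndarray:
        scenes = np.stack([scene_at(float(t)) for t in self._scene_times])
        return self.render_full(scenes)[None]  # leading measurement axis
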