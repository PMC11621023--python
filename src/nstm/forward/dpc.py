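"""Differential phase contrast (DPC) forward model.

DPC captures four raw images under complementary half-circular illumination
patterns.  Under the weak-object approximation each background-normalised
image is linear in the sample's absorption ``o_u`` and quantitative phase
``o_p`` through a pair of transfer functions in 2D Fourier space:

    forward_i(o_u, o_p) = F2D^-1[ H_u^i F2D(o_u) + H_p^i F2D(o_p) ]

The absorption transfer function ``H_u`` is real (even part of the
source-pupil cross-correlation); the phase transfer function ``H_p`` is
purely imaginary, vanishes at zero frequency (a constant phase is invisible)
and flips sign when the half-circle source is mirrored.

Fourier conventions: unnormalised forward DFT, 1/N inverse, frequency origin
at array index 0; all transfer functions are stored in that layout.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2

from .base import ForwardModel, MeasurementSet, RenderUnit, uniform_times

__all__ = [
    "dpc_transfer_functions",
    "pupil_function",
    "half_circle_source",
    "DPCSystem",
]


def pupil_function(
    shape: tuple[int, int], wavelength: float, na: float, pixel_size: float
) -> np.ndarray:
    """Binary circular pupil with cutoff NA/lambda on the fftfreq grid."""
    fy = fftfreq(shape[0], d=pixel_size)
    fx = fftfreq(shape[1], d=pixel_size)
    rho = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    return (rho <= na / wavelength).astype(np.float64)


def half_circle_source(
    shape: tuple[int, int],
    wavelength: float,
    na_illum: float,
    pixel_size: float,
    angle_deg: float,
) -> np.ndarray:
    """Half-circular source pattern on the frequency grid.

    ``angle_deg`` is the direction of the half-plane normal, measured from
    the +x (column) frequency axis towards +y (row); 90 keeps the "top"
    half (positive row frequencies).  Points exactly on the dividing line
    are excluded so mirrored patterns are exact sign partners.
    """
    fy = fftfreq(shape[0], d=pixel_size)[:, None]
    fx = fftfreq(shape[1], d=pixel_size)[None, :]
    rho = np.sqrt(fy**2 + fx**2)
    ang = np.deg2rad(angle_deg)
    proj = np.cos(ang) * fx + np.sin(ang) * fy
    return ((rho <= na_illum / wavelength) & (proj > 0)).astype(np.float64)


def _flip_conj(a: np.ndarray) -> np.ndarray:
    """conj(a(-u)) on a grid with the frequency origin at index 0."""
    return np.conj(np.roll(a[::-1, ::-1], 1, axis=(0, 1)))


def dpc_transfer_functions(
    source: np.ndarray, pupil: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weak-object absorption and phase transfer functions.

    Both arrays live on the same frequency grid as ``source`` and
    ``pupil`` (origin at index 0).  With the source-pupil cross-correlation
    ``C(u) = sum_{u'} S(u') P*(u') P(u' + u)`` and background
    ``B = sum S |P|^2``:

        H_u(u) = -(C(u) + conj(C(-u))) / B     (absorption darkens)
        H_p(u) =  i (C(u) - conj(C(-u))) / B

    Raises if the source deposits no energy inside the pupil (the
    background normalisation is undefined).
    """
    source = np.asarray(source, dtype=np.float64)
    pupil = np.asarray(pupil, dtype=np.complex128)
    background = float(np.sum(source * np.abs(pupil) ** 2))
    if background <= 0.0:
        raise ValueError("source has zero total intensity inside the pupil")
    # cross-correlation via FFT: sum_x conj(a)(x) b(x+u) = IDFT[conj(DFT a) DFT b]
    a = source * pupil  # conj(a) = S P*
    corr = ifft2(np.conj(fft2(a)) * fft2(pupil))
    h_u = -(corr + _flip_conj(corr)) / background
    h_p = 1j * (corr - _flip_conj(corr)) / background
    return h_u, h_p


class DPCSystem(ForwardModel):
    """Four-pattern DPC acquisition with precomputed transfer pairs.

    Parameters
    ----------
    h_u, h_p : (T, H, W) complex arrays
        Per-measurement absorption / phase transfer functions (loadable
        from file or built with :meth:`from_optics`).
    times : optional per-measurement times; defaults to uniform spacing.
    """

    modality = "dpc"
    scene_channels = 2  # (absorption, phase)

    def __init__(self, h_u: np.ndarray, h_p: np.ndarray, times=None):
        self.h_u = np.asarray(h_u, dtype=np.complex128)
        self.h_p = np.asarray(h_p, dtype=np.complex128)
        if self.h_u.shape != self.h_p.shape or self.h_u.ndim != 3:
            raise ValueError("h_u and h_p must both be (T, H, W)")
        self.scene_shape = self.h_u.shape[1:]
        self._times = (
            uniform_times(self.h_u.shape[0]) if times is None else np.asarray(times, float)
        )

    @classmethod
    def from_optics(
        cls,
        shape: tuple[int, int],
        wavelength: float = 0.5,
        na: float = 0.25,
        pixel_size: float = 0.454,
        angles=(90.0, 270.0, 0.0, 180.0),
        times=None,
    ) -> "DPCSystem":
        """Build the four half-circle patterns (top/bottom/left/right) with
        illumination NA matched to the objective NA."""
        pupil = pupil_function(shape, wavelength, na, pixel_size)
        h_u, h_p = [], []
        for ang in angles:
            src = half_circle_source(shape, wavelength, na, pixel_size, ang)
            hu, hp = dpc_transfer_functions(src, pupil)
            h_u.append(hu)
            h_p.append(hp)
        return cls(np.stack(h_u), np.stack(h_p), times=times)

    # ------------------------------------------------------------------ #
    @property
    def num_measurements(self) -> int:
        return self.h_u.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self._times

    def render(self, scene: np.ndarray, i: int) -> np.ndarray:
        """Background-normalised intensity image for measurement ``i``.

        ``scene`` is (2, H, W): absorption then phase.  Zero scene renders
        to the zero image (background-subtracted convention); the map is
        linear in the scene.
        """
        o_u, o_p = self._check_scene(scene)
        spec = self.h_u[i] * fft2(o_u) + self.h_p[i] * fft2(o_p)
        return np.real(ifft2(spec))

    def adjoint(self, g: np.ndarray, i: int) -> np.ndarray:
        """Adjoint of :meth:`render` (exact VJP of the linear map)."""
        gf = fft2(g)
        g_u = np.real(ifft2(np.conj(self.h_u[i]) * gf))
        g_p = np.real(ifft2(np.conj(self.h_p[i]) * gf))
        return np.stack([g_u, g_p])

    def _check_scene(self, scene: np.ndarray):
        scene = np.asarray(scene)
        if scene.shape != (2, *self.scene_shape):
            raise ValueError(
                f"scene must be (2, {self.scene_shape[0]}, {self.scene_shape[1]}), "
                f"got {scene.shape}"
            )
        return scene[0], scene[1]

    # ------------------------------------------------------------------ #
    def render_units(self, measurements: MeasurementSet) -> list[RenderUnit]:
        self.check_measurements(measurements)
        units = []
        for i in range(self.num_measurements):
            units.append(
                RenderUnit(
                    times=(float(self._times[i]),),
                    target=measurements.images[i],
                    apply=lambda scenes, i=i: self.render(scenes[0], i),
                    vjp=lambda g, i=i: [self.adjoint(g, i)],
                    label=f"dpc[{i}]",
                )
            )
        return units

    def simulate(self, scene_at: Callable[[float], np.ndarray]) -> np.ndarray:
        return np.stack(
            [self.render(scene_at(float(t)), i) for i, t in enumerate(self._times)]
        )
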