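"""Three-dimensional structured illumination microscopy (SIM) forward model.

3D SIM acquires 15 raw images per focal plane: three illumination pattern
orientations with five lateral phase shifts each.  Instead of the
conventional Fourier band separation (which assumes a static scene across
the five phases), the forward model is evaluated in real space per
measurement: the fluorescent density ``o`` is modulated by the illumination
pattern split into its three harmonic bands, each band is filtered by its
optical transfer function, and the bands are summed,

    forward_i(o) = sum_j  F3D^-1[ OTF_j  F3D( illum_{i,j} o ) ],  j in {0,1,2}

Band 0 is the constant (widefield) term, band 1 the fundamental lateral
frequency carrying the three-beam axial modulation, band 2 the doubled
lateral frequency.  The axial cos(2 pi nu_z z) modulation of band 1 is kept
in the real-space illumination pattern; the per-band OTFs then default to
one detection OTF shared by all bands (the two forms are algebraically
identical because the model is linear) and remain individually loadable.

Measurements sharing (orientation, phase) across depth planes are grouped
and rendered in one pass at a shared representative time, so an ``n_z``-plane
stack needs only 15 scene evaluations regardless of ``n_z``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.fft import fftfreq, fftn, ifft2, ifftn

from .base import ForwardModel, MeasurementSet, RenderUnit, uniform_times

__all__ = [
    "SIMSystem",
    "PlaneGroup",
    "build_index_table",
    "sim_group_planes",
    "detection_otf_3d",
]

N_ORIENTATIONS = 3
N_PHASES = 5


def build_index_table(n_z: int, order: str = "z_inner") -> np.ndarray:
    """Raw-measurement index table, rows = (z, orientation, phase).

    ``order='z_inner'`` sweeps depth fastest inside each (orientation,
    phase) pair — the layout under which plane grouping is temporally
    contiguous; ``'z_outer'`` acquires all 15 pattern images per plane
    before stepping z.
    """
    rows = []
    if order == "z_inner":
        for o in range(N_ORIENTATIONS):
            for p in range(N_PHASES):
                for z in range(n_z):
                    rows.append((z, o, p))
    elif order == "z_outer":
        for z in range(n_z):
            for o in range(N_ORIENTATIONS):
                for p in range(N_PHASES):
                    rows.append((z, o, p))
    else:
        raise ValueError(f"unknown acquisition order {order!r}")
    return np.asarray(rows, dtype=np.int64)


@dataclass(frozen=True)
class PlaneGroup:
    """All depth planes sharing one (orientation, phase) pattern."""

    orientation: int
    phase: int
    raw_indices: tuple  # ordered by z
    time: float  # representative (mean) acquisition time


def sim_group_planes(index_table: np.ndarray, n_z: int, times=None) -> list[PlaneGroup]:
    """Partition raw measurements into the 15 (orientation, phase) groups.

    Always yields exactly 3 x 5 = 15 groups of ``n_z`` members each; raises
    with the missing (z, orientation, phase) triples if the table is not a
    complete acquisition.  Each group's time is the mean of its members'
    acquisition times (the grouped render treats them as simultaneous).
    """
    index_table = np.asarray(index_table)
    t_raw = uniform_times(len(index_table)) if times is None else np.asarray(times, float)
    expected = {
        (z, o, p)
        for z in range(n_z)
        for o in range(N_ORIENTATIONS)
        for p in range(N_PHASES)
    }
    seen = {tuple(row) for row in index_table}
    missing = sorted(expected - seen)
    if missing or len(index_table) != n_z * N_ORIENTATIONS * N_PHASES:
        raise ValueError(
            f"incomplete SIM acquisition: {len(index_table)} raw images, "
            f"missing (z, orientation, phase) = {missing[:10]}"
        )
    groups = []
    for o in range(N_ORIENTATIONS):
        for p in range(N_PHASES):
            members = [
                (int(index_table[i, 0]), i)
                for i in range(len(index_table))
                if index_table[i, 1] == o and index_table[i, 2] == p
            ]
            members.sort()
            idx = tuple(i for _, i in members)
            groups.append(
                PlaneGroup(o, p, idx, float(np.mean([t_raw[i] for i in idx])))
            )
    return groups


def detection_otf_3d(
    shape: tuple[int, int, int],
    na: float,
    wavelength: float,
    pixel_size: float,
    z_step: float,
    refractive_index: float = 1.0,
) -> np.ndarray:
    """Numerical 3D incoherent (detection) OTF from the defocused pupil.

    The intensity PSF at defocus z is |F2D^-1[P(u) exp(i 2 pi z kz(u))]|^2
    with kz = sqrt((n/lambda)^2 - |u|^2) inside the pupil; the PSF stack is
    normalised to unit total energy (OTF DC gain = 1) and transformed with
    the frequency origin at index 0 on all axes.
    """
    n_z, n_y, n_x = shape
    fy = fftfreq(n_y, d=pixel_size)[:, None]
    fx = fftfreq(n_x, d=pixel_size)[None, :]
    rho2 = fy**2 + fx**2
    pupil = rho2 <= (na / wavelength) ** 2
    kz = np.sqrt(np.maximum((refractive_index / wavelength) ** 2 - rho2, 0.0))
    z = fftfreq(n_z, d=1.0 / (n_z * z_step))  # [0, dz, ..., -dz] layout
    psf = np.empty(shape)
    for iz, zz in enumerate(z):
        field = ifft2(pupil * np.exp(2j * np.pi * kz * zz))
        psf[iz] = np.abs(field) ** 2
    psf /= psf.sum()
    return fftn(psf)


class SIMSystem(ForwardModel):
    """Three-beam 3D SIM acquisition: n_z planes x 3 orientations x 5 phases.

    Parameters
    ----------
    shape : (n_z, n_y, n_x) scene raster.
    pattern_freq : lateral illumination frequency in cycles per physical
        unit (defaults to 0.8 of the incoherent cutoff 2 NA / lambda).
    axial_freq : axial modulation frequency of band 1 (cycles per unit).
    mod_depths : per-band modulation depths (m0, m1, m2); the summed
        pattern stays nonnegative when m0 >= m1 + m2.
    otfs : optional per-band OTF arrays (3, *shape) loaded from file;
        defaults to one shared detection OTF.
    order : acquisition ordering, ``'z_inner'`` or ``'z_outer'``.
    """

    modality = "sim"
    scene_channels = 1

    def __init__(
        self,
        shape: tuple[int, int, int],
        na: float = 1.46,
        wavelength: float = 0.488,
        pixel_size: float = 0.0406,
        z_step: float = 0.15,
        pattern_freq: float | None = None,
        axial_freq: float | None = None,
        mod_depths: tuple[float, float, float] = (1.0, 0.6, 0.3),
        orientations_deg: tuple[float, ...] = (0.0, 60.0, 120.0),
        phases=None,
        otfs: np.ndarray | None = None,
        order: str = "z_inner",
        times=None,
    ):
        self.scene_shape = tuple(shape)
        self.n_z = shape[0]
        self.na, self.wavelength = na, wavelength
        self.pixel_size, self.z_step = pixel_size, z_step
        self.pattern_freq = (
            0.8 * 2.0 * na / wavelength if pattern_freq is None else pattern_freq
        )
        self.axial_freq = (
            (na**2) / (2.0 * wavelength) if axial_freq is None else axial_freq
        )
        self.mod_depths = tuple(mod_depths)
        self.orientations_deg = tuple(orientations_deg)
        self.phases = (
            2.0 * np.pi * np.arange(N_PHASES) / N_PHASES if phases is None else np.asarray(phases)
        )
        if len(self.orientations_deg) != N_ORIENTATIONS or len(self.phases) != N_PHASES:
            raise ValueError("expected 3 orientations and 5 phases")
        if otfs is None:
            base = detection_otf_3d(self.scene_shape, na, wavelength, pixel_size, z_step)
            self.otfs = np.stack([base] * 3)
        else:
            self.otfs = np.asarray(otfs, dtype=np.complex128)
            if self.otfs.shape != (3, *self.scene_shape):
                raise ValueError(
                    f"need one OTF per band, shape (3, *{self.scene_shape}); "
                    f"got {self.otfs.shape}"
                )
        self.order = order
        self.index_table = build_index_table(self.n_z, order)
        self._times = (
            uniform_times(len(self.index_table)) if times is None else np.asarray(times, float)
        )
        self.groups = sim_group_planes(self.index_table, self.n_z, self._times)

    # ------------------------------------------------------------------ #
    @property
    def num_measurements(self) -> int:
        return self.n_z * N_ORIENTATIONS * N_PHASES

    @property
    def times(self) -> np.ndarray:
        return self._times

    # ------------------------------------------------------------------ #
    def illumination_bands(self, orientation: int, phase: int) -> list[np.ndarray]:
        """The three real-space harmonic bands of pattern (orientation, phase)."""
        n_z, n_y, n_x = self.scene_shape
        m0, m1, m2 = self.mod_depths
        yy = (np.arange(n_y) * self.pixel_size)[None, :, None]
        xx = (np.arange(n_x) * self.pixel_size)[None, None, :]
        zz = (np.arange(n_z) * self.z_step)[:, None, None]
        theta = np.deg2rad(self.orientations_deg[orientation])
        arg = (
            2.0 * np.pi * self.pattern_freq * (np.cos(theta) * xx + np.sin(theta) * yy)
            + self.phases[phase]
        )
        band0 = np.broadcast_to(np.float64(m0), self.scene_shape).copy()
        band1 = m1 * np.cos(arg) * np.cos(2.0 * np.pi * self.axial_freq * zz)
        band2 = m2 * np.cos(2.0 * arg)
        return [band0, band1, band2]

    def render_group(self, scene: np.ndarray, group: PlaneGroup) -> np.ndarray:
        """Rendered intensity volume for one (orientation, phase) group."""
        o = self._check_scene(scene)
        bands = self.illumination_bands(group.orientation, group.phase)
        out = np.zeros(self.scene_shape)
        for j in range(3):
            out += np.real(ifftn(self.otfs[j] * fftn(bands[j] * o)))
        return out

    def adjoint_group(self, g: np.ndarray, group: PlaneGroup) -> np.ndarray:
        bands = self.illumination_bands(group.orientation, group.phase)
        gf = fftn(g)
        out = np.zeros(self.scene_shape)
        for j in range(3):
            out += bands[j] * np.real(ifftn(np.conj(self.otfs[j]) * gf))
        return out[None]  # restore channel axis

    def _check_scene(self, scene: np.ndarray) -> np.ndarray:
        scene = np.asarray(scene)
        if scene.shape == (1, *self.scene_shape):
            scene = scene[0]
        if scene.shape != self.scene_shape:
            raise ValueError(f"scene must be {self.scene_shape}, got {scene.shape}")
        return scene

    # ------------------------------------------------------------------ #
    def render_units(self, measurements: MeasurementSet) -> list[RenderUnit]:
        self.check_measurements(measurements)
        units = []
        for group in self.groups:
            target = np.stack([measurements.images[i] for i in group.raw_indices])
            units.append(
                RenderUnit(
                    times=(group.time,),
                    target=target,
                    apply=lambda scenes, g=group: self.render_group(scenes[0], g),
                    vjp=lambda gr, g=group: [self.adjoint_group(gr, g)],
                    label=f"sim[o{group.orientation} p{group.phase}]",
                )
            )
        return units

    def simulate(self, scene_at: Callable[[float], np.ndarray]) -> np.ndarray:
        """Raw image stack (num_measurements, n_y, n_x), acquisition order."""
        raw = np.empty((self.num_measurements, *self.scene_shape[1:]))
        for group in self.groups:
            vol = self.render_group(scene_at(group.time), group)
            for z_pos, i in enumerate(group.raw_indices):
                raw[i] = vol[z_pos]
        return raw
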