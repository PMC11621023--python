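"""Common surface of the differentiable imaging forward models.

Every supported system is linear and deterministic in the scene, exposes the
measurement times it needs, and can be decomposed into *render units*: the
smallest pieces the training loop evaluates independently.  A unit names the
scene time points it needs, renders a prediction from those scenes, and
back-propagates a gradient onto them.  For a four-image phase-contrast
acquisition the units are the four measurements; for structured illumination
they are the plane-grouped (orientation, phase) passes; for the
rolling-shutter lensless camera they are chunks of sensor rows.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["MeasurementSet", "RenderUnit", "ForwardModel"]


@dataclass
class MeasurementSet:
    """Raw images with their temporal coordinates.

    ``images`` carries a leading measurement axis; its trailing shape is
    modality specific (2D images, or channel-leading frames for RGB).
    ``times`` holds one normalised time in [0, 1] per measurement.
    """

    images: np.ndarray
    times: np.ndarray
    modality: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.images.shape[0] != self.times.shape[0]:
            raise ValueError(
                f"{self.images.shape[0]} measurements but {self.times.shape[0]} times"
            )

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class RenderUnit:
    """One independently renderable piece of the acquisition.

    Attributes
    ----------
    times : scene time points this unit needs, in order.
    target : measured data this unit is compared against.
    apply : maps the list of scenes (one per time) to the prediction.
    vjp : maps an upstream gradient to one gradient array per scene.
    label : human-readable identifier used in diagnostics.
    """

    times: tuple
    target: np.ndarray
    apply: Callable[[Sequence[np.ndarray]], np.ndarray]
    vjp: Callable[[np.ndarray], list]
    label: str = ""


class ForwardModel(ABC):
    """Deterministic, scene-linear renderer of a multi-shot acquisition."""

    modality: str
    scene_shape: tuple
    scene_channels: int

    @property
    @abstractmethod
    def num_measurements(self) -> int:
        """Number of raw measurements the system acquires."""

    @property
    @abstractmethod
    def times(self) -> np.ndarray:
        """Normalised acquisition time of each raw measurement."""

    @abstractmethod
    def render_units(self, measurements: MeasurementSet) -> list[RenderUnit]:
        """Decompose the acquisition into training units."""

    @abstractmethod
    def simulate(self, scene_at: Callable[[float], np.ndarray]) -> np.ndarray:
        """Render the full raw measurement stack from a scene provider.

        ``scene_at(t)`` must return the (channels, *scene_shape) scene at
        normalised time ``t``.
        """

    def check_measurements(self, measurements: MeasurementSet) -> None:
        if len(measurements) != self.num_measurements:
            raise ValueError(
                f"{self.modality}: expected {self.num_measurements} measurements, "
                f"got {len(measurements)}"
            )


def uniform_times(n: int) -> np.ndarray:
    """Default acquisition times: uniform in [0, 1] by capture order."""
    if n == 1:
        return np.zeros(1)
    return np.arange(n) / (n - 1)
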