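"""Core data containers for circular-scan photoacoustic tomography.

The acquisition model is a single detector rotated on a circle of radius
``radius`` around the sample: position ``i`` sits at angle
``start_angle + i * angle_step`` (degrees, counterclockwise, angle 0 on the
+x axis), and sample ``j`` of each A-line corresponds to time
``time_offset + j / sampling_frequency`` after the laser pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math
import warnings

import numpy as np


class ValidationError(ValueError):
    """Raised when a domain object or operation input violates its contract."""


class FormatError(ValueError):
    """Raised when a file's header and payload disagree or values are malformed."""


# Slack on the full-circle bound: n_positions * angle_step may exceed 360 deg
# only by floating-point round-off.
_FULL_CIRCLE_TOL = 1e-6


@dataclass(frozen=True)
class ScanGeometry:
    """Circular acquisition geometry and timing.

    Parameters
    ----------
    radius
        Scan-circle radius in metres.
    n_positions
        Number of detector positions on the circle.
    angle_step
        Angular increment between consecutive positions, degrees.
    speed_of_sound
        Acoustic speed of the (homogeneous) medium, m/s.
    sampling_frequency
        A-line sampling rate, Hz.
    n_samples
        Samples per A-line.
    start_angle
        Angle of position 0, degrees. Default 0 (on the +x axis).
    time_offset
        Time of the first sample relative to the laser pulse, seconds.
    """

    radius: float
    n_positions: int
    angle_step: float
    speed_of_sound: float
    sampling_frequency: float
    n_samples: int
    start_angle: float = 0.0
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValidationError(f"radius must be > 0, got {self.radius}")
        if self.n_positions < 1:
            raise ValidationError(f"n_positions must be >= 1, got {self.n_positions}")
        if self.speed_of_sound <= 0:
            raise ValidationError("speed_of_sound must be > 0")
        if self.sampling_frequency <= 0:
            raise ValidationError("sampling_frequency must be > 0")
        if self.n_samples < 2:
            raise ValidationError(f"n_samples must be >= 2, got {self.n_samples}")
        span = self.n_positions * self.angle_step
        if span > 360.0 + _FULL_CIRCLE_TOL:
            raise ValidationError(
                f"n_positions * angle_step = {span:.6f} deg exceeds a full circle"
            )

    @property
    def angles_deg(self) -> np.ndarray:
        """Detector angles in degrees, position order."""
        return self.start_angle + self.angle_step * np.arange(self.n_positions)

    @property
    def sample_times(self) -> np.ndarray:
        """Time of each A-line sample relative to the laser pulse, seconds."""
        return self.time_offset + np.arange(self.n_samples) / self.sampling_frequency

    def with_positions(self, n_positions: int, angle_step: float) -> "ScanGeometry":
        return replace(self, n_positions=n_positions, angle_step=angle_step)


@dataclass
class Sinogram:
    """Stack of A-lines: rows are acquisition positions, columns time samples."""

    data: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(f"sinogram data must be 2-D, got {self.data.ndim}-D")
        if self.data.shape[0] != self.geometry.n_positions:
            raise ValidationError(
                f"sinogram has {self.data.shape[0]} rows but geometry declares "
                f"{self.geometry.n_positions} positions"
            )
        if self.data.shape[1] != self.geometry.n_samples:
            raise ValidationError(
                f"sinogram has {self.data.shape[1]} columns but geometry declares "
                f"{self.geometry.n_samples} samples"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("sinogram contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ImageGrid:
    """Square-pixel reconstruction grid centred on the scan centre.

    Pixel (row i, col j) maps to physical coordinates
    ``x = (j - (nx-1)/2) * pixel_size``, ``y = ((ny-1)/2 - i) * pixel_size``:
    row 0 is the top of the image (+y), consistent with screen display.
    """

    nx: int = 250
    ny: int = 250
    pixel_size: float = 1e-4

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValidationError("grid must have at least one pixel per axis")
        if not (self.pixel_size > 0):
            raise ValidationError("pixel_size must be > 0")

    @property
    def x_coords(self) -> np.ndarray:
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pixel_size

    @property
    def y_coords(self) -> np.ndarray:
        return ((self.ny - 1) / 2.0 - np.arange(self.ny)) * self.pixel_size

    @property
    def half_extent(self) -> float:
        """Physical half-width of the larger grid axis, metres."""
        return max(self.nx, self.ny) * self.pixel_size / 2.0

    def check_inside(self, radius: float) -> None:
        if self.half_extent >= radius:
            warnings.warn(
                f"grid half-extent {self.half_extent * 1e3:.1f} mm reaches beyond "
                f"the scan radius {radius * 1e3:.1f} mm; pixels outside the circle "
                "are not physically reconstructable",
                stacklevel=3,
            )


@dataclass
class ReconImage:
    """Reconstructed 2-D initial-pressure map on an :class:`ImageGrid`."""

    values: np.ndarray
    grid: ImageGrid
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValidationError(
                f"image shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("image contains non-finite values")
        if self.normalized and not math.isclose(
            float(np.max(np.abs(self.values))), 1.0, rel_tol=1e-12
        ):
            raise ValidationError("normalized image must have max |value| == 1")
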