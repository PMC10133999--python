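"""Detector placement and time-of-flight arithmetic."""

from __future__ import annotations

import numpy as np

from .core import ScanGeometry


def detector_positions(geometry: ScanGeometry) -> np.ndarray:
    """Cartesian (x, y) detector positions in metres, shape (n_positions, 2).

    Position ``i`` sits at angle ``start_angle + i * angle_step`` degrees,
    counterclockwise from the +x axis, at distance ``radius`` from the scan
    centre.
    """
    theta = np.deg2rad(geometry.angles_deg)
    return geometry.radius * np.column_stack([np.cos(theta), np.sin(theta)])


def delay_to_sample(distance, geometry: ScanGeometry):
    """Fractional A-line sample index for a given propagation distance.

    ``index = (distance / speed_of_sound - time_offset) * sampling_frequency``.
    The result may be fractional or outside ``[0, n_samples - 1]``; the
    caller decides how to interpolate or discard.
    """
    return (
        np.asarray(distance) / geometry.speed_of_sound - geometry.time_offset
    ) * geometry.sampling_frequency
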