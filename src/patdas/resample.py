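"""Acquisition-side A-line operations: pair averaging and angular downsampling."""

from __future__ import annotations

from .core import Sinogram, ValidationError


def average_pairs(sinogram: Sinogram) -> Sinogram:
    """Average every two consecutive A-lines, halving the position count.

    Output row ``i`` is the mean of input rows ``2i`` and ``2i + 1``; the
    angle step doubles and the output row keeps the angular position of its
    first constituent (the sub-resolution midpoint shift is ignored).
    """
    geometry = sinogram.geometry
    if geometry.n_positions % 2 != 0:
        raise ValidationError(
            f"pair averaging needs an even number of positions, got {geometry.n_positions}"
        )
    data = sinogram.data
    averaged = 0.5 * (data[0::2] + data[1::2])
    new_geometry = geometry.with_positions(
        geometry.n_positions // 2, geometry.angle_step * 2.0
    )
    return Sinogram(averaged, new_geometry)


def downsample_positions(sinogram: Sinogram, factor: int) -> Sinogram:
    """Keep every ``factor``-th A-line starting at index 0.

    Exactly ``n_positions // factor`` rows survive (floor convention, e.g.
    800 positions at factor 3 keep 266); surviving rows are copied verbatim
    and the angle step is multiplied by ``factor``.
    """
    geometry = sinogram.geometry
    factor = int(factor)
    if factor < 1 or factor > geometry.n_positions:
        raise ValidationError(
            f"factor must be in [1, n_positions={geometry.n_positions}], got {factor}"
        )
    n_keep = geometry.n_positions // factor
    kept = sinogram.data[: n_keep * factor : factor].copy()
    new_geometry = geometry.with_positions(n_keep, geometry.angle_step * factor)
    return Sinogram(kept, new_geometry)
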