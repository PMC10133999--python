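"""Delay-and-sum backprojection for circular-scan photoacoustic tomography.

Each image pixel sums, over all detector positions, the A-line sample at
that pixel's time of flight (simple DAS, backprojecting the raw pressure).
The universal-backprojection filtered term b = 2p - 2t dp/dt can be applied
to the sinogram beforehand via :func:`fbp_weighting_term`.
"""

from __future__ import annotations

import numpy as np

from .core import ImageGrid, ReconImage, Sinogram, ValidationError
from .geometry import delay_to_sample, detector_positions

_DETECTOR_CHUNK = 64  # detectors per vectorised block; bounds peak memory


def das_reconstruct(
    sinogram: Sinogram,
    grid: ImageGrid | None = None,
    interpolation: str = "linear",
    weighting: str = "uniform",
) -> ReconImage:
    """Reconstruct an initial-pressure image by delay-and-sum backprojection.

    Parameters
    ----------
    sinogram
        A-line matrix bound to its scan geometry.
    grid
        Reconstruction grid; defaults to 250 x 250 pixels at 0.1 mm/pixel.
    interpolation
        ``"linear"`` interpolates the fractional delay index between adjacent
        samples; ``"nearest"`` rounds it. Delays outside the recorded window
        contribute zero.
    weighting
        ``"uniform"`` gives every detector weight 1 (simple DAS);
        ``"solid_angle"`` weights each contribution by the arc the detector
        element subtends at the pixel, divided by the full 2*pi view.

    Returns
    -------
    ReconImage
        Unnormalised reconstruction.
    """
    if grid is None:
        grid = ImageGrid()
    if interpolation not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    if weighting not in ("uniform", "solid_angle"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    geometry = sinogram.geometry
    grid.check_inside(geometry.radius)

    det = detector_positions(geometry)
    data = sinogram.data
    n_samples = geometry.n_samples
    X, Y = np.meshgrid(grid.x_coords, grid.y_coords)  # (ny, nx)
    image = np.zeros((grid.ny, grid.nx))
    step_rad = np.deg2rad(geometry.angle_step) if geometry.n_positions > 1 else 2 * np.pi

    for lo in range(0, geometry.n_positions, _DETECTOR_CHUNK):
        hi = min(lo + _DETECTOR_CHUNK, geometry.n_positions)
        dx = det[lo:hi, 0][:, None, None] - X[None]  # (chunk, ny, nx)
        dy = det[lo:hi, 1][:, None, None] - Y[None]
        dist = np.sqrt(dx * dx + dy * dy)
        idx = delay_to_sample(dist, geometry)

        if interpolation == "nearest":
            nearest = np.rint(idx).astype(np.int64)
            valid = (idx >= 0) & (idx <= n_samples - 1)
            nearest = np.clip(nearest, 0, n_samples - 1)
            rows = np.arange(lo, hi)[:, None, None]
            contrib = np.where(valid, data[rows, nearest], 0.0)
        else:
            i0 = np.floor(idx).astype(np.int64)
            frac = idx - i0
            valid0 = (i0 >= 0) & (i0 <= n_samples - 1)
            valid1 = (i0 + 1 >= 0) & (i0 + 1 <= n_samples - 1)
            in_range = (idx >= 0) & (idx <= n_samples - 1)
            i0c = np.clip(i0, 0, n_samples - 1)
            i1c = np.clip(i0 + 1, 0, n_samples - 1)
            rows = np.arange(lo, hi)[:, None, None]
            v0 = np.where(valid0, data[rows, i0c], 0.0)
            v1 = np.where(valid1, data[rows, i1c], 0.0)
            contrib = np.where(in_range, (1.0 - frac) * v0 + frac * v1, 0.0)

        if weighting == "solid_angle":
            # Arc element R*dtheta seen at the pixel: project onto the
            # element's inward normal (towards the scan centre) and divide
            # by the full 2*pi angular view and the pixel-element distance.
            nx_ = det[lo:hi, 0][:, None, None]
            ny_ = det[lo:hi, 1][:, None, None]
            d_safe = np.maximum(dist, 1e-12)
            cos_alpha = ((nx_ - X[None]) * nx_ + (ny_ - Y[None]) * ny_) / (
                d_safe * geometry.radius
            )
            weight = geometry.radius * step_rad * np.abs(cos_alpha) / (2 * np.pi * d_safe)
            contrib = contrib * weight

        image += contrib.sum(axis=0)
    return ReconImage(image, grid, normalized=False)


def fbp_weighting_term(sinogram: Sinogram, derivative_scale: float = 1.0) -> Sinogram:
    """Universal-backprojection filtered term b = 2p - 2t dp/dt per A-line.

    The time derivative uses second-order central differences (first-order
    one-sided at the trace ends). ``derivative_scale`` multiplies the
    derivative term; setting it to the sound speed reproduces the literal
    ``2ct dp/dt`` variant sometimes printed, whose extra ``c`` factor is
    dimensionally spurious in the standard formulation.
    """
    geometry = sinogram.geometry
    if geometry.n_samples < 3:
        raise ValidationError("fbp term needs at least 3 time samples")
    t = geometry.sample_times
    dpdt = np.gradient(sinogram.data, t, axis=1)
    b = 2.0 * sinogram.data - 2.0 * derivative_scale * t[None, :] * dpdt
    return Sinogram(b, geometry)


def normalize_image(image: ReconImage) -> ReconImage:
    """Scale so the maximum absolute value is 1; signs are preserved."""
    peak = float(np.max(np.abs(image.values)))
    if peak == 0.0:
        raise ValidationError("cannot normalize an all-zero image")
    return ReconImage(image.values / peak, image.grid, normalized=True)
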