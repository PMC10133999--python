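"""Image-quality metrics: ROI-based SNR, MSE/PSNR, and global SSIM.

SNR follows the reconstruction-domain convention
``20*log10(mu_i / sigma_0)`` where ``mu_i`` is the mean of the ten largest
absolute pixel values inside a signal region of interest and ``sigma_0`` is
the standard deviation of absolute pixel values in a background region
outside the photoacoustic targets. PSNR and SSIM are full-reference metrics
against a distortion-free reconstruction; SSIM here is the single-window
global form computed from whole-image moments with the population
(divide-by-N) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ReconImage, ValidationError

#: Side length (pixels) of the default corner background patches.
DEFAULT_CORNER = 25


def _values(image) -> np.ndarray:
    if isinstance(image, ReconImage):
        return image.values
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("image must be 2-D")
    return arr


@dataclass(frozen=True)
class RoiSpec:
    """Signal and background regions as half-open (row0, row1, col0, col1) bounds."""

    signal_roi: tuple[int, int, int, int]
    background_roi: tuple[int, int, int, int]

    def validate(self, shape: tuple[int, int]) -> None:
        for name, (r0, r1, c0, c1) in (
            ("signal_roi", self.signal_roi),
            ("background_roi", self.background_roi),
        ):
            if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
                raise ValidationError(f"{name} {self.__dict__[name]} outside image {shape}")
        sr0, sr1, sc0, sc1 = self.signal_roi
        if (sr1 - sr0) * (sc1 - sc0) < 10:
            raise ValidationError("signal_roi must contain at least 10 pixels")
        br0, br1, bc0, bc1 = self.background_roi
        if sr0 < br1 and br0 < sr1 and sc0 < bc1 and bc0 < sc1:
            raise ValidationError("signal and background ROIs must be disjoint")


def _default_masks(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Whole-image signal mask and four merged corner patches as background."""
    ny, nx = shape
    c = min(DEFAULT_CORNER, ny // 2, nx // 2)
    if c < 2:
        raise ValidationError(f"image {shape} too small for corner background patches")
    background = np.zeros(shape, dtype=bool)
    background[:c, :c] = background[:c, nx - c :] = True
    background[ny - c :, :c] = background[ny - c :, nx - c :] = True
    return np.ones(shape, dtype=bool), background


def snr_db(image, roi: RoiSpec | None = None) -> float:
    """ROI signal-to-noise ratio in dB.

    ``mu_i`` is the mean of the 10 largest absolute values in the signal
    ROI, ``sigma_0`` the standard deviation of absolute values in the
    background ROI. Without an explicit ``roi`` the signal ROI is the whole
    image and the background the four corner patches (25 x 25 px each,
    shrunk on small images).
    """
    values = np.abs(_values(image))
    if roi is None:
        signal_mask, background_mask = _default_masks(values.shape)
        signal = values[signal_mask]
        background = values[background_mask]
    else:
        roi.validate(values.shape)
        r0, r1, c0, c1 = roi.signal_roi
        signal = values[r0:r1, c0:c1].ravel()
        r0, r1, c0, c1 = roi.background_roi
        background = values[r0:r1, c0:c1].ravel()
    if signal.size < 10:
        raise ValidationError("signal ROI must contain at least 10 pixels")
    if background.size < 2:
        raise ValidationError("background ROI must contain at least 2 pixels")
    mu_i = float(np.mean(np.sort(signal)[-10:]))
    sigma_0 = float(np.std(background))
    if sigma_0 == 0.0:
        raise ValidationError("background standard deviation is zero; SNR undefined")
    return 20.0 * math.log10(mu_i / sigma_0)


def mse(reference, test) -> float:
    """Mean squared error between two equally sized images."""
    ref, tst = _values(reference), _values(test)
    if ref.shape != tst.shape:
        raise ValidationError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    return float(np.mean((ref - tst) ** 2))


def psnr_db(reference, test) -> float:
    """Peak signal-to-noise ratio ``10*log10(peakval^2 / MSE)`` in dB.

    ``peakval`` is the maximum value of the reference image. Identical
    images give ``math.inf`` (zero error), not an exception.
    """
    ref = _values(reference)
    err = mse(reference, test)
    peak = float(np.max(ref))
    if peak <= 0:
        raise ValidationError("reference image must have a positive peak value")
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / err)


def ssim(reference, test, c1: float | None = None, c2: float | None = None) -> float:
    """Global structural similarity index from whole-image moments.

    One window covers the whole image; means, variances and the
    cross-covariance use the population convention. Defaults follow the
    usual constants ``C1 = (0.01 L)^2`` and ``C2 = (0.03 L)^2`` with ``L``
    the reference dynamic range.
    """
    x, y = _values(reference), _values(test)
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    if c1 is None or c2 is None:
        dynamic_range = float(x.max() - x.min())
        if c1 is None:
            c1 = (0.01 * dynamic_range) ** 2
        if c2 is None:
            c2 = (0.03 * dynamic_range) ** 2
    if c1 < 0 or c2 < 0:
        raise ValidationError("SSIM constants must be non-negative")
    mu_x, mu_y = float(x.mean()), float(y.mean())
    var_x, var_y = float(x.var()), float(y.var())
    cov_xy = float(np.mean((x - mu_x) * (y - mu_y)))

    def factor(num: float, den: float) -> float:
        # A factor whose numerator and denominator both vanish is neutral
        # (its limit as the moments go to zero), e.g. the luminance term for
        # two zero-mean images with C1 = 0.
        if den == 0.0:
            if num == 0.0:
                return 1.0
            raise ValidationError("SSIM undefined: zero denominator with C1 = C2 = 0")
        return num / den

    luminance = factor(2 * mu_x * mu_y + c1, mu_x**2 + mu_y**2 + c1)
    structure = factor(2 * cov_xy + c2, var_x + var_y + c2)
    return luminance * structure


@dataclass(frozen=True)
class QualityReport:
    """SNR of a reconstruction plus full-reference metrics when available."""

    snr_db: float
    psnr_db: float | None = None
    ssim: float | None = None
    mse: float | None = None

    def to_dict(self) -> dict:
        return {
            "snr_db": self.snr_db,
            "psnr_db": self.psnr_db,
            "ssim": self.ssim,
            "mse": self.mse,
        }


def evaluate(image, reference=None, roi: RoiSpec | None = None) -> QualityReport:
    """Assemble a :class:`QualityReport` for one reconstruction.

    Always computes the ROI SNR; adds MSE/PSNR/SSIM when a reference image
    is supplied.
    """
    snr = snr_db(image, roi)
    if reference is None:
        return QualityReport(snr_db=snr)
    return QualityReport(
        snr_db=snr,
        psnr_db=psnr_db(reference, image),
        ssim=ssim(reference, image),
        mse=mse(reference, image),
    )
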