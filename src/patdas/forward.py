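"""Analytic forward model for circular-scan photoacoustic acquisition.

A uniform disc (2-D section of a sphere) absorber of radius ``a`` and
initial-pressure amplitude ``A`` observed by an ideal point detector at
distance ``d`` in a homogeneous medium with sound speed ``vs`` radiates the
classic bipolar N-shaped transient

    p(d, t) = A * (d - vs*t) / (2*d)   for |d - vs*t| <= a,  else 0.

Sinograms are superpositions of these transients over all phantom sources,
so the model is exactly linear in the source amplitudes. Band-limited
detection is modelled by a zero-phase Gaussian bandpass and noise by seeded
additive white Gaussian noise referenced to the peak signal amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ScanGeometry, Sinogram, ValidationError
from .geometry import detector_positions
from .phantom import Phantom


@dataclass(frozen=True)
class TransducerModel:
    """Band-limited detector: Gaussian amplitude response.

    ``fractional_bandwidth`` is the full width at half maximum of the
    response divided by the centre frequency (e.g. 0.7 for a 70% nominal
    bandwidth transducer).
    """

    center_frequency: float = 2.25e6
    fractional_bandwidth: float = 0.7

    def __post_init__(self) -> None:
        if not (self.center_frequency > 0):
            raise ValidationError("center_frequency must be > 0")
        if not (0 < self.fractional_bandwidth < 2):
            raise ValidationError("fractional_bandwidth must be in (0, 2)")


def forward_pressure(phantom: Phantom, geometry: ScanGeometry) -> Sinogram:
    """Simulate the sinogram of ``phantom`` under ``geometry``.

    Every source must lie strictly inside the scan circle. Returns the
    superposed N-wave transients sampled on the geometry's time grid.
    """
    det = np.asarray(detector_positions(geometry))  # (n_pos, 2)
    times = geometry.sample_times
    vs = geometry.speed_of_sound
    out = np.zeros((geometry.n_positions, geometry.n_samples))
    for cx, cy, radius, amplitude in phantom.sources:
        if math.hypot(cx, cy) + radius >= geometry.radius:
            raise ValidationError(
                f"source at ({cx * 1e3:.2f}, {cy * 1e3:.2f}) mm with radius "
                f"{radius * 1e3:.2f} mm reaches the scan circle "
                f"(radius {geometry.radius * 1e3:.1f} mm)"
            )
        d = np.hypot(det[:, 0] - cx, det[:, 1] - cy)  # (n_pos,)
        u = d[:, None] - vs * times[None, :]
        wave = np.where(np.abs(u) <= radius, amplitude * u / (2.0 * d[:, None]), 0.0)
        out += wave
    return Sinogram(out, geometry)


def _bandpass_gain(freqs: np.ndarray, transducer: TransducerModel) -> np.ndarray:
    """Amplitude response of the detector at non-negative frequencies.

    Gabor-style pair of Gaussians (one centred at +fc, its mirror at -fc)
    so the response is exactly zero at DC, as a physical bandpass must be;
    the FWHM of the main lobe equals fractional_bandwidth * fc.
    """
    fc = transducer.center_frequency
    sigma = transducer.fractional_bandwidth * fc / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-((freqs - fc) ** 2) / (2 * sigma**2)) - np.exp(
        -((freqs + fc) ** 2) / (2 * sigma**2)
    )


# Relative floor on the amplitude response used when taking its logarithm for
# the minimum-phase construction; well below every gain the tests assert on.
_GAIN_FLOOR = 1e-7


def _transducer_response(n: int, fs: float, transducer: TransducerModel) -> np.ndarray:
    """Complex detector response at the ``n``-point real-FFT bins.

    The magnitude is the Gaussian band gain of :func:`_bandpass_gain`; the
    phase is the minimum phase consistent with that magnitude (real
    ultrasound detectors are causal, and a causal response is what keeps the
    recorded wavelet asymmetric in time the way measured transducer impulse
    responses are). Computed by the standard real-cepstrum folding method.
    """
    f_full = np.fft.fftfreq(n, d=1.0 / fs)
    mag = np.maximum(_bandpass_gain(np.abs(f_full), transducer), _GAIN_FLOOR)
    cepstrum = np.fft.ifft(np.log(mag)).real
    fold = np.zeros(n)
    fold[0] = 1.0
    if n % 2 == 0:
        fold[n // 2] = 1.0
        fold[1 : n // 2] = 2.0
    else:
        fold[1 : (n + 1) // 2] = 2.0
    response = np.exp(np.fft.fft(fold * cepstrum))
    return response[: n // 2 + 1]


def apply_bandpass(sinogram: Sinogram, transducer: TransducerModel) -> Sinogram:
    """Apply the detector's band-limited response to every A-line.

    Filtering happens in the frequency domain (real FFT per row) with the
    Gaussian amplitude response and minimum (causal) phase; the sampling
    rate must satisfy Nyquist for the centre frequency.
    """
    fs = sinogram.geometry.sampling_frequency
    if fs <= 2.0 * transducer.center_frequency:
        raise ValidationError(
            f"sampling frequency {fs:.3g} Hz violates Nyquist for centre "
            f"frequency {transducer.center_frequency:.3g} Hz"
        )
    n = sinogram.geometry.n_samples
    response = _transducer_response(n, fs, transducer)
    filtered = np.fft.irfft(np.fft.rfft(sinogram.data, axis=1) * response, n=n, axis=1)
    return Sinogram(filtered, sinogram.geometry)


def _filtered_wavelet(
    radius: float, geometry: ScanGeometry, transducer: TransducerModel, oversample: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited N-wave shape w(tau) for a unit-amplitude source of radius
    ``radius``, tabulated on a fine grid of tau = t - d/vs.

    The raw N-wave as a function of tau is ``-vs * tau`` on |tau| <= a/vs for
    every detector (the 1/(2d) range factor separates out), so the detector's
    impulse response need only be convolved with it once. The convolution is
    carried out on a grid ``oversample`` times finer than the acquisition
    sampling, which makes later linear interpolation onto the sample times
    essentially exact.
    """
    vs = geometry.speed_of_sound
    fs_fine = geometry.sampling_frequency * oversample
    sigma_f = transducer.fractional_bandwidth * transducer.center_frequency / (
        2.0 * math.sqrt(2.0 * math.log(2.0))
    )
    # Support: N-wave half-width on the left, plus the causal filter's ringing
    # tail on the right (the impulse-response envelope time scale is
    # 1/(2 pi sigma_f)).
    tail = 14.0 / (2.0 * math.pi * sigma_f)
    n_left = int(math.ceil((radius / vs + tail / 4.0) * fs_fine))
    n_right = int(math.ceil((radius / vs + tail) * fs_fine))
    tau = np.arange(-n_left, n_right + 1) / fs_fine
    ramp = np.where(np.abs(tau) <= radius / vs, -vs * tau, 0.0)
    n_fft = 4 * tau.size  # zero padding keeps the circular FFT convolution linear
    response = _transducer_response(n_fft, fs_fine, transducer)
    wavelet = np.fft.irfft(np.fft.rfft(ramp, n=n_fft) * response, n=n_fft)[: tau.size]
    return tau, wavelet


def forward_pressure_bandlimited(
    phantom: Phantom, geometry: ScanGeometry, transducer: TransducerModel
) -> Sinogram:
    """Simulate band-limited detection sampled at the acquisition rate.

    Physically the transducer filters the continuous pressure before the ADC
    samples it, so the band-limited waveform is evaluated analytically (fine
    tabulated convolution of the N-wave with the detector response) at the
    exact sample times. This avoids the aliasing that sampling the
    discontinuous raw N-wave at the acquisition rate and filtering digitally
    would introduce.
    """
    fs = geometry.sampling_frequency
    if fs <= 2.0 * transducer.center_frequency:
        raise ValidationError(
            f"sampling frequency {fs:.3g} Hz violates Nyquist for centre "
            f"frequency {transducer.center_frequency:.3g} Hz"
        )
    det = np.asarray(detector_positions(geometry))
    vs = geometry.speed_of_sound
    t0 = geometry.time_offset
    n_samples = geometry.n_samples
    out = np.zeros((geometry.n_positions, n_samples))

    # Tabulate one wavelet per distinct source radius.
    wavelets: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for cx, cy, radius, amplitude in phantom.sources:
        if math.hypot(cx, cy) + radius >= geometry.radius:
            raise ValidationError(
                f"source at ({cx * 1e3:.2f}, {cy * 1e3:.2f}) mm with radius "
                f"{radius * 1e3:.2f} mm reaches the scan circle "
                f"(radius {geometry.radius * 1e3:.1f} mm)"
            )
        if radius not in wavelets:
            wavelets[radius] = _filtered_wavelet(radius, geometry, transducer)
        tau, wavelet = wavelets[radius]

        d = np.hypot(det[:, 0] - cx, det[:, 1] - cy)  # (n_pos,)
        # Only samples within the wavelet support contribute; evaluate a
        # fixed-width window of columns per detector.
        n_window = int(math.ceil((tau[-1] - tau[0]) * fs)) + 2
        j_start = np.floor((d / vs + tau[0] - t0) * fs).astype(np.int64)
        cols = j_start[:, None] + np.arange(n_window)[None, :]
        in_range = (cols >= 0) & (cols <= n_samples - 1)
        t = t0 + cols / fs
        values = amplitude / (2.0 * d[:, None]) * np.interp(
            t - d[:, None] / vs, tau, wavelet, left=0.0, right=0.0
        )
        values[~in_range] = 0.0
        rows = np.broadcast_to(np.arange(geometry.n_positions)[:, None], cols.shape)
        np.add.at(out, (rows, np.clip(cols, 0, n_samples - 1)), values)
    return Sinogram(out, geometry)


def add_noise(sinogram: Sinogram, target_snr_db: float, seed: int) -> Sinogram:
    """Add seeded white Gaussian noise at a peak-referenced SNR.

    The noise standard deviation is set so that
    ``20*log10(max|signal| / sigma) == target_snr_db``. A non-finite
    (``inf``) target disables noise and returns a copy.
    """
    if math.isinf(target_snr_db):
        return Sinogram(sinogram.data.copy(), sinogram.geometry)
    peak = float(np.max(np.abs(sinogram.data)))
    if peak == 0.0:
        raise ValidationError("cannot set a finite SNR on an all-zero sinogram")
    sigma = peak / 10.0 ** (target_snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = sinogram.data + rng.normal(0.0, sigma, size=sinogram.data.shape)
    return Sinogram(noisy, sinogram.geometry)
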