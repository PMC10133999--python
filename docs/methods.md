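# Methods

## Acquisition model

A circular scan is described by `ScanGeometry`: a single ideal point detector
visits `n_positions` stops on a circle of `radius` (position *i* at
`start_angle + i·angle_step` degrees, counterclockwise, 0° on the +x axis) and
records `n_samples` pressure samples at `sampling_frequency`; sample *j*
corresponds to `t = time_offset + j / sampling_frequency` after the laser
pulse. The medium is homogeneous with sound speed `speed_of_sound`. Defaults
follow the standard small-animal configuration: 41 mm radius, 1500 m/s,
25 MHz sampling. Three geometry presets are bundled: `sim-2.25MHz`
(800 × 1500), `phantom-nd:yag` (2400 × 1024, the shape of an Nd:YAG phantom
scan after pair averaging) and `invivo-pld` (600 × 1024).

## Phantoms and forward model

Phantoms are sets of uniform circular absorbers `(cx, cy, radius, amplitude)`.
Extended shapes are drawn as chains of overlapping discs (step ≤ disc radius),
which keeps the forward model closed-form while reproducing the target
topology:

* **point** — five point targets, one at the scan centre, four on the axes at
  5 mm spacing; disc radius 0.5 mm (a few reconstruction pixels, as a point
  target drawn on a 0.1 mm simulation grid would be).
* **triangle** — an isosceles triangle outline (base = height = 10 mm,
  centroid at the origin) of 0.3 mm discs, emulating a thin-line (horsehair)
  target.
* **vessel** — fixed branching polylines tracing a midline sagittal sinus, two
  transverse sinuses and four cortical branches of a rat brain, drawn with
  0.3 mm discs; the integer seed applies a ≤ 0.15 mm deterministic jitter to
  the control points so seeds index distinct but topologically identical
  vasculature.

Shaped phantoms must fit the 2.5 × 2.5 cm reconstruction field of view, and
every source must lie strictly inside the scan circle.

The outgoing wave of a uniform spherical absorber in a homogeneous medium is
the bipolar N-wave `p(d, t) = A (d − v_s t) / (2d)` on `|d − v_s t| ≤ a`;
sinograms superpose these transients, so the model is exactly linear in the
source amplitudes. `forward_pressure` samples this raw wave on the acquisition
grid.

## Band-limited detection

The detector has a Gaussian amplitude response centred at `center_frequency`
with FWHM = `fractional_bandwidth × center_frequency` (default 2.25 MHz,
70 %), built as a Gabor pair of Gaussians so the DC gain is exactly zero. Its
phase is the **minimum phase** consistent with that magnitude (real-cepstrum
construction). Two considerations fix this choice:

1. Physically, transducer impulse responses are causal and asymmetric; a
   zero-phase response is not realizable.
2. Numerically decisive: the raw N-wave is an odd function of `t − d/v_s`, and
   a zero-phase (time-symmetric) filter preserves that odd symmetry. Simple
   DAS evaluates, at each pixel, an angular average of the wavelet, and the
   angular average of an odd wavelet cancels almost exactly — the measured
   image-to-sinogram peak ratio collapses to ~1 instead of ~10², so sinogram
   noise passes straight through to the image and the reconstructions look
   nothing like measured circular-scan images. The causal response breaks the
   odd symmetry and restores the coherent stacking that real systems (and
   full-wave simulated data) exhibit.

Two sampling paths are provided. `apply_bandpass` filters an existing sinogram
per A-line in the frequency domain. `forward_pressure_bandlimited` — used by
the dataset simulator — evaluates the *continuous* filtered wave at the exact
sample times: the filtered wavelet (ramp ⊛ impulse response, identical for all
detectors up to the 1/(2d) range factor) is tabulated once per source radius
on a grid 64× finer than the acquisition rate and interpolated. Sampling the
discontinuous raw N-wave at 25 MHz and filtering digitally would alias
out-of-band energy into a ~−30 dB background floor; filtering before sampling
is both the physical order (the ADC samples the transducer output) and
alias-free.

Noise is additive white Gaussian, seeded, with standard deviation set by a
peak-referenced sinogram SNR: `20·log₁₀(max|signal|/σ) = target_snr_db`
(default 40 dB for the synthetic datasets; `inf` disables noise).

## Reconstruction

`das_reconstruct` backprojects onto a grid of `nx × ny` square pixels centred
on the scan centre (default 250 × 250 at 0.1 mm/pixel; row 0 is +y). For each
pixel and detector the fractional delay index is
`(d/v_s − time_offset)·f_s`; the A-line is linearly interpolated there
(nearest-neighbour selectable), indices outside `[0, n_samples − 1]`
contribute zero (no clamping), and detectors enter with uniform weight 1
(simple DAS). The 2-D solid-angle weight — the arc `R·Δθ` projected on the
element's inward normal, divided by `2π·d` — is available as an option but is
not the default, since the simple beamformer is the reference method here.
The implementation is vectorised over detector blocks of 64 and is verified
against a literal triple-loop oracle to 10⁻¹⁰ of the image magnitude.

The filtered term `b = 2p − 2t·∂p/∂t` (`fbp_weighting_term`) uses a
second-order central finite difference (first-order one-sided at the trace
ends). Some texts print the derivative term with an extra factor of the sound
speed `c`; that form is dimensionally inconsistent with the delay
`t = |r − r₀|/v_s` convention, so the `t·∂p/∂t` form is the default and a
`derivative_scale` constant reproduces the literal `c t ∂p/∂t` variant when
wanted. Reconstructed values stay signed; `normalize_image` divides by the
maximum absolute value, and only image export maps to non-negative grey
levels.

## Metrics

* `snr_db`: μᵢ = mean of the 10 largest *absolute* pixel values in the signal
  ROI (reconstructions are signed, so amplitudes are absolute values);
  σ₀ = standard deviation of absolute values in the background ROI;
  SNR = 20·log₁₀(μᵢ/σ₀). Without an explicit `RoiSpec` the signal ROI is the
  whole image and the background the union of the four 25 × 25-pixel corner
  patches (shrunk proportionally on small images) — corners of the standard
  grid lie well outside every bundled phantom.
* `mse` / `psnr_db`: plain mean squared error and
  10·log₁₀(peakval²/MSE) with peakval the reference maximum; identical images
  report `inf` rather than raising.
* `ssim`: the global single-window form computed from whole-image means,
  variances and cross-covariance with the population (divide-by-N)
  convention; defaults C₁ = (0.01·L)², C₂ = (0.03·L)² with L the reference
  dynamic range. A factor whose numerator and denominator both vanish (e.g.
  luminance for zero-mean images with C₁ = 0) is taken at its limit, 1.

## Downsampling study

`run_downsampling_study` simulates each phantom once (band-limited forward +
seeded noise; per-phantom noise seeds are spawned from the study seed),
reconstructs at each downsampling factor, normalizes, and reports per row the
surviving dataset size, the ROI SNR, and PSNR/SSIM/MSE against the factor-1
reconstruction of the same phantom (factor 1 is its own reference: PSNR `inf`,
SSIM 1). `downsample_positions` keeps rows 0, k, 2k, … (⌊N/k⌋ survivors — 800
positions at factor 3 keep 266; 600 keep 200), multiplying the angle step by
k; surviving rows are copied verbatim. `average_pairs` halves 4800-line scans
to 2400 by averaging consecutive pairs, keeping the first row's angle (the
≤ 0.075° midpoint shift is far below system resolution).

At the default conditions (seed 0) the full-sampling images reach 44–57 dB
SNR, and twofold downsampling costs ≤ 3.4 dB SNR with PSNR ≈ 38–52 dB and
SSIM ≥ 0.99 against the full reconstruction — the quantities
`scripts/acceptance.py` recomputes.

## Numerical and design notes

* Fractional-delay interpolation is linear by default; the `nearest` option
  exists for speed comparisons and oracle testing.
* The minimum-phase construction floors the log-magnitude at 10⁻⁷ of peak;
  the response magnitude at the centre frequency is preserved to < 10⁻⁹ and
  at DC stays ≈ 10⁻⁷.
* The filtered-wavelet table spans the N-wave support plus 14 envelope time
  constants of ringing tail; agreement with a 16× oversample-filter-decimate
  reference is within 8 % of peak (dominated by the reference's own residual
  aliasing).
* Sinogram files carry a plain-text header plus either a float32
  little-endian payload (bit-exact round trip) or CSV rows at 9 decimal
  digits; headers with unknown keys load with a logged warning.
* Image export maps min → 0 and max → full scale (8- or 16-bit); an all-equal
  image maps to zeros.
* `n_positions` may be inferred on the CLI as `round(360/angle_step)`,
  mirroring a two-parameter (radius, angle step) user workflow.

## What the synthetic data does and does not show

The generator reproduces the geometry, sampling, band-limitation and noise
seeding of a circular-scan acquisition, and its images show the expected
sparse-view behaviour (streak artifacts growing from factor 2 to factor 3).
It does **not** model full-wave propagation (heterogeneous media,
reflections), frequency-dependent attenuation, finite detector aperture (and
the tangential resolution loss it causes off-centre), or 3-D effects — so
passing tests demonstrate correctness of the reconstruction and metric
pipeline under the stated physics, not performance on experimental
recordings, whose noise is typically stronger and spatially structured.
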