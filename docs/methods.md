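# Methods

This note documents the measurement models, the synthetic phantom that
validates them, the numerical choices, and what a passing test does and
does not establish.  Units are HU, millimeters, lp/mm and mGy
throughout (lp/cm and cGy are converted at the reporting interface).

## Coordinate and unit conventions

Volumes are `(slice, row, col)`, 0-based, axial slices ordered by
increasing table position; physical z comes from recorded slice
positions, never from file order.  Polar angles used for phantom
layout are degrees counterclockwise from the +col (3 o'clock)
direction.  All statistics use HU after rescale.

## Synthetic phantom

The generator renders a cylindrical body (default radius 45 mm,
background 100 HU — chosen so that "n% contrast" disks are exactly
n HU, with air at −1000 HU outside) containing four sections along z:
density/geometry (high- and low-HU inserts, four 3 mm air holes on a
50 mm square, a slanted wire), resolution (a high-contrast disk for
the circular-edge MTF plus bar groups up to 0.7 lp/mm), low-contrast
disks (diameters 15…2 mm at 1% contrast), and a uniform section.

Design choices that make the ground truth analytic:

- **Edges are area-weighted.** Disks and bars are painted with
  oversampled subpixel coverage (8×8, 16× for bar columns), so an
  unblurred edge is a one-pixel integration ramp, not an aliased
  staircase.  The consequence is that every rendered image already
  carries the pixel-aperture transfer `sinc(f·p)`; see "error budget"
  below.
- **System blur is an isotropic in-plane Gaussian** of standard
  deviation σ (default 0.5 mm), so the true MTF is
  `exp(−2π²σ²f²)` with closed-form `f50 = √(ln 2 / 2π²σ²)`.
- **The slice profile is Gaussian in z** with configurable FWHM
  (default = nominal slice thickness); a rectangular profile is
  available since both limits have analytic FWHM.  The slanted wire
  deposits `peak · SSP(z_slice − z_wire(x))` over a narrow Gaussian row
  band, with `z_wire` advancing by `Δx·tan(23°)` — exactly the signal
  the slanted-wire method reads out, so the in-plane wire streak
  shifts by `slice_spacing / tan(23°)` per slice.
- **Noise is white Gaussian in HU**, specified as σ_ref at a reference
  protocol (default 10.7 HU at 18 mGy × 2 mm, a realistic simulator
  operating point) and rescaled by `√(ref_product / product)` — the
  quantum-only assumption that also underlies the scaled-noise metric.
  Real CT noise is spatially correlated by the reconstruction kernel;
  white noise is a deliberate simplification that keeps the σ-recovery
  oracle closed-form.  A green noise test therefore validates the
  scaling law and the ROI statistics, not noise texture.

Determinism: identical spec + seed gives bit-identical volumes
(`numpy.random.default_rng(seed)` is the only randomness).

## Circular-edge MTF

Every pixel within a band (default analysis uses ±8 mm around a 12 mm
radius edge for oracle comparisons; ±4 mm around the 6 mm default
insert in the end-to-end pipeline) contributes one ESF sample at its
signed radial distance to the edge.  The insert center is refined by a
contrast-weighted centroid over a *circular* window of 1.6× the
nominal radius — circular because a square window reaching the
phantom/air boundary at its corners biases the centroid by half a
pixel, which was the single largest error source found during
development.  The edge radius is refined from the half-level crossing
of a coarse (half-pixel) radial profile.

The ESF is averaged in bins of 0.1× pixel spacing (empty interior bins
linearly interpolated and flagged), baseline-subtracted,
differentiated (`numpy.gradient`), windowed, and Fourier-transformed;
the normalized magnitude up to the pixel Nyquist is the MTF, with
f50/f10 by linear interpolation and "beyond Nyquist" reported rather
than extrapolated.

**Windowing.** A Hann window spanning the full grid narrows wide LSFs:
the quadratic term of the cosine inflates f50/f10 by
`≈ (πσ/L)²` (≈4% for σ = 1 mm on an 8 mm half-span).  The
implementation instead uses a Tukey-style window, flat over the
central 40% of the span and cosine-tapered outside, which keeps that
bias below 0.1% while still suppressing differentiated-noise leakage.

**Error budget for oracle comparisons.** Comparing a measured MTF to
the pure Gaussian closed form requires the other transfer terms to be
negligible: the tests therefore render at 0.1 mm pixels (aperture
< 0.5% at f10 for σ = 0.3 mm) with a 12 mm edge radius and 8 mm band
(curvature and tail truncation < 1% at σ = 1 mm).  These are
measurement-protocol choices derived from the closed-form budget
before running the tests.  Residual agreement is ~2%; the acceptance
tolerance is 3%.  At clinical pixel sizes (0.5–1 mm) the aperture term
is real physics and the measured f50 is legitimately below the blur-
only value, as the worked example in the README shows.

**Bar patterns.** Michelson modulation
`(max − min)/(max + min − 2·background)` of the across-bar profile,
averaged along bars, per-period extrema averaged over interior
periods.  A square-wave modulation exceeds the sine-wave MTF (Coltman:
`CTF = (4/π)·[MTF(f) − MTF(3f)/3 + …]`), so bar-vs-MTF tests use a
±0.05 tolerance at 0.6 lp/mm where the correction is ≈0.045.  A group
is "discernible" at modulation ≥ 0.1, mirroring the 10%-MTF vanishing
convention.

## Slanted-wire SSP

Rows over the wire are averaged, the profile median is subtracted
(making the result invariant to uniform HU offsets), the axis is
multiplied by tan(angle), the peak is normalized to 1, and the FWHM is
taken by linear interpolation of the half-maximum crossings nearest
the peak.  Five consecutive usable slices (wire peak ≥ 50 HU above
background) are analyzed and their FWHMs averaged; fewer are used, and
recorded, when the window is truncated.  FWHM-averaging (not
profile-averaging) is the default; profiles from different slices have
shifted peaks, so averaging profiles without registration would bias
the width.

The wire's in-plane image is the true SSP convolved with the in-plane
PSF scaled by tan(angle): a σ = 0.5 mm blur adds
`(0.5·tan 23°)² = (0.21 mm)²` in quadrature, reading a 1.25 mm profile
as ≈1.35 mm.  This matches real scanners (which is why measured
effective slice thickness exceeds nominal) and is deliberately not
deconvolved.  Recovery tests that compare against the generating FWHM
therefore use a thin 0.2 mm in-plane PSF, keeping the bias under 1.5%
at the thinnest profile tested, against a 5% tolerance.

## Uniformity, noise, scaled noise

Uniformity is `max_i |mean_center − mean_peripheral_i|` over four
peripheral 20×20 px ROIs at 12/3/6/9 o'clock, placed at 0.7× the body
radius (clears edge rolloff, stays in the uniform region; fully
configurable).  The headline noise is the central-ROI sample standard
deviation (n−1); all five stds are reported.  The scaled noise
multiplies by `√(product_test / product_ref)`; which reference
protocol pairs with which test protocol is always an explicit config
mapping, never inferred.

## CNR and low-contrast visibility

CNR per slice on 6×6 px ROIs, arithmetic mean over a five-slice window
centered on the ROI slice (truncated at volume edges, count recorded).
`σ_B ≤ 0` (noiseless renders) raises a degenerate-input error at the
CNR operation.  The scaled CNR multiplies by `σ_B / σ̂_B`, i.e.
divides by the Eq.-style noise scale factor — an algebraic identity
that is tested as such.

The visual smallest-disk call is replaced by a Rose-type index:
visible iff `CNR·√(disk area in px) ≥ k` (default k = 3) **and** the
measured contrast is at least 3 standard errors of the ROI mean
difference.  The significance gate exists because the index uses an
*estimated* CNR: without it, zero-contrast disks are "seen" by
estimator noise alone (the 15 mm disk needs only CNR ≈ 0.12, well
inside sampling error).  On a noiseless render the disk is visible
whenever its rendered contrast is nonzero.  The surrogate is monotone
in the same quantities as a human call but is not a human-observer
model; reported diameters should be read alongside the raw CNR.

## Geometry and insert HU

Holes are localized by inverted contrast-weighted centroid
(`clip(median − HU, 0, ∞)`) in a 6 mm window (±3 mm); distances are
the four adjacent-pair lengths of the hole square in physical mm, and
the headline value is the max |d − 50 mm|.  In the crowded composite
module the blur tails of nearby low-HU inserts can bias a centroid by
~0.1 mm; the dedicated geometry fixtures render holes without inserts,
and the 0.5 mm acceptance bound holds in both configurations.  Insert
HU uses a 6×6 px ROI at each center; manufacturer reference ranges
ship only as user-editable configuration, and the range deviation is
`max(low − mean, mean − high, 0)`.

## CTDI_vol

Readings are CTDI₁₀₀ values (already length-normalized);
`CTDI_w = ⅓·mean(central) + ⅔·mean(peripheral)`, `CTDI_vol = CTDI_w /
pitch`.  Repeatability is the population CoV (std/mean, ddof 0) per
position — absent, not zero, for a single reading.  Chamber
calibration and charge-to-dose conversion are out of scope.

## Reporting

`run_full_analysis` records every stage failure against its metric and
still produces the report; tolerance entries for missing metrics
resolve to `not-evaluated`.  "<" bounds are strict.  Reports contain
no timestamps and serialize with sorted keys, so identical inputs give
byte-identical JSON.  ROI placements and intermediate scalars are
logged via the `phantomiq` logger for QA auditability.

## Known limitations

- No projection/reconstruction physics: no sinograms, beam hardening,
  scatter, or kernel-correlated noise; no noise-power spectrum.
- Single-frame axial geometry only; the on-disk format is a raw array
  with a JSON sidecar (DICOM is not supported in this build).
- The low-contrast surrogate is not a model observer (no CHO/NPWE).
- HU-to-electron-density calibration and trend tracking over time are
  out of scope.
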