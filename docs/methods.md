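# Methods

## The measurement chain

The package models film dosimetry of Ru‑106 ophthalmic applicators as a
four-stage chain, each stage a pure function over the previous one:

1. **Scan → ROI statistics.** Film scans (TIFF, 8/16-bit, grayscale or
   RGB) are analysed on the red channel only, in physical coordinates:
   the origin is the centre of the top-left pixel, x right, y down,
   `mm = pixel_index · 25.4 / dpi`. A circular ROI owns every pixel
   whose centre lies within the circle (ties at the exact radius are
   included) — a deterministic rule that a brute-force enumeration can
   verify. At 300 dpi a 1-mm ROI covers 109 pixels. No registration is
   performed; the triangular-mark alignment protocol of the film holder
   is the caller's responsibility (an explicit grid origin may be
   supplied).

2. **ROI statistics → ΔnetOD.** `netOD = log10((P0 − Pbg)/(P − Pbg))`
   so the value grows as the film darkens, re-zeroed against the 0 Gy
   control film. The published form of the log ratio is typographically
   ambiguous about orientation; the convention here is the one under
   which the response is monotone increasing in dose, consistent with
   the Devic error-propagation formalism that the uncertainty stage
   assumes. `Pbg` is a single scalar per scan session (default 0).
   The propagated SD uses the ROI pixel-value SDs directly — *not*
   divided by √n — because the propagation formula is written in terms
   of pixel-value SDs; standard-error semantics are available via a
   flag.

3. **ΔnetOD → dose.** The response is fitted in both directions as a
   two-term power law. The two parameter triples (a, b, n) are distinct
   parameter sets and are never interchanged; the inverse form
   `D = a·x + b·xⁿ` is fitted *directly* to (ΔnetOD, dose) pairs rather
   than obtained by numerically inverting the forward fit, and is the
   form used for dose conversion. Fitting is unweighted nonlinear least
   squares (weights optional): a linear pre-fit of (a, b) with n pinned
   at 2 provides a deterministic start, then the full 3-parameter fit
   runs with n ∈ (1, 5]. Parameter SDs come from the fit covariance
   diagonal with n at its estimate — matching an uncertainty formalism
   that uses only SD(a) and SD(b), treats them as uncorrelated, and
   treats n as exact. The (0 Gy, 0) anchor is included exactly. Fits
   are rejected when the input data or the fitted curve is non-monotone
   on the calibration domain.

4. **Dose → verdicts.** Depth-dose profiles are fitted with a quartic,
   normalised at 2 mm, compared at the 11 certified depths in
   *percentage points* of normalised dose — the definition consistent
   with the certified record, where the 4-mm entry (0.54 vs 0.52 →
   1.93 pp) rules out relative percent, which would give ≈ 3.8. Summary
   SD is the population SD (divisor N). Planar differences, by
   contrast, are *relative* percent, since planar doses are absolute;
   region summaries aggregate |diff| cumulatively over the nested
   R1 ⊂ R2 ⊂ R3 point sets, and the 5 %-of-maximum filter operates on
   the *reference* doses so the excluded set is reproducible under
   measurement noise.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| half-life | 373.6 | days | Ru‑106 decay correction of the certified dose rate |
| calibration schedule | 2.5, 5, 10, 15, 20 | min | at 120.1 mGy/min spans 0.30–2.40 Gy |
| ROI diameter (planar) | 1.0 | mm | matches the certified-point aperture |
| normalisation depth | 2.0 | mm | CAX reference depth |
| exponent bounds | (1, 5] | — | keeps the power term super-linear and the fit monotone near zero |
| grid spacing | CCA 2.55 / COB 3.30 / CIB 3.37 | mm | per-model inter-point distance within the documented 2.55–3.37 mm range |
| low-dose threshold | 5 | % of max | exclusion rule for peripheral points; boundary kept |
| coverage factor k | 2 | — | ≈ 95 % expanded uncertainty |
| QA tolerances | ratio ±2 pp; region mean ≤ 5 %; expanded ≤ 11 % | — | the 11 % bound is the conventional certification criterion this method improves on |

## The synthetic generator

The generator emulates the study conditions, not film physics:

* **True response** `ΔnetOD = 0.14·D − 0.002·D^2.2` — a weakly
  saturating curve (≈ 4 % below linear at 2.4 Gy), typical of
  diacetylene-based film read in reflection below ~3 Gy. The physical
  truth deliberately lives in the *forward* parameterisation so that
  fitting the inverse form is a genuine estimation problem; with this
  curvature the best inverse-form fit reproduces the exact inverse to
  ≈ 0.04 % over the calibrated range. (A much stronger curvature would
  expose the capacity limit of the three-parameter inverse form —
  ≈ 0.5 % at 4× this curvature — which is a property of the model
  family, not of the fitter.)
* **Pixel model** P0 = 40000, Pbg = 1000 at 16 bits; additive i.i.d.
  Gaussian noise (SD 200 counts ≈ 0.5 % of P0) on both pre and post
  images; clip and round to the bit depth. Identical seeds give
  bit-identical TIFFs.
* **Planar field** — logistic plateau/fall-off
  `D(r) = D0·L(r)/L(0)`, `L(r) = 1/(1 + exp((r − R)/w))` with R the
  active radius and w = 1 mm, so the 5 % crossing sits ≈ 3 mm outside
  the active edge. For the notched models a sector centred on +y
  (half-angle 25°, starting at 10.5 mm for the optic notch and 8.0 mm
  for the iris notch) is attenuated to 2 % — the substrate-leakage
  level. These constants were chosen so the filter produces the
  structurally correct kept-point patterns: the fully circular model
  keeps all 33 points, the optic notch leaves R2 intact (25) while the
  outermost ring falls below 5 %, and the iris notch additionally
  removes exactly one R2 point (24).
* **Certified planar reference** — no public certificate lists the 33
  point doses, so `synthetic_certified_planar` evaluates the analytic
  field at the grid points as a synthetic stand-in. Measured-vs-
  reference comparisons therefore quantify the pipeline's estimation
  error (noise, quantisation, ROI averaging over gradients,
  calibration-form mismatch) against an exactly known reference — they
  do not validate the certificate itself.

What passing tests therefore show: the analysis chain is unbiased and
precise under its own stated noise model. What they cannot show:
scanner lateral-response nonuniformity, film-grain spatial correlation,
post-exposure darkening kinetics, arc-vs-chord geometric distortion of
the flattened film, or plaque-positioning error — all absent from the
generator and listed as non-goals.

## Numerical choices and degenerate inputs

* ROI masks are computed exactly on the bounding box; a uniform image
  yields SD = 0 exactly.
* `dose_from_netod` clamps ΔnetOD in [−10⁻⁶, 0) to zero and rejects
  anything more negative; `measure_planar` additionally floors noisy
  near-zero-dose readings at 0 Gy (they fall to the 5 % filter).
  Conversions implying doses outside the calibrated range emit a
  warning; uncertainty budgets *refuse* evaluation below the smallest
  calibration dose — the response is uncharacterised there and no
  extrapolation is performed.
* Budgets are undefined at exactly zero dose (0/0 in both components).
* Quartic evaluation allows at most 1 mm of extrapolation beyond the
  fitted depth span (the certified 0.83-mm point vs a shallowest
  detector position near 1.5 mm).
* The detector air-gap/sensitive-volume geometry is handled as a single
  scalar depth offset applied before fitting (default 0: inputs are
  assumed depth-corrected).
* The QA report evaluates the expanded-uncertainty verdict at the doses
  the session actually delivers (default 1.2/1.8/2.4 Gy). At the 0.3 Gy
  calibration floor, single-pixel-SD propagation under 0.5 % pixel
  noise exceeds the 11 % bound by construction — a signal-to-noise
  statement about single pixels, not a defect of the method; ROI means
  carry far smaller uncertainty.

## Problem sizes

Analyses and tests run on 30–36 mm planar rasters at 300 dpi
(≈ 430² px), 6-point calibration schedules, 10⁵-draw Monte-Carlo
oracles and 200-replicate noisy-fit studies; all sizes are set where
the statistics are stable at the tolerances tested.

## Known limitations

Single-channel (red) densitometry only; no multichannel correction, no
fiducial auto-detection, no gamma-index or distance-to-agreement
analysis, no 2-D interpolation between grid points, and no modelling of
the arc-to-chord mapping discussed qualitatively for flattened curved
films — peripheral agreement on real films will be worse than the
synthetic tests indicate.
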