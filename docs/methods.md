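# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `viatrace`, in the spirit of a methods appendix: what
is computed, under which assumptions, and what the synthetic validation
does and does not demonstrate.

## Intensity to absorbance

A pixel's absorbance is A = −log₁₀((I − I_min)/(I_max − I_min)), with
the blank (I_max) and dark (I_min) references averaged over repeated
frames (kept in floating point) before conversion. Choices:

- **Cap.** Transmittance ratios at or below 10⁻ᶜᵃᵖ (including I ≤
  I_min, which noise produces in nearly opaque regions) are assigned
  A = cap, default 4.0 — beyond any realistic camera dynamic range. The
  cap is a reporting ceiling, not a claim about the sample.
- **Negative absorbance is kept.** Pixels brighter than the blank
  (noise) map to A < 0 and are *not* clipped, so the background noise
  distribution stays symmetric and downstream mixture/peak fits are
  unbiased.
- **Degenerate references error out.** Any pixel with I_max ≤ I_min
  indicates a broken reference pair; the conversion raises with the
  offending pixel count rather than emitting NaN.
- **Exposure check.** A frame is flagged when more than 0.1 % of its
  pixels sit at zero or within 1 % of full scale; quantitative
  absorbance requires the camera's linear range.

## Beer–Lambert calibration

ε is estimated from a dilution series as the per-record mean ± sample
SD of εᵢ = Aᵢ/(cᵢ·lᵢ) (concentrations converted to mol/m³ so ε carries
m²/mol). A through-origin regression slope is available as an
alternative (`method="slope"`); the per-record mean is the default
because dilution-series ε values are conventionally reported as
mean ± SD. Moles under a pixel follow as A · pixel_area/ε; this assumes
the dye in the column imaged by the pixel obeys Beer–Lambert at the
imaging wavelength and that path-length effects inside a cell are
captured by the absorbance sum.

Percent differences between paired results use the mean of the two
values as denominator: 100·|x−y|/((x+y)/2). (One known published volume
comparison appears to use the larger value as denominator instead; the
mean-denominator convention is applied uniformly here and reproduces
every other quoted comparison.)

## Segmentation

- **Adaptive threshold.** Foreground is A > local_mean + k·S, where
  local_mean is a uniform filter over a window sized to the odd integer
  nearest ⅛ of the smaller image dimension, k = 1 − 2·sensitivity, and
  S is the image's 1st–99th percentile absorbance spread. The
  percentile spread (rather than max − min) makes the offset immune to
  a handful of extreme pixels — one unusually dark cell or a capped
  pixel would otherwise raise the threshold image-wide and clip the
  faint scattering rims of ordinary cells. `sensitivity` is a per-image
  knob: 0.5 reduces to a plain local-mean comparison (appropriate for
  clean, high-contrast images), values below 0.5 demand a positive
  contrast margin. The synthetic experiments all use 0.45, which puts
  the margin ≈ 30 read-noise SDs above background while still detecting
  rim-stained live cells at about one-third of the typical ring
  strength.
- **Morphology.** Holes are filled by default (unstained live cells
  image as scattering rings and must be closed into disks before area
  and Feret measurement); components are 8-connected; border-touching
  objects are dropped (partial cells bias volume and moles); objects
  are kept when their equivalent-circle radius lies in [r_min, r_max],
  default 4–16 µm, bracketing Jurkat-sized suspension cells.
- **Feret diameters** are computed by rotating calipers over the convex
  hull of pixel-*corner* coordinates, so a single pixel has Feret
  (√2, 1)·pixel_size rather than zero. Maximum Feret is the largest
  hull-vertex distance; minimum Feret is the smallest width over hull
  edges.
- **Volume** models the cell as a prolate spheroid: V = (4/3)π·a·b·c
  with a = Feret_max/2 and b = c = Feret_min/2 — a single focal plane
  gives no depth, so rotational symmetry about the long axis is
  assumed. Volumes are cubic in diameter, so focus-driven segmentation
  changes amplify in molarity; mol/cell is the more robust unit.

## Correction strategies

- **Strategy 1 (raw)** sums absorbance over each segmented cell.
- **Strategy 2 (background subtracted)** first estimates the medium's
  absorbance per field of view from a two-component Gaussian mixture
  over the pixel histogram (lower-mean component = medium) and
  subtracts it before segmentation. When the components overlap
  (|µ₁−µ₂| < max(σ₁,σ₂)), either weight falls below 5 %, or EM fails,
  the histogram mode is used instead — for sparse fields the mode *is*
  the medium level. Per-field fitting is the default because
  illumination and medium can drift between fields. For speed the
  mixture is fitted on an at-most-100 000-pixel strided subsample.
- **Strategy 3 (background & scattering subtracted)** subtracts
  µ_LT_noBG — the Gaussian-peak mean of the live stained control's
  per-cell moles after strategy 2 — from every cell's moles, and
  recomputes molarity from the corrected moles. The offset is fitted
  once per experiment on pooled LT cells; values above the 95th
  percentile are excluded from the fit so the few genuinely dead cells
  in a healthy culture cannot bias the peak (truncating the far upper
  tail does not move a Gaussian peak's fitted centre). All histogram
  binning uses the Freedman–Diaconis rule, capped at 2000 bins.

## Classification

- **C_min** combines the live (LT) and dead (DT) control values, fits a
  Lorentzian pair (mol/cell; the heavy-tailed choice) or Gaussian pair
  (molarity) to the pooled histogram by nonlinear least squares
  (initialised at the group medians and SDs), and takes the minimum of
  the fitted curve on a 2001-point scan between the fitted peak
  centres. Because the controls are labelled, the fit is validated
  against the known group locations: if the fitted centres stray more
  than 3(σ_live + σ_dead) from the group medians, coincide, or the
  minimum falls outside the between-median interval, the raw-histogram
  minimum between the medians is used instead (also available
  explicitly via `use_fitted=False`). A separability precondition
  (peak distance > pooled SD) raises on degenerate inputs.
- **3σ cutoff**: µ + 3σ of the Gaussian fitted to the live peak,
  capturing 99.9 % of the live fit; used when no dead control exists or
  live-cell recall dominates the risk profile.
- **Tie rule.** A cell exactly at the threshold counts as dead — the
  conservative side for dose-safety applications.

## Synthetic phantoms — what they emulate

Each field renders I = dark + illumination·10^(−OD) with Poisson shot
noise, Gaussian read noise and integer quantization; the blank is the
illumination field, the dark frame the dark level. Defaults (the fixed
study conditions of all shipped experiments): 512×512 px at 0.65 µm/px,
16-bit, 30 000-count illumination with a 5 % linear tilt, 400-count
dark level, 50-count read noise SD. The OD map holds a uniform medium
absorbance (0 for buffer, 0.3 for dye-stained treatments), elliptical
cells (semi-axes ~N(5.5, 0.5) µm, mild eccentricity) whose intracellular
dye — drawn N(20.6, 3) fmol truncated at 0 for dead stained cells — is
spread uniformly over the footprint, and a 1 µm-wide positive-OD ring
at each boundary whose integrated apparent content is drawn
N(3.3, 1.0) fmol. The ring is a *phenomenological* stand-in for
edge scattering, calibrated so live stained cells measure ≈3.3 fmol
apparent dye after background subtraction. Experiments follow the
4-blank/4-dark/10-field control design with 100 non-overlapping cells
per field; mixtures are an exact 1:1 live:dead split. All randomness
flows from a single seed; identical seeds give bit-identical frames.

What passing synthetic tests shows: the conversion, calibration,
segmentation, correction and classification chain is mathematically
correct and unbiased under realistic camera noise at known ground
truth. What it does not show: robustness to defocus and diffraction
(no PSF is modelled), touching or aggregated cells (no watershed
splitting is implemented), real scattering physics, staining kinetics,
or cell-handling variability. Published real-cell values (e.g.
~20.6 fmol/cell for heat-shock-killed cells) set the *scale* of the
generator's defaults; they are not desk-reproducible and are not claimed
as validation targets.

## Problem sizes and determinism

The shipped validation experiments use 2–10 fields of 100 cells per
treatment (≥1000 mixture cells per experiment) and 3–10 independent
seeds per check — sizes chosen to make Monte-Carlo error a small
fraction of the tolerances being checked while keeping a full run in
minutes on one CPU. The Gaussian-mixture background fit uses a fixed
`random_state`, histogram rules are deterministic, and CSV output uses
a fixed float format, so reruns on identical inputs are byte-stable.

## Known limitations

- The adaptive-threshold detection limit means rim-stained live cells
  with very faint rings (≲1 fmol apparent content at default
  conditions) can be missed, slightly inflating percent-dead in
  mixtures (observed ≈ +1.3 points at the default conditions).
- A small systematic deficit (≈1–2 %) in recovered dead-cell dye arises
  from ring pixels whose faint tails fall below threshold; it is well
  inside the stochastic tolerance of the validation but would matter
  for sub-percent absolute accuracy claims.
- Strategy 3's offset is a single global shift; cells whose scattering
  deviates strongly from the LT population (different size or refractive
  index) are corrected imperfectly.
- Molarity inherits cubic sensitivity to Feret measurement through the
  ellipsoid volume; between-instrument molarity comparisons are
  correspondingly weaker than mol/cell comparisons.
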