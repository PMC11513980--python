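# Methods

`opmraman` implements the data-processing side of a single-objective
hyperspectral line-scanning light-sheet (oblique plane) Raman
microscope, together with a synthetic instrument model that generates
every input the pipeline needs with known ground truth. This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic tests do and do not demonstrate.

## Instrument geometry and the calibration model

In hyperspectral mode one camera axis (x′) is spatial — position along
the obliquely launched laser line — and the other (y) is a mixed
spatial/spectral axis: a 300 lp/mm grating disperses the m = −1 order
along y. To good approximation the wavelength at a camera pixel is
affine in three quantities,

    λ(x′, y, g) = λ_ref + D · (y − y_ref − k·(x′ − x_ref)) + G · (g − g_ref),

where D is the dispersion (nm per y pixel, fixed by the grating
constant or supplied), G the galvo-y gain, and k the x′-proportional
vertical image shift caused by the grating tilt. Two quantities are
genuinely unknown per grating insertion and are fit by calibration: k
and the grating-tilt offset, which we fold into λ_ref. Convention:
larger y index = longer wavelength; pixels are 0-based pixel centers.

Raman shifts use Δν̃ = 10⁷(1/λ_exc − 1/λ) with wavelengths in nm; the
default excitation is 660 nm. A wavelength width Δλ converts to
Δν̃ = Δλ·10⁷/λ², so a fixed nm resolution corresponds to *fewer* cm⁻¹
at larger Stokes shift (6 nm ≈ 88.6 cm⁻¹ at 3,000 cm⁻¹ but
110.2 cm⁻¹ at 1,600 cm⁻¹).

Calibration proceeds in three stages:

1. **Coarse** — broadband fluorescence through the 664 nm longpass
   filter. Per column the half-maximum crossing row of the step is
   found with sub-pixel interpolation (threshold 50% of the plateau —
   the midpoint is the natural choice absent a measured filter edge
   shape); de-tilted rows are averaged and λ_ref set so they map to the
   cutoff at the frame's galvo setting. Columns whose step contrast is
   below 4 noise SDs are skipped; no usable column is an error.
2. **Fine** — frames of isolated PS/PMMA particles. Peaks are detected
   per signal-carrying column (boxcar width 3, prominence 3× a robust
   noise SD, parabolic sub-pixel refinement), matched to reference
   shifts within 80 cm⁻¹, and (Δλ_ref, k) fit by least squares;
   matching and fitting are iterated once. Reference lists should hold
   the *observable* peak positions at the instrument's resolution
   (`effective_peak_shifts` computes them): unresolved doublets such as
   PS 1001/1031 cm⁻¹ merge into a single observable peak, and matching
   against the raw line list would be ill-posed. Fewer than 3 matches,
   or matches at a single x′, leave the fit under-determined.
3. **Re-calibration** — after reinserting the grating cube, anchor
   peaks of a fresh muscle-standard spectrum (collagen 1670 ± 60,
   water 3240 ± 120 cm⁻¹ windows; widths chosen to contain the peak at
   a few-pixel miscalibration without capturing neighbors) are compared
   with the stored standard. Peak positions use an intensity-weighted
   centroid above 60% height — robust for both sharp and broad anchors
   — and the affine axis update is estimated twice, the second pass on
   the warped spectrum, which cancels the centroid's band-truncation
   bias. Recovery is a few cm⁻¹ / a few 10⁻³ in scale on constructed
   displacements.

## Synthetic instrument and phantoms

Compound spectra are sums of Gaussian peaks on a smooth autofluorescence
hump. Gaussian (rather than Voigt) line shapes are adequate at the
instrument's 88–200 cm⁻¹ resolution. Peak positions follow standard
polymer tables (PS 1001/1031/1602/2904/3054; PMMA 812/988/1450/1730/2950;
PA6 1063/1130/1440/1635/2900/3300 cm⁻¹) and the tissue bands used for
the biology (collagen 960/1330/1670, carotenoids 1160/1525, lipids
1450/2880, protein 2930, water ~3240 broad).

The camera forward model places each column's spectrum on the y axis
through the inverse calibration map, blurs along y with the beam's
Gaussian profile (10 µm FWHM at field center; for emitters smaller than
the beam the *object* size sets the kernel, which is why sparse
particles show better-than-beam spectral resolution), rotates by the
residual camera tilt (default 0.5° in simulations — small enough to be
realistic, large enough to exercise the compensation step), and applies
exposure scaling, an additive structured background (coverslip band +
mirror blob), Poisson shot noise, and Gaussian read noise. The blur is
applied on a 0.25-pixel oversampled axis *before* sampling at pixel
pitch, otherwise sub-pixel peak phase aliases across columns. Beam blur
is applied along y only: the 650 nm lateral resolution is far below the
simulated x′ pixel pitch (3.6 µm).

Default simulation geometry: 120 × 48-pixel frames, dispersion
200 nm / 120 rows, y pixel pitch 1.8 µm, with row 0 two nm below the
excitation line so the default −40…3400 cm⁻¹, 20 cm⁻¹ grid (173 bins)
is fully covered.

The beating-heart phantom is a blood-filled chamber (carotenoids +
water) inside a contracting myocardium annulus (lipids + protein) in
static collagen/water tissue. The chamber radius oscillates with an
exactly integer period (default 14 frames at 28.6 fps), so frame t and
t + period are pixel-identical by construction; compartment edges are
sigmoid-softened (0.8 px) to avoid single-pixel popping. Acquisition
emits round(dwell/exposure) frames per 5 µm stage step with the true
phase recorded per frame; because camera and stage are unsynchronized,
the first few frames of each step still image the previous row
(default 3). A 100-frame conventional (spectrally integrated,
full-field) video is rendered at 2× the scan pitch and must be resized
downstream, exercising the resampling step. The photon budget is set by
scaling the brightest t = 0 pixel to ~300 expected counts per 35 ms
exposure with 3-count read noise — mid-range SNR for in vivo Raman at
video rate.

**Desk scale.** Tests run the phantom at 10 y steps × 560 frames per
step (40 cardiac cycles per step, so the 40-deep synchronized average
has one exact-phase candidate per cycle) rather than the instrument's
~46 steps × 1,000 frames; the 1,000-frames-per-dwell arithmetic and the
middle-800 trimming rule are asserted separately at true scale, which
costs nothing because no rendering is involved.

## Preprocessing

Fixed order: background subtraction (clamped at zero — Raman counts are
nonnegative; a signed variant exists for noise studies) → bilinear
rotation compensating camera tilt → crop → optional x′ binning (mean
over non-overlapping groups, remainder dropped) and illumination-
gradient compensation. The gradient functional form is not dictated by
physics here; the default is exponential (Beer–Lambert-like), with
linear as an option, and the strength is user-set or fitted from the
column-mean profile of a homogeneous region.

Deskew shears a stack of oblique planes into an orthogonal volume:
plane i is placed at depth i·Δs·sin θ and shifted laterally by
i·Δs·cos θ / pixel_size rows with linear interpolation (θ = 38° tilt by
default); the output is padded so total intensity is conserved to
better than 1%.

## Spectral analysis

Extraction resamples each column onto the uniform shift grid by linear
interpolation after removing the x′-proportional row shift; uncovered
bins are zeroed with a warning. Interpolation error is quadratic in the
ratio of pixel pitch to peak width, so features near the grid Nyquist
limit carry a few-percent amplitude error — the recovery tests use
adequately sampled peaks.

Beam deconvolution is Richardson–Lucy with a Gaussian kernel (the 18 µm
beam estimate by default), 10 iterations with early stop when the mean
relative change drops below 10⁻⁴, reflective boundaries. It preserves
nonnegativity and conserves flux to <1%; it is cross-checked against an
independent Richardson–Lucy implementation in the tests.

Fluorescence subtraction is an exact decomposition (raman + baseline
reconstructs the input bit-for-bit). The default estimator is
asymmetric least squares (λ = 10⁵, p = 0.01, ≤10 reweighting
iterations, pentadiagonal banded solve), with an iteratively clipped
low-order polynomial as alternative; the estimator sits behind a single
interface so it can be swapped. AsLS recovers isolated peak areas to
~0.1% on polynomial baselines but under-follows strongly curved
baselines at the default stiffness — acceptable for band *contrast*,
and a bias common to all phases of a time series.

Band maps average (optionally baseline-subtracted) intensities over a
window — default center ± 40 cm⁻¹, closed interval on bin centers, ties
included. For the cardiac false-color channels the autofluorescence
band (1100–1200 cm⁻¹) is deliberately computed *without* baseline
subtraction (it is the baseline), while the lipid/protein (2800–2900)
and water (3100–3300 cm⁻¹) channels are baseline-subtracted. False
color normalizes each channel by its maximum over the whole series so
temporal changes stay comparable; ROI time series are ROI means per
band normalized to a series maximum of 1.

## Microplastic classification

Training spectra are selected by peak counting in two fingerprint
regimes (700–1850 and 2700–3200 cm⁻¹) after a width-5 moving average,
requiring at least 3/4/3 peaks in the first and 2/1/1 in the second
regime for PS/PMMA/PA6. The prominence floor is 3× a robust noise SD —
scale-free, since no absolute threshold is given by the physics. The
rule is monotone: adding a peak never turns acceptance into rejection.
Counting presupposes sampling fine enough to resolve the class's listed
bands (the PS 1001/1031 doublet needs ≲5 cm⁻¹ sampling); selection is
therefore applied to finely sampled line spectra, not the 20 cm⁻¹
analysis grid.

CNN preprocessing: remove the least-squares linear trend, subtract the
mean, divide by the maximum absolute value, crop to 560–3360 cm⁻¹
(141 bins at 20 cm⁻¹). The result is invariant to positive rescaling
of the input; all-zero/trend-only spectra are rejected.

The classifier is a single 1D convolution layer (64 filters, kernel 3)
→ ReLU → max pool (size 2) → flatten → dense softmax over {PS, PMMA,
PA6, agarose, dish}, trained with Adam (10⁻³, batch 64) on
cross-entropy, stratified 80/20 split, implemented directly in numpy so
a fixed seed gives bit-reproducible training. Design note: pooling must
keep positional information — Raman classes are distinguished by where
their peaks sit, and a *global* max pool over kernel-3 features
empirically caps accuracy near 65%, while the position-preserving
pool(2)/flatten head reaches ≥98% on the synthetic library (held-out).
Score-weighted rendering maps total intensity I to
R = I(s_PS + g), G = I(s_PMMA + g), B = I(s_PA6 + g) with
g = (s_agarose + s_dish)/3, so polymer pixels are colored and
agarose/dish pixels gray.

The synthetic library draws per-spectrum log-normal amplitude jitter
(σ = 0.25), ±5 cm⁻¹ center jitter, a random smooth autofluorescence
(hump + slope + curvature), instrument-resolution blur (60 cm⁻¹), an
overall log-normal intensity scale, and additive Gaussian noise
(σ = 0.05). This emulates spectral variability, not imaging artifacts:
a high library accuracy shows the architecture and preprocessing are
adequate for spectra of this character, not that field spectra from a
particular instrument will classify equally well.

## Retrospective cardiac gating

Per y step the (preprocessed) hyperspectral frames are summed over the
−40…3400 cm⁻¹ pixels, column-wise, into a kymograph (time × x′); with
more than 800 frames only the middle 800 are used (edge frames may
straddle stage positions). Columns whose temporal SD does not strictly
exceed 0.8× the mean column SD are dropped. For each cardiac time
point, the matching row of the resized reference video over an 11-frame
window — *centered* on the time point: 5 before + frame + 5 after,
which keeps the patch "slightly shorter" than the ~14-frame cycle,
whereas an 11-before-plus-11-after reading would exceed it — is
cross-correlated (zero-mean, unit-variance normalized, so scores are
comparable across phases) against the kymograph. Peaks are constrained
to |horizontal lag| ≤ 2 columns, local maxima along the vertical lag
are ranked by score (ties by smaller |lag|), and the top 40 frames are
averaged pixelwise. Averaging uses the mean rather than the sum so
output units stay per-frame counts (a constant factor versus summing).
Rows with partial patch overlap are excluded from the peak search.

Assembled per-(phase, y) rows form a (phase × y × x′ × shift) cube;
missing cells are zero-filled and flagged. On the default phantom the
median phase-assignment error is 0 frames, ≥90% of selected frames lie
within ±1 frame of the query phase, and phase-resolved band maps
correlate with the true compound distributions at mean r ≥ 0.8; the
error grows monotonically as read noise is scaled ×1/×3/×10. Because
selection draws only from the current step's kymograph rows, frames
from other y positions can never contaminate a cell.

## Degenerate inputs and tie-breaks

Constant edge images, peak-free anchor bands, all-constant kymographs,
empty ROIs/windows/index lists, and trend-only spectra raise typed
errors rather than returning garbage. Richardson–Lucy refuses negative
input; baseline fitting reports divergence. Where detectors break ties
(equal correlation scores, equal pooled activations) the earlier index
wins, fixed by implementation.

## Known limitations

- The synthetic data contain no scattering-induced spectral
  degradation, no photobleaching (an optional decay hook exists but is
  off), no heart-rate drift, and no sample drift in x′; real data have
  all four. The gating algorithm tolerates rate drift in principle
  (each time point is matched independently) but this is untested here.
- The fluorescence estimator is a generic AsLS, not a
  physically-derived model of tissue autofluorescence.
- Linear-interpolation extraction limits recovery of peaks sharper than
  ~2 camera pixels; deconvolution partially compensates.
- The classifier is validated on synthetic spectra only; no measured
  polymer spectra ship with the package.
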