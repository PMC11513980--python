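"""Spectral calibration: coarse, fine, and re-calibration.

The pixel->wavelength map (see :class:`~opmraman.types.CalibrationModel`)
has two free parameters: the grating-tilt offset (folded into
``lambda_ref``) and the x'-proportional vertical shift prefactor.  They
are estimated in three stages, mirroring instrument practice:

1. *Coarse*: image broadband fluorescence through the longpass filter;
   the transmission edge on the camera must map to the filter cutoff
   wavelength.  Fixes ``lambda_ref`` to within a few pixels.
2. *Fine*: image isolated emitters of known compounds (PS, PMMA beads)
   and least-squares match the detected Raman peak positions against
   reference shifts, fitting both free parameters.
3. *Re-calibration*: whenever the grating is re-inserted, compare anchor
   peaks (collagen ~1670, water ~3240 cm^-1) of a freshly measured
   standard spectrum against the stored standard and apply the affine
   axis correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal

from .axis import wavelength_to_shift
from .errors import CalibrationError, InvalidInputError, UnderdeterminedError
from .types import CalibrationModel, HyperspectralFrame, Spectrum

__all__ = [
    "coarse_calibrate",
    "fine_calibrate",
    "recalibrate_from_standard",
    "AxisUpdate",
    "detect_peaks",
]

DEFAULT_ANCHOR_BANDS = ((1670.0 - 60.0, 1670.0 + 60.0),
                        (3240.0 - 120.0, 3240.0 + 120.0))


def _boxcar(v, width=3):
    if width <= 1:
        return np.asarray(v, dtype=float)
    from scipy.ndimage import uniform_filter1d

    # nearest-edge handling: zero padding would fabricate edge maxima
    return uniform_filter1d(np.asarray(v, dtype=float), width, mode="nearest")


def _noise_sd(v):
    # robust high-frequency noise estimate: MAD of first differences / sqrt(2)
    d = np.diff(np.asarray(v, dtype=float))
    return 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)


def _parabolic_refine(v, i):
    """Sub-sample peak position by parabola through v[i-1:i+2]."""
    if i <= 0 or i >= len(v) - 1:
        return float(i)
    denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (v[i - 1] - v[i + 1]) / denom


def detect_peaks(values, prominence_sigma=3.0, smooth_width=3):
    """Local-maximum positions (fractional indices) after boxcar smoothing.

    The prominence floor is ``prominence_sigma`` times a robust noise-SD
    estimate of the trace, which keeps the detector scale-free.
    """
    v = _boxcar(values, smooth_width)
    floor = prominence_sigma * max(_noise_sd(values), 1e-12 * (np.ptp(v) + 1e-300))
    idx, _ = signal.find_peaks(v, prominence=floor)
    return np.array([_parabolic_refine(v, i) for i in idx]), v[idx] if len(idx) else np.array([])


def coarse_calibrate(
    edge_image: HyperspectralFrame,
    cutoff_nm: float,
    model0: CalibrationModel,
    min_contrast_sigma: float = 4.0,
) -> CalibrationModel:
    """Anchor ``lambda_ref`` to a longpass transmission edge.

    Per column, the half-maximum crossing row of the (smoothed) step is
    located with sub-pixel interpolation; the de-tilted crossing rows
    are averaged and ``lambda_ref`` is set so that row maps to
    ``cutoff_nm`` at the frame's galvo-y setting (the beam is usually
    steered so the edge sits mid-frame).  Raises
    :class:`CalibrationError` when the step contrast does not clear
    ``min_contrast_sigma`` noise SDs.
    """
    img = np.asarray(edge_image.pixels, dtype=float)
    ny, nx = img.shape
    q = max(ny // 4, 1)
    detilted = []
    for c in range(nx):
        v = _boxcar(img[:, c], 3)
        floor = float(np.median(v[:q]))
        plateau = float(np.median(v[-q:]))
        contrast = plateau - floor
        if contrast <= min_contrast_sigma * max(_noise_sd(img[:, c]), 0.0):
            continue
        half = 0.5 * (floor + plateau)
        above = np.nonzero(v >= half)[0]
        if len(above) == 0 or above[0] == 0:
            continue
        i = above[0]
        # linear sub-pixel interpolation of the crossing
        y_edge = i - 1 + (half - v[i - 1]) / (v[i] - v[i - 1])
        detilted.append(
            y_edge - model0.y_ref - model0.tilt_shift_prefactor * (c - model0.x_ref)
        )
    if not detilted:
        raise CalibrationError("no detectable transmission edge in any column")
    u = float(np.mean(detilted))
    lam_ref = (cutoff_nm - model0.dispersion * u
               - model0.galvo_gain * (edge_image.galvo_y - model0.galvo_ref))
    return model0.replace(
        lambda_ref=lam_ref,
        provenance={**model0.provenance, "coarse": {"cutoff_nm": cutoff_nm,
                                                    "edge_columns": len(detilted)}},
    )


def _collect_peak_observations(frames, model, signal_fraction=0.2):
    """Detected peak (x', y) positions from columns carrying signal."""
    obs = []  # (frame index, x', y)
    for fi, fr in enumerate(frames):
        img = np.asarray(fr.pixels, dtype=float)
        gmax = img.max()
        if gmax <= 0:
            continue
        col_max = img.max(axis=0)
        for c in np.nonzero(col_max > signal_fraction * gmax)[0]:
            rows, _ = detect_peaks(img[:, c])
            for r in np.atleast_1d(rows):
                obs.append((fi, float(c), float(r), fr.galvo_y))
    return obs


def fine_calibrate(
    spectra_frames: Sequence[HyperspectralFrame],
    reference_peaks: Sequence[tuple],
    model0: CalibrationModel,
    frame_compounds: Optional[Sequence[str]] = None,
    match_tol_cm1: float = 80.0,
) -> CalibrationModel:
    """Fit the two free calibration parameters to known Raman peaks.

    ``reference_peaks`` is a list of (compound, shift_cm1) rows; when
    ``frame_compounds`` names the compound in each frame, matching is
    restricted per frame.  Detected peaks are matched to the nearest
    reference within ``match_tol_cm1`` (evaluated with the current
    model), the wavelength offset and tilt-shift prefactor are fit by
    least squares, and matching is repeated once with the refined model.
    """
    refs_all = np.array([s for _, s in reference_peaks], dtype=float)
    compounds = [c for c, _ in reference_peaks]
    obs = _collect_peak_observations(spectra_frames, model0)
    if len(obs) == 0:
        raise UnderdeterminedError("no peaks detected in the supplied frames")

    def match(model):
        matched = []  # (x', y, galvo, ref shift)
        for fi, c, r, g in obs:
            pool = refs_all
            if frame_compounds is not None:
                sel = [k for k, cp in enumerate(compounds)
                       if cp == frame_compounds[fi]]
                pool = refs_all[sel]
            if len(pool) == 0:
                continue
            s = model.pixel_to_shift(c, r, g)
            j = int(np.argmin(np.abs(pool - s)))
            if abs(pool[j] - s) <= match_tol_cm1:
                matched.append((c, r, g, float(pool[j])))
        return matched

    model = model0
    for _ in range(2):  # match -> fit -> re-match -> fit
        matched = match(model)
        if len(matched) < 3:
            raise UnderdeterminedError(
                f"only {len(matched)} matched peaks; need at least 3"
            )
        xs = np.array([m[0] for m in matched])
        if np.ptp(xs) < 2.0:
            raise UnderdeterminedError(
                "matched peaks span a single x' position; the tilt-shift "
                "prefactor is unconstrained"
            )
        ys = np.array([m[1] for m in matched])
        gs = np.array([m[2] for m in matched])
        refs = np.array([m[3] for m in matched])

        def residuals(p):
            dlam, k = p
            m = model0.replace(lambda_ref=model0.lambda_ref + dlam,
                               tilt_shift_prefactor=k)
            lam = m.pixel_to_wavelength(xs, ys, gs)
            return wavelength_to_shift(lam, m.excitation_nm) - refs

        p0 = (model.lambda_ref - model0.lambda_ref, model.tilt_shift_prefactor)
        fit = optimize.least_squares(residuals, p0, method="lm")
        model = model0.replace(
            lambda_ref=model0.lambda_ref + fit.x[0],
            tilt_shift_prefactor=float(fit.x[1]),
        )
    rms = float(np.sqrt(np.mean(residuals(fit.x) ** 2)))
    return model.replace(
        provenance={**model0.provenance,
                    "fine": {"n_matched": len(matched), "rms_cm1": rms}}
    )


@dataclass(frozen=True)
class AxisUpdate:
    """Affine Raman-shift axis correction: s_corrected = scale*s + shift."""

    scale: float
    shift: float

    def apply_to_axis(self, shifts):
        return self.scale * np.asarray(shifts, dtype=float) + self.shift

    def apply(self, spectrum: Spectrum, resample: bool = True) -> Spectrum:
        """Correct a spectrum's axis; optionally resample to the old grid."""
        corrected = self.apply_to_axis(spectrum.shifts)
        if not resample:
            return Spectrum(corrected, spectrum.intensities.copy(),
                            label=spectrum.label)
        vals = np.interp(spectrum.shifts, corrected, spectrum.intensities,
                         left=0.0, right=0.0)
        return Spectrum(spectrum.shifts.copy(), vals, label=spectrum.label)

    @property
    def is_identity(self):
        return abs(self.scale - 1.0) < 1e-9 and abs(self.shift) < 1e-9


def _anchor_peak(spectrum: Spectrum, band) -> float:
    """Sub-bin position of the band's dominant peak.

    A local maximum is required inside the band; its position is refined
    by a parabola through the three samples around the highest maximum.
    The parabola has a small shape-dependent bias on non-quadratic
    peaks, but it is the *same* bias for the standard and the (aligned)
    new spectrum, so the two-pass estimation in
    :func:`recalibrate_from_standard` cancels it.
    """
    lo, hi = band
    m = (spectrum.shifts >= lo) & (spectrum.shifts <= hi)
    if m.sum() < 3:
        raise CalibrationError(f"anchor band {band} not covered by spectrum")
    # smooth the whole spectrum first: smoothing only the band slice
    # would distort its edge bins
    v = _boxcar(spectrum.intensities, 3)[m]
    s = spectrum.shifts[m]
    idx, _ = signal.find_peaks(v)
    if len(idx) == 0:
        raise CalibrationError(f"no peak found inside anchor band {band}")
    i = idx[int(np.argmax(v[idx]))]
    frac = _parabolic_refine(v, i)
    return float(np.interp(frac, np.arange(len(s)), s))


def recalibrate_from_standard(
    new_spectrum: Spectrum,
    standard_spectrum: Spectrum,
    anchor_bands=DEFAULT_ANCHOR_BANDS,
) -> AxisUpdate:
    """Affine axis update aligning a new measurement to the stored standard.

    The highest peak inside each anchor band (defaults: collagen ~1670
    and water ~3240 cm^-1 windows) is located in both spectra; the
    returned update maps the new spectrum's axis onto the standard's.
    """
    if len(anchor_bands) < 2:
        raise InvalidInputError("need at least two anchor bands")
    p_std = np.array([_anchor_peak(standard_spectrum, b) for b in anchor_bands])
    # two passes: the second runs on the warped spectrum, where the
    # centroid estimator's band-truncation bias cancels between the two
    # (then nearly identical) spectra
    update = AxisUpdate(1.0, 0.0)
    current = new_spectrum
    for _ in range(2):
        p_new = np.array([_anchor_peak(current, b) for b in anchor_bands])
        A = np.vstack([p_new, np.ones_like(p_new)]).T
        (scale, shift), *_ = np.linalg.lstsq(A, p_std, rcond=None)
        if scale <= 0:
            raise CalibrationError("recovered axis scale is non-positive")
        update = AxisUpdate(scale=float(scale * update.scale),
                            shift=float(scale * update.shift + shift))
        current = update.apply(new_spectrum)
    return update
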