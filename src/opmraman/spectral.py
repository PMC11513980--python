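"""From calibrated camera frames to spectra and biochemical maps.

Covers per-column spectrum extraction (undoing the x'-dependent grating
shift), Richardson-Lucy removal of the laser-beam profile from the
spectral axis, fluorescence-baseline estimation and subtraction,
band-intensity maps (mean over a wavenumber window), false-color
composition, and ROI time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.linalg import solveh_banded

from .axis import fwhm_nm_to_cm1
from .errors import DegenerateSignalError, InvalidInputError
from .types import CalibrationModel, HyperspectralFrame, InstrumentConfig, Spectrum

__all__ = [
    "BandDefinition",
    "FalseColorSpec",
    "FIG_CHANNELS_HEART",
    "extract_spectra",
    "extract_spectrum_matrix",
    "deconvolve_beam",
    "subtract_fluorescence",
    "subtract_fluorescence_cube",
    "band_intensity_map",
    "compose_false_color",
    "roi_time_series",
]


@dataclass(frozen=True)
class BandDefinition:
    """A wavenumber window over which intensities are averaged.

    Either ``center`` +/- ``half_width`` (default 40 cm^-1) or an
    explicit ``window = (lo, hi)``.  Bin centers inside the *closed*
    interval contribute.
    """

    name: str
    center: Optional[float] = None
    half_width: float = 40.0
    window: Optional[tuple] = None
    subtract_baseline: bool = False

    def bounds(self):
        if self.window is not None:
            lo, hi = self.window
        elif self.center is not None:
            lo, hi = self.center - self.half_width, self.center + self.half_width
        else:
            raise InvalidInputError(f"band {self.name}: no window defined")
        if not lo < hi:
            raise InvalidInputError(f"band {self.name}: empty window {lo}..{hi}")
        return float(lo), float(hi)


@dataclass(frozen=True)
class FalseColorSpec:
    """Three bands mapped to R, G, B with per-channel normalization."""

    red: BandDefinition
    green: BandDefinition
    blue: BandDefinition
    normalization: str = "series-max"

    def __post_init__(self):
        names = {self.red.name, self.green.name, self.blue.name}
        if len(names) < 3:
            raise InvalidInputError("false-color channels must be distinct bands")


# Beating-heart rendering channels: the autofluorescence channel is
# deliberately computed WITHOUT baseline subtraction (it *is* the
# baseline); the two Raman channels with it.
FIG_CHANNELS_HEART = FalseColorSpec(
    red=BandDefinition("autofluorescence", window=(1100.0, 1200.0),
                       subtract_baseline=False),
    green=BandDefinition("lipids_proteins", window=(2800.0, 2900.0),
                         subtract_baseline=True),
    blue=BandDefinition("water", window=(3100.0, 3300.0),
                        subtract_baseline=True),
)


def extract_spectrum_matrix(frame, model: CalibrationModel, grid,
                            galvo_y=None, warn_partial=True):
    """Resample a camera frame onto a uniform shift grid, per column.

    Returns an (n_x, n_grid) matrix.  Each column's rows are mapped to
    Raman shifts through the calibration model (which removes the
    x'-proportional vertical shift) and linearly interpolated onto the
    grid; grid bins outside the column's spectral coverage are zero and
    trigger a partial-coverage warning.
    """
    img = frame.pixels if isinstance(frame, HyperspectralFrame) else np.asarray(frame, dtype=float)
    g = (frame.galvo_y if isinstance(frame, HyperspectralFrame) and galvo_y is None
         else (galvo_y if galvo_y is not None else model.galvo_ref))
    ny, nx = img.shape
    grid = np.asarray(grid, dtype=float)
    y = np.arange(ny)
    out = np.empty((nx, len(grid)))
    partial = False
    for x in range(nx):
        s = model.pixel_to_shift(x, y, g)
        if s[0] > s[-1]:   # ensure increasing for np.interp
            s, v = s[::-1], img[::-1, x]
        else:
            v = img[:, x]
        if grid[0] < s[0] - 1e-9 or grid[-1] > s[-1] + 1e-9:
            partial = True
        out[x] = np.interp(grid, s, v, left=0.0, right=0.0)
    if partial and warn_partial:
        warnings.warn("grid extends beyond the frame's spectral coverage; "
                      "uncovered bins set to zero", stacklevel=2)
    return out


def extract_spectra(frame, model: CalibrationModel, grid,
                    galvo_y=None) -> list:
    """One :class:`Spectrum` per x' column of a hyperspectral frame."""
    mat = extract_spectrum_matrix(frame, model, grid, galvo_y=galvo_y)
    grid = np.asarray(grid, dtype=float)
    return [Spectrum(grid.copy(), row) for row in mat]


# ----------------------------------------------------------------------
# Richardson-Lucy beam deconvolution
# ----------------------------------------------------------------------

def _gaussian_kernel(sigma):
    half = max(int(np.ceil(4.0 * sigma)), 1)
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def richardson_lucy_1d(data, sigma_bins, iterations=10, tol=1e-4, axis=-1):
    """Richardson-Lucy deconvolution with a Gaussian kernel along one axis.

    Multiplicative update with reflective boundaries; stops early when
    the mean relative change drops below ``tol``.  Nonnegative input
    yields nonnegative output and total intensity is conserved to within
    boundary interpolation error.
    """
    d = np.asarray(data, dtype=float)
    if np.any(d < 0):
        raise InvalidInputError("Richardson-Lucy requires nonnegative input")
    if sigma_bins <= 1e-6:
        return d.copy()
    k = _gaussian_kernel(sigma_bins)
    eps = 1e-12
    est = np.clip(d, eps, None)
    for _ in range(int(iterations)):
        conv = ndimage.convolve1d(est, k, axis=axis, mode="reflect")
        ratio = d / np.clip(conv, eps, None)
        corr = ndimage.convolve1d(ratio, k, axis=axis, mode="reflect")
        new = est * corr
        change = np.mean(np.abs(new - est)) / (np.mean(np.abs(est)) + eps)
        est = new
        if change < tol:
            break
    return est


def deconvolve_beam(obj, kernel_fwhm_um, model: CalibrationModel,
                    cfg: InstrumentConfig, iterations=10, tol=1e-4):
    """Remove the laser beam's spatial profile from the spectral axis.

    The beam FWHM (um, sample plane) converts to y pixels via the pixel
    pitch; for a frame the deconvolution runs along y directly, for a
    spectrum the width is further converted to cm^-1 at the spectrum's
    center shift via the model's dispersion and applied on the shift
    grid.  Default 10 iterations with early stop (default beam estimate:
    the 18 um profile in :class:`InstrumentConfig`).
    """
    if kernel_fwhm_um <= 0:
        raise InvalidInputError("kernel FWHM must be positive")
    to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    fwhm_px = kernel_fwhm_um / cfg.y_pixel_pitch
    if isinstance(obj, Spectrum):
        fwhm_nm = fwhm_px * abs(model.dispersion)
        center = float(np.median(obj.shifts))
        fwhm_cm1 = fwhm_nm_to_cm1(fwhm_nm, center, model.excitation_nm)
        sigma_bins = fwhm_cm1 * to_sigma / obj.step
        out = richardson_lucy_1d(obj.intensities, sigma_bins,
                                 iterations=iterations, tol=tol)
        return Spectrum(obj.shifts.copy(), out, label=obj.label)
    if isinstance(obj, HyperspectralFrame):
        out = richardson_lucy_1d(obj.pixels, fwhm_px * to_sigma,
                                 iterations=iterations, tol=tol, axis=0)
        return HyperspectralFrame(out, exposure=obj.exposure,
                                  galvo_y=obj.galvo_y, stage_y=obj.stage_y,
                                  timestamp=obj.timestamp)
    return richardson_lucy_1d(np.asarray(obj, dtype=float),
                              fwhm_px * to_sigma,
                              iterations=iterations, tol=tol, axis=0)


# ----------------------------------------------------------------------
# Fluorescence baseline
# ----------------------------------------------------------------------

def _asls_banded_system(n, lam):
    """Upper banded form of lam * D2'D2 for the AsLS normal equations."""
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    A = (lam * (d2.T @ d2)).tocsc()
    ab = np.zeros((3, n))
    ab[0, 2:] = A.diagonal(2)
    ab[1, 1:] = A.diagonal(1)
    ab[2, :] = A.diagonal(0)
    return ab


def asls_baseline(y, lam=1e5, p=0.01, niter=10):
    """Asymmetric-least-squares smooth baseline (Eilers-style).

    Minimizes sum w_i (y_i - z_i)^2 + lam * sum (Delta^2 z)^2 with
    asymmetric weights w = p above the baseline, 1-p below, iterated to
    convergence of the weights.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise InvalidInputError("spectrum too short for baseline estimation")
    ab0 = _asls_banded_system(n, lam)
    w = np.ones(n)
    z = y.copy()
    for _ in range(int(niter)):
        ab = ab0.copy()
        ab[2] += w
        z = solveh_banded(ab, w * y)
        wn = np.where(y > z, p, 1.0 - p)
        if np.array_equal(wn, w):
            break
        w = wn
    if not np.all(np.isfinite(z)):
        raise DegenerateSignalError("baseline fit diverged")
    return z


def polynomial_baseline(y, x=None, degree=3, niter=20):
    """Iteratively clipped low-order polynomial baseline."""
    y = np.asarray(y, dtype=float)
    x = np.linspace(-1, 1, len(y)) if x is None else np.asarray(x, dtype=float)
    target = y.copy()
    for _ in range(int(niter)):
        coef = np.polynomial.polynomial.polyfit(x, target, degree)
        fit = np.polynomial.polynomial.polyval(x, coef)
        target = np.minimum(target, fit)
    return fit


def subtract_fluorescence(spectrum: Spectrum, method="asls", **params):
    """Split a spectrum into (raman, baseline) with raman + baseline = input.

    The baseline is a smooth estimate of the autofluorescence; the
    default estimator is asymmetric least squares (configurable lam, p),
    with an iteratively clipped polynomial as alternative
    (``method='polynomial'``).  The decomposition is exact by
    construction: the Raman part is the input minus the baseline.
    """
    y = spectrum.intensities
    if method == "asls":
        base = asls_baseline(y, **params)
    elif method == "polynomial":
        base = polynomial_baseline(y, x=spectrum.shifts, **params)
    else:
        raise InvalidInputError(f"unknown baseline method {method!r}")
    raman = y - base
    base = y - raman   # re-derive so raman + baseline == input bit-for-bit
    return (Spectrum(spectrum.shifts.copy(), raman, label=spectrum.label),
            Spectrum(spectrum.shifts.copy(), base, label=spectrum.label))


def subtract_fluorescence_cube(cube, method="asls", **params):
    """Baseline-subtract every spectrum of a (..., n_bins) array."""
    arr = np.asarray(cube, dtype=float)
    flat = arr.reshape(-1, arr.shape[-1])
    out = np.empty_like(flat)
    if method == "asls":
        lam = params.get("lam", 1e5)
        ab0 = _asls_banded_system(arr.shape[-1], lam)
        p = params.get("p", 0.01)
        niter = params.get("niter", 10)
        for i, y in enumerate(flat):
            w = np.ones(len(y))
            z = y
            for _ in range(niter):
                ab = ab0.copy()
                ab[2] += w
                z = solveh_banded(ab, w * y)
                wn = np.where(y > z, p, 1.0 - p)
                if np.array_equal(wn, w):
                    break
                w = wn
            out[i] = y - z
    else:
        for i, y in enumerate(flat):
            out[i] = y - polynomial_baseline(y, **params)
    return out.reshape(arr.shape)


# ----------------------------------------------------------------------
# Band maps, false color, ROI series
# ----------------------------------------------------------------------

def band_intensity_map(cube, shifts, band: BandDefinition, baseline_params=None):
    """Mean intensity over a wavenumber window, per pixel.

    ``cube`` has the shift axis last (any leading shape); bins whose
    centers fall inside the closed window contribute.  With
    ``band.subtract_baseline`` the fluorescence baseline is removed per
    spectrum before averaging.
    """
    arr = np.asarray(cube, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    lo, hi = band.bounds()
    m = (shifts >= lo) & (shifts <= hi)
    if not m.any():
        raise InvalidInputError(f"band {band.name}: no grid bins in [{lo}, {hi}]")
    if band.subtract_baseline:
        arr = subtract_fluorescence_cube(arr, **(baseline_params or {}))
    return arr[..., m].mean(axis=-1)


def compose_false_color(maps: Sequence[np.ndarray], spec: FalseColorSpec = None):
    """Stack three band maps into an RGB image (or image series).

    Each channel is independently normalized by its maximum over the
    *whole* input (so temporal changes stay comparable across a series)
    and clipped to [0, 1].  All-zero channels normalize to zero with a
    warning.  Output shape: input shape + (3,).
    """
    if len(maps) != 3:
        raise InvalidInputError("need exactly three band maps")
    shapes = {np.asarray(m).shape for m in maps}
    if len(shapes) != 1:
        raise InvalidInputError("band maps must share a shape")
    chans = []
    for i, m in enumerate(maps):
        a = np.clip(np.asarray(m, dtype=float), 0.0, None)
        mx = a.max()
        if mx <= 0:
            warnings.warn(f"channel {i} is all zero", stacklevel=2)
            chans.append(np.zeros_like(a))
        else:
            chans.append(np.clip(a / mx, 0.0, 1.0))
    return np.stack(chans, axis=-1)


def roi_time_series(band_maps_over_time, roi):
    """Per-band ROI mean vs time, normalized to max 1 per band.

    ``band_maps_over_time`` maps band name -> (t, ny, nx) array; ``roi``
    is (y0, y1, x0, x1) in map pixels.
    """
    y0, y1, x0, x1 = roi
    if y1 <= y0 or x1 <= x0:
        raise InvalidInputError("empty ROI")
    out = {}
    for name, stack in band_maps_over_time.items():
        a = np.asarray(stack, dtype=float)
        if y1 > a.shape[1] or x1 > a.shape[2]:
            raise InvalidInputError("ROI outside maps")
        series = a[:, y0:y1, x0:x1].mean(axis=(1, 2))
        mx = np.abs(series).max()
        out[name] = series / mx if mx > 0 else series
    return out
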