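"""Core domain types.

The calibration model maps camera pixel coordinates to wavelength.  On
the camera, one axis (columns, x') is spatial — position along the
illuminated line — and the other (rows, y) is a mixed spatial/spectral
axis: the grating disperses the m = -1 order along y, so the row index
is, to good approximation, affine in wavelength, in the galvo-y beam
position, and (through the grating tilt) in x'.

Sign convention: larger y-pixel index = longer wavelength.  Pixel
coordinates are 0-based and refer to pixel centers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .axis import shift_to_wavelength, wavelength_to_shift
from .errors import InvalidInputError

__all__ = [
    "InstrumentConfig",
    "CalibrationModel",
    "HyperspectralFrame",
    "FrameSeries",
    "Spectrum",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Fixed physical parameters of the instrument.

    Beam widths are intensity FWHM in the sample plane; the beam width
    sets the vertical (y) spatial resolution in hyperspectral mode and
    hence the spectral resolution.  Pixel pitches are sample-plane
    equivalents (camera pitch / magnification).
    """

    excitation_wavelength: float = 660.0   # nm
    grating_density: float = 300.0         # line pairs / mm
    tilt_angle: float = 38.0               # degrees, oblique plane vs sample
    beam_fwhm_center: float = 10.0         # um, at field center
    beam_fwhm_edge: float = 20.0           # um, at field edges
    deconvolution_fwhm: float = 18.0       # um, beam-profile estimate for RL
    frame_exposure: float = 0.035          # s
    longpass_cutoff: float = 664.0         # nm
    y_pixel_pitch: float = 1.8             # um per y pixel (sample plane)
    x_pixel_pitch: float = 3.6             # um per x' pixel (sample plane)
    camera_tilt_deg: float = 0.0           # residual camera rotation

    def __post_init__(self):
        if self.excitation_wavelength <= 0:
            raise InvalidInputError("excitation wavelength must be > 0")
        if not (0.0 < self.tilt_angle < 90.0):
            raise InvalidInputError("tilt angle must be in (0, 90) degrees")
        if self.beam_fwhm_center > self.beam_fwhm_edge:
            raise InvalidInputError("center beam FWHM cannot exceed edge FWHM")
        if self.longpass_cutoff < self.excitation_wavelength:
            raise InvalidInputError("longpass cutoff below excitation line")
        if self.y_pixel_pitch <= 0 or self.x_pixel_pitch <= 0:
            raise InvalidInputError("pixel pitches must be positive")


@dataclass
class CalibrationModel:
    """Affine pixel -> wavelength map with two instrument-specific unknowns.

    lambda(x', y, g) = lambda_ref
                       + dispersion * (y - y_ref - k * (x' - x_ref))
                       + galvo_gain * (g - galvo_ref)

    where k = ``tilt_shift_prefactor`` is the x'-proportional vertical
    image shift caused by the grating tilt, and the grating-tilt offset
    is folded into ``lambda_ref``.  These two are the free parameters
    determined by calibration; the dispersion follows from the grating
    constant (or is supplied), and the galvo gain from the scan optics.
    """

    lambda_ref: float                 # nm at (x_ref, y_ref, galvo_ref)
    dispersion: float                 # nm per y pixel (>0: larger y = redder)
    galvo_gain: float = 0.0           # nm per galvo-y unit
    tilt_shift_prefactor: float = 0.0  # y pixels per x' pixel
    y_ref: float = 0.0
    x_ref: float = 0.0
    galvo_ref: float = 0.0
    excitation_nm: float = 660.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dispersion == 0:
            raise InvalidInputError("dispersion must be nonzero")

    def pixel_to_wavelength(self, x_prime, y, galvo_y=None):
        """Wavelength (nm) at camera pixel (x', y) for a galvo-y setting.

        Affine in all three inputs; extrapolation beyond the frame is
        permitted (the map is globally affine).  Accepts arrays.
        """
        g = self.galvo_ref if galvo_y is None else galvo_y
        x = np.asarray(x_prime, dtype=float)
        yy = np.asarray(y, dtype=float)
        lam = (
            self.lambda_ref
            + self.dispersion
            * (yy - self.y_ref - self.tilt_shift_prefactor * (x - self.x_ref))
            + self.galvo_gain * (np.asarray(g, dtype=float) - self.galvo_ref)
        )
        return lam if np.ndim(lam) else float(lam)

    def wavelength_to_row(self, lambda_nm, x_prime=None, galvo_y=None):
        """Inverse map: fractional y row where ``lambda_nm`` lands."""
        g = self.galvo_ref if galvo_y is None else galvo_y
        x = self.x_ref if x_prime is None else x_prime
        lam = np.asarray(lambda_nm, dtype=float)
        y = (
            self.y_ref
            + self.tilt_shift_prefactor * (np.asarray(x, dtype=float) - self.x_ref)
            + (lam - self.lambda_ref - self.galvo_gain * (g - self.galvo_ref))
            / self.dispersion
        )
        return y if np.ndim(y) else float(y)

    def pixel_to_shift(self, x_prime, y, galvo_y=None):
        """Raman shift (cm^-1) at camera pixel (x', y)."""
        return wavelength_to_shift(
            self.pixel_to_wavelength(x_prime, y, galvo_y), self.excitation_nm
        )

    def shift_to_row(self, shift_cm1, x_prime=None, galvo_y=None):
        """Fractional y row where Raman shift ``shift_cm1`` lands."""
        lam = shift_to_wavelength(shift_cm1, self.excitation_nm)
        return self.wavelength_to_row(lam, x_prime=x_prime, galvo_y=galvo_y)

    def replace(self, **kw):
        return dataclasses.replace(self, **kw)

    # nm of dispersion covered by one y pixel expressed in cm^-1 at a shift
    def dispersion_cm1_at(self, shift_cm1):
        """Local spectral pitch (cm^-1 per y pixel) at a given shift."""
        lam = shift_to_wavelength(shift_cm1, self.excitation_nm)
        return abs(self.dispersion) * 1.0e7 / lam**2


@dataclass
class HyperspectralFrame:
    """One camera exposure: rows = y (mixed spectral axis), cols = x'."""

    pixels: np.ndarray
    exposure: float = 0.035     # s
    galvo_y: float = 0.0
    stage_y: float = 0.0        # um
    timestamp: float = 0.0      # s

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidInputError("frame pixels must be a 2D array")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class FrameSeries:
    """A stack of frames sharing shape/exposure, ordered by time.

    ``frames[t, y, x']`` with per-frame stage position and timestamp.
    """

    frames: np.ndarray           # (t, ny, nx)
    exposure: float
    galvo_y: float = 0.0
    stage_y: Optional[np.ndarray] = None     # (t,) um
    timestamps: Optional[np.ndarray] = None  # (t,) s

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidInputError("frame series must be 3D (t, y, x')")
        n = len(self.frames)
        if self.stage_y is None:
            self.stage_y = np.zeros(n)
        if self.timestamps is None:
            self.timestamps = self.exposure * np.arange(n)
        self.stage_y = np.asarray(self.stage_y, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.stage_y) != n or len(self.timestamps) != n:
            raise InvalidInputError("metadata length mismatch")
        if np.any(np.diff(self.timestamps) < 0):
            raise InvalidInputError("timestamps must be nondecreasing")

    def __len__(self):
        return len(self.frames)

    def frame(self, i) -> HyperspectralFrame:
        return HyperspectralFrame(
            self.frames[i],
            exposure=self.exposure,
            galvo_y=self.galvo_y,
            stage_y=float(self.stage_y[i]),
            timestamp=float(self.timestamps[i]),
        )


@dataclass
class Spectrum:
    """Intensity on a strictly increasing Raman-shift grid (cm^-1)."""

    shifts: np.ndarray
    intensities: np.ndarray
    label: Optional[str] = None

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.shape != self.intensities.shape or self.shifts.ndim != 1:
            raise InvalidInputError("shifts/intensities must be matching 1D")
        if np.any(np.diff(self.shifts) <= 0):
            raise InvalidInputError("shift axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidInputError("intensities must be finite")

    @property
    def step(self):
        return float(self.shifts[1] - self.shifts[0]) if len(self.shifts) > 1 else 0.0

    def crop(self, lo, hi) -> "Spectrum":
        m = (self.shifts >= lo) & (self.shifts <= hi)
        return Spectrum(self.shifts[m], self.intensities[m], label=self.label)

    def copy(self) -> "Spectrum":
        return Spectrum(self.shifts.copy(), self.intensities.copy(), label=self.label)
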