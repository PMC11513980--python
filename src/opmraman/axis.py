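"""Spectral-axis arithmetic.

Conversions between wavelength (nm) and Raman shift (wavenumbers, cm^-1),
resolution bookkeeping, Gaussian-beam irradiance, and the trivial but
load-bearing acquisition arithmetic (exposure -> frame rate, dwell ->
frames per stage step).

Conventions: wavelengths in nm, Raman shifts in cm^-1, beam widths as
FWHM in um, powers in mW. A positive (Stokes) shift corresponds to a
wavelength longer than the excitation line; anti-Stokes shifts are
negative.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "wavelength_to_shift",
    "shift_to_wavelength",
    "fwhm_nm_to_cm1",
    "beam_peak_power_density",
    "frames_per_second",
    "frames_per_step",
    "make_shift_grid",
]

# 1 cm = 1e7 nm, so shift[cm^-1] = 1e7 * (1/lambda_exc - 1/lambda), nm in.
_NM_PER_CM = 1.0e7


def wavelength_to_shift(lambda_nm, excitation_nm):
    """Raman shift (cm^-1) of scattered wavelength ``lambda_nm``.

    Negative for anti-Stokes wavelengths (shorter than the excitation).
    Accepts scalars or arrays.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0) or excitation_nm <= 0:
        raise InvalidInputError("wavelengths must be positive")
    out = _NM_PER_CM * (1.0 / excitation_nm - 1.0 / lam)
    return out if out.ndim else float(out)


def shift_to_wavelength(shift_cm1, excitation_nm):
    """Scattered wavelength (nm) at Raman shift ``shift_cm1``.

    Exact inverse of :func:`wavelength_to_shift`. The shift must lie
    below the pole 1e7/excitation_nm (where the wavelength diverges).
    """
    s = np.asarray(shift_cm1, dtype=float)
    if excitation_nm <= 0:
        raise InvalidInputError("excitation wavelength must be positive")
    if np.any(s >= _NM_PER_CM / excitation_nm):
        raise InvalidInputError(
            f"shift at/above the pole {_NM_PER_CM / excitation_nm:.1f} cm^-1"
        )
    out = 1.0 / (1.0 / excitation_nm - s / _NM_PER_CM)
    return out if out.ndim else float(out)


def fwhm_nm_to_cm1(delta_lambda_nm, shift_cm1, excitation_nm):
    """Convert a spectral width from nm to cm^-1 at a given Raman shift.

    A fixed wavelength width Delta-lambda corresponds to a wavenumber
    width Delta-lambda * 1e7 / lambda^2, evaluated at the scattered
    wavelength of ``shift_cm1``; the cm^-1 width therefore *decreases*
    with increasing Stokes shift.
    """
    if np.any(np.asarray(delta_lambda_nm) < 0):
        raise InvalidInputError("width must be nonnegative")
    lam = shift_to_wavelength(shift_cm1, excitation_nm)
    out = np.asarray(delta_lambda_nm, dtype=float) * _NM_PER_CM / lam**2
    return out if out.ndim else float(out)


def beam_peak_power_density(power_mw, fwhm_um):
    """Peak irradiance (mW/um^2) at the center of a Gaussian beam.

    For a circular Gaussian beam of total power P and intensity FWHM w,
    the on-axis irradiance is I0 = 4 ln 2 * P / (pi * w^2).
    """
    if power_mw < 0 or fwhm_um <= 0:
        raise InvalidInputError("power must be >= 0 and FWHM > 0")
    return 4.0 * np.log(2.0) * power_mw / (np.pi * fwhm_um**2)


def frames_per_second(exposure_s):
    """Continuous-readout frame rate implied by an exposure time."""
    if exposure_s <= 0:
        raise InvalidInputError("exposure must be positive")
    return 1.0 / exposure_s


def frames_per_step(seconds_per_step, exposure_s):
    """Number of frames recorded during one stage dwell."""
    if seconds_per_step <= 0:
        raise InvalidInputError("dwell must be positive")
    return int(round(seconds_per_step / exposure_s))


def make_shift_grid(lo=-40.0, hi=3400.0, step=20.0):
    """Uniform Raman-shift grid [lo, hi] inclusive, default 20 cm^-1 pitch."""
    if step <= 0 or hi <= lo:
        raise InvalidInputError("need step > 0 and hi > lo")
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)
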