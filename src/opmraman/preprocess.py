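"""Frame-level corrections applied before any spectral analysis.

Fixed pipeline order: background subtraction -> rotation (compensating
residual camera tilt) -> crop -> optional x' binning and illumination-
gradient compensation.  Every helper is pure and shape-deterministic;
:func:`preprocess_frame` records the applied order in its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .errors import InvalidInputError

__all__ = [
    "PreprocessConfig",
    "subtract_background",
    "rotate_and_crop",
    "bin_x",
    "compensate_gradient",
    "deskew_volume",
    "preprocess_frame",
    "preprocess_stack",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the fixed preprocessing chain."""

    rotation_deg: float = 0.0
    crop: Optional[Tuple[int, int, int, int]] = None   # (y0, y1, x0, x1)
    x_bin: int = 1
    gradient_mode: str = "off"          # off | linear | exponential
    gradient_strength: float = 0.0
    clamp_negative: bool = True

    def __post_init__(self):
        if self.x_bin < 1:
            raise InvalidInputError("x_bin must be >= 1")
        if self.gradient_mode not in ("off", "linear", "exponential"):
            raise InvalidInputError(f"unknown gradient mode {self.gradient_mode!r}")


def subtract_background(frame, background_frame, clamp=True):
    """Pixelwise background subtraction, clamped at zero by default.

    Raman intensities are nonnegative, so negative residuals after
    subtracting the measured optical/camera background are clipped
    unless ``clamp=False`` (signed output, e.g. for noise studies).
    """
    a = np.asarray(frame, dtype=float)
    b = np.asarray(background_frame, dtype=float)
    if a.shape != b.shape and np.ndim(background_frame) != 0:
        raise InvalidInputError(f"shape mismatch {a.shape} vs {b.shape}")
    out = a - b
    return np.clip(out, 0.0, None) if clamp else out


def rotate_and_crop(frame, rotation_deg=0.0, crop=None):
    """Bilinear rotation about the frame center, then crop.

    Out-of-bounds pixels are filled with zero.  Intended for the small
    residual camera tilt (|rotation| < 5 degrees).
    """
    img = np.asarray(frame, dtype=float)
    if abs(rotation_deg) >= 5.0:
        raise InvalidInputError("rotation intended for |angle| < 5 degrees")
    out = img if rotation_deg == 0.0 else _sk_rotate(
        img, rotation_deg, resize=False, order=1, mode="constant",
        cval=0.0, preserve_range=True,
    )
    if crop is not None:
        y0, y1, x0, x1 = crop
        ny, nx = out.shape
        if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise InvalidInputError(f"crop {crop} outside frame {out.shape}")
        out = out[y0:y1, x0:x1]
    return out


def bin_x(frame, factor):
    """Mean over non-overlapping column groups; remainder columns dropped."""
    if factor < 1 or int(factor) != factor:
        raise InvalidInputError("bin factor must be a positive integer")
    img = np.asarray(frame, dtype=float)
    factor = int(factor)
    if factor == 1:
        return img.copy()
    nx = img.shape[-1] // factor * factor
    trimmed = img[..., :nx]
    shape = trimmed.shape[:-1] + (nx // factor, factor)
    return trimmed.reshape(shape).mean(axis=-1)


def compensate_gradient(image, mode="exponential", strength=0.0):
    """Rescale columns to undo laser attenuation along propagation (x').

    linear: g(c) = 1 + strength * c/(ncols-1)
    exponential (Beer-Lambert-like): g(c) = exp(strength * c/(ncols-1))

    Returns ``(compensated, scaling_vector)``.
    """
    img = np.asarray(image, dtype=float)
    if strength < 0:
        raise InvalidInputError("gradient strength must be >= 0")
    ncols = img.shape[-1]
    t = np.arange(ncols) / max(ncols - 1, 1)
    if mode == "off" or strength == 0.0:
        g = np.ones(ncols)
    elif mode == "linear":
        g = 1.0 + strength * t
    elif mode == "exponential":
        g = np.exp(strength * t)
    else:
        raise InvalidInputError(f"unknown gradient mode {mode!r}")
    return img * g, g


def deskew_volume(stack, tilt_deg, plane_step_um, pixel_size_um):
    """Shear a stack of oblique planes into an orthogonal volume.

    ``stack[i]`` is the i-th oblique plane (rows along the scan-coupled
    axis).  Plane i is placed at depth i * plane_step * sin(tilt) and
    sheared laterally by i * plane_step * cos(tilt) / pixel_size rows,
    with linear interpolation; output rows are padded so no intensity is
    lost.  Returns ``(volume, z_spacing_um)``.
    """
    vol_in = np.asarray(stack, dtype=float)
    if vol_in.ndim != 3:
        raise InvalidInputError("stack must be 3D (plane, row, col)")
    if not (0.0 < tilt_deg <= 90.0):
        raise InvalidInputError("tilt must be in (0, 90] degrees")
    theta = np.deg2rad(tilt_deg)
    shift_per_plane = plane_step_um * np.cos(theta) / pixel_size_um
    z_spacing = plane_step_um * np.sin(theta)
    n, ny, nx = vol_in.shape
    total = shift_per_plane * (n - 1)
    pad = int(np.ceil(abs(total) - 1e-9)) if abs(total) > 1e-9 else 0
    out = np.zeros((n, ny + pad, nx))
    rows = np.arange(ny + pad, dtype=float)
    for i in range(n):
        s = shift_per_plane * i if total >= 0 else shift_per_plane * i - total
        # place plane i shifted by s rows (linear interpolation)
        src = rows - s
        lo = np.floor(src).astype(int)
        frac = src - lo
        valid0 = (lo >= 0) & (lo < ny)
        valid1 = (lo + 1 >= 0) & (lo + 1 < ny)
        plane = np.zeros((ny + pad, nx))
        plane[valid0] += (1 - frac[valid0])[:, None] * vol_in[i, lo[valid0]]
        plane[valid1] += frac[valid1][:, None] * vol_in[i, np.clip(lo[valid1] + 1, 0, ny - 1)]
        out[i] = plane
    return out, float(z_spacing)


def preprocess_frame(frame, cfg: PreprocessConfig, background=None):
    """Apply the fixed chain to one frame; returns (frame, provenance)."""
    img = np.asarray(frame, dtype=float)
    steps = []
    if background is not None:
        img = subtract_background(img, background, clamp=cfg.clamp_negative)
        steps.append("background")
    if cfg.rotation_deg or cfg.crop:
        img = rotate_and_crop(img, cfg.rotation_deg, cfg.crop)
        steps.append("rotate_crop")
    if cfg.x_bin > 1:
        img = bin_x(img, cfg.x_bin)
        steps.append(f"bin_x{cfg.x_bin}")
    if cfg.gradient_mode != "off" and cfg.gradient_strength > 0:
        img, _ = compensate_gradient(img, cfg.gradient_mode, cfg.gradient_strength)
        steps.append(f"gradient_{cfg.gradient_mode}")
    return img, {"order": steps}


def preprocess_stack(frames, cfg: PreprocessConfig, background=None):
    """Vectorized chain over a (t, y, x') stack."""
    out = []
    for f in np.asarray(frames, dtype=float):
        img, _ = preprocess_frame(f, cfg, background=background)
        out.append(img)
    return np.stack(out)
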