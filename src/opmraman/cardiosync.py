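"""Retrospective cardiac-phase-synchronized reconstruction.

A hyperspectral line scan of a periodically moving sample records ~1,000
frames per y position while a short conventional video of the full field
serves as the phase reference.  Per y position the hyperspectral frames
are spectrally integrated into a kymograph (time x x'), low-variance
columns are discarded, and for every cardiac time point an 11-frame
window of the video's matching row is cross-correlated against the
kymograph; the top-scoring vertical-lag peaks identify the scan frames
at the same cardiac phase, which are then averaged (cutting shot and
read noise by ~ sqrt(40) ~ 6).  Combining time points and y positions
yields a full phase-resolved hyperspectral cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from skimage.feature import match_template
from skimage.transform import resize as _sk_resize

from .errors import DegenerateSignalError, InvalidInputError
from .spectral import extract_spectrum_matrix
from .types import CalibrationModel, FrameSeries, HyperspectralFrame

__all__ = [
    "Kymograph",
    "PhaseTable",
    "spectral_integrate",
    "filter_columns",
    "prepare_reference",
    "reference_patch",
    "phase_correlate",
    "synchronized_average",
    "assemble_cycle",
    "reconstruct_cycle",
]


@dataclass
class Kymograph:
    """Spectrally integrated line intensity vs time at one y position.

    ``values[t, c]`` over retained columns; ``column_mask`` marks which
    original x' columns survive, ``frame_indices`` maps rows back to
    frame numbers within the source series.
    """

    values: np.ndarray
    column_mask: np.ndarray
    frame_indices: np.ndarray
    y_step: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.column_mask = np.asarray(self.column_mask, dtype=bool)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if len(self.frame_indices) != len(self.values):
            raise InvalidInputError("frame_indices length must match rows")
        if self.column_mask.sum() != self.values.shape[1]:
            raise InvalidInputError("column mask does not match value columns")


@dataclass
class PhaseTable:
    """Selected frames and scores per (cardiac time point, y step)."""

    entries: Dict[Tuple[int, int], dict] = field(default_factory=dict)

    def add(self, phase, y_step, indices, scores):
        order = np.argsort(-np.asarray(scores))
        self.entries[(int(phase), int(y_step))] = {
            "indices": np.asarray(indices)[order],
            "scores": np.asarray(scores, dtype=float)[order],
        }

    def indices(self, phase, y_step):
        return self.entries[(int(phase), int(y_step))]["indices"]

    def to_records(self):
        rows = []
        for (ph, ys), e in sorted(self.entries.items()):
            for rank, (i, s) in enumerate(zip(e["indices"], e["scores"])):
                rows.append({"phase": ph, "y_step": ys, "rank": rank,
                             "frame": int(i), "score": float(s)})
        return rows


def spectral_integrate(series, model: CalibrationModel,
                       shift_range=(-40.0, 3400.0), use_middle=800,
                       galvo_y=None) -> Kymograph:
    """Sum each frame over the in-range spectral pixels, per column.

    Only the middle ``use_middle`` frames are used when more are
    available (the camera and stage are unsynchronized, so edge frames
    may straddle y positions); with fewer frames all are used, with a
    warning.
    """
    if isinstance(series, FrameSeries):
        frames = series.frames
        g = series.galvo_y if galvo_y is None else galvo_y
    else:
        frames = np.asarray(series)
        g = model.galvo_ref if galvo_y is None else galvo_y
    n, ny, nx = frames.shape
    y = np.arange(ny)[:, None]
    x = np.arange(nx)[None, :]
    s = model.pixel_to_shift(x, y, g)
    mask = (s >= shift_range[0]) & (s <= shift_range[1])
    if n > use_middle:
        start = (n - use_middle) // 2
        idx = np.arange(start, start + use_middle)
    else:
        if n < use_middle:
            warnings.warn(
                f"only {n} frames available (< {use_middle}); using all",
                stacklevel=2,
            )
        idx = np.arange(n)
    vals = np.einsum("tyx,yx->tx", np.asarray(frames[idx], dtype=float), mask.astype(float))
    return Kymograph(vals, np.ones(nx, dtype=bool), idx)


def filter_columns(kym: Kymograph, threshold_fraction=0.8) -> Kymograph:
    """Drop columns without significant time variation.

    Retains columns whose temporal SD strictly exceeds
    ``threshold_fraction`` times the mean column SD.
    """
    if len(kym.values) < 2:
        raise InvalidInputError("need at least two rows to compute SDs")
    sd = kym.values.std(axis=0, ddof=0)
    keep = sd > threshold_fraction * sd.mean()
    if not keep.any():
        raise DegenerateSignalError("no columns exceed the SD threshold")
    mask = kym.column_mask.copy()
    mask[np.nonzero(mask)[0][~keep]] = False
    return Kymograph(kym.values[:, keep], mask, kym.frame_indices.copy(),
                     y_step=kym.y_step)


def prepare_reference(video, scan_shape):
    """Resize reference video frames to the scan's (n_y_steps, n_x) grid."""
    frames = video.frames if hasattr(video, "frames") else np.asarray(video)
    out = np.empty((len(frames), *scan_shape))
    for t, f in enumerate(frames):
        out[t] = _sk_resize(np.asarray(f, dtype=float), scan_shape, order=1,
                            anti_aliasing=True, preserve_range=True)
    return out


def reference_patch(video_resized, y_row, time_point, window=11,
                    column_mask=None):
    """Extract the scan row's time variation around one video time point.

    Takes the matching y row from a ``window``-frame window centered on
    ``time_point`` (slightly shorter than one cardiac cycle); windows
    extending past the video bounds wrap cyclically (the motion is
    periodic) and the returned flag reports it.  Returns
    ``(patch, wrapped)`` with patch shape (window, n_retained_columns).
    """
    vid = np.asarray(video_resized, dtype=float)
    n = len(vid)
    if window < 1 or window > n:
        raise InvalidInputError("window must be in [1, n_video_frames]")
    half = window // 2
    t0 = int(time_point)
    idx = np.arange(t0 - half, t0 - half + window)
    wrapped = bool(idx.min() < 0 or idx.max() >= n)
    patch = vid[idx % n, y_row, :]
    if column_mask is not None:
        patch = patch[:, np.asarray(column_mask, dtype=bool)]
    return patch, wrapped


def phase_correlate(patch, kym: Kymograph, top_k=40,
                    horizontal_tolerance=2):
    """Find kymograph rows whose time variation matches the patch.

    Normalized (zero-mean, unit-variance) 2D cross-correlation of the
    patch against the kymograph; candidate peaks are constrained to
    (near-)zero horizontal lag (within ``horizontal_tolerance``
    columns), local maxima along the vertical lag are ranked by score
    (ties by smaller |vertical lag| from the kymograph center) and the
    top ``top_k`` frame indices returned as ``(indices, scores, trace)``.
    """
    from scipy.signal import find_peaks

    patch = np.asarray(patch, dtype=float)
    if patch.shape[1] != kym.values.shape[1]:
        raise InvalidInputError("patch and kymograph column masks differ")
    T = len(kym.values)
    w = len(patch)
    if w > T:
        raise InvalidInputError("patch taller than kymograph")
    ncc = match_template(kym.values, patch, pad_input=True)
    center_c = (ncc.shape[1] - 1) // 2
    lo = max(center_c - horizontal_tolerance, 0)
    hi = min(center_c + horizontal_tolerance, ncc.shape[1] - 1)
    trace = ncc[:, lo:hi + 1].max(axis=1)
    half = w // 2
    valid = np.zeros(T, dtype=bool)
    valid[half:T - (w - 1 - half)] = True
    trace = np.where(valid, trace, -np.inf)
    peaks, _ = find_peaks(trace)
    if len(peaks) == 0:
        raise DegenerateSignalError("no correlation peaks found")
    order = sorted(peaks, key=lambda r: (-trace[r], abs(r - T // 2)))
    if len(order) < top_k:
        warnings.warn(
            f"only {len(order)} correlation peaks (< {top_k}); using all",
            stacklevel=2,
        )
    sel = np.array(order[:top_k], dtype=int)
    return kym.frame_indices[sel], trace[sel], trace


def synchronized_average(frames, indices) -> HyperspectralFrame:
    """Pixelwise mean of the selected frames (per-frame count units)."""
    idx = np.asarray(indices, dtype=int)
    if len(idx) == 0:
        raise InvalidInputError("empty index list")
    if isinstance(frames, FrameSeries):
        avg = np.asarray(frames.frames[idx], dtype=float).mean(axis=0)
        return HyperspectralFrame(avg, exposure=frames.exposure,
                                  galvo_y=frames.galvo_y,
                                  stage_y=float(np.mean(frames.stage_y[idx])),
                                  timestamp=float(np.mean(frames.timestamps[idx])))
    arr = np.asarray(frames, dtype=float)
    return HyperspectralFrame(arr[idx].mean(axis=0))


def assemble_cycle(averaged_frames: Dict[Tuple[int, int], HyperspectralFrame],
                   phases: Sequence[int], y_steps: Sequence[int],
                   model: CalibrationModel, grid):
    """Stack per-(phase, y) averaged rows into a phase-resolved cube.

    Each averaged camera frame holds the spectra of one scan line; it is
    converted to an (n_x, n_bins) row and placed at its (phase, y)
    position.  Missing cells are zero-filled and flagged in the returned
    mask.  Output: ``(cube[phase, y, x', shift], present_mask)``.
    """
    grid = np.asarray(grid, dtype=float)
    first = next(iter(averaged_frames.values()))
    nx = first.shape[1]
    cube = np.zeros((len(phases), len(y_steps), nx, len(grid)))
    present = np.zeros((len(phases), len(y_steps)), dtype=bool)
    for pi, ph in enumerate(phases):
        for yi, ys in enumerate(y_steps):
            fr = averaged_frames.get((ph, ys))
            if fr is None:
                continue
            cube[pi, yi] = extract_spectrum_matrix(fr, model, grid,
                                                   warn_partial=False)
            present[pi, yi] = True
    if not present.all():
        warnings.warn(f"{(~present).sum()} missing (phase, y) cells "
                      "zero-filled", stacklevel=2)
    return cube, present


def reconstruct_cycle(series_by_step: Sequence[FrameSeries],
                      video, model: CalibrationModel, grid,
                      time_points: Sequence[int],
                      window=11, top_k=40, shift_range=(-40.0, 3400.0),
                      threshold_fraction=0.8, use_middle=800,
                      rotation_deg=0.0, background=None):
    """End-to-end phase-synchronized reconstruction.

    ``series_by_step`` holds the hyperspectral frames of each y step,
    ``video`` the conventional reference (a
    :class:`~opmraman.synthetic.ReferenceVideo` or raw (t, ny, nx)
    array).  Frames are preprocessed (background subtraction, camera
    de-tilt), integrated into per-step kymographs, phase-matched against
    the video, averaged ``top_k`` deep, and assembled into a
    ``(phase, y, x', shift)`` cube.

    Returns ``(cube, phase_table, info)``.
    """
    from .preprocess import PreprocessConfig, preprocess_stack

    n_y = len(series_by_step)
    nx = series_by_step[0].frames.shape[2]
    video_resized = prepare_reference(video, (n_y, nx))
    pcfg = PreprocessConfig(rotation_deg=rotation_deg)
    table = PhaseTable()
    averaged = {}
    for j, series in enumerate(series_by_step):
        frames = series.frames.astype(float)
        if background is not None or rotation_deg != 0.0:
            frames = preprocess_stack(frames, pcfg, background=background)
        clean = FrameSeries(frames, exposure=series.exposure,
                            galvo_y=series.galvo_y, stage_y=series.stage_y,
                            timestamps=series.timestamps)
        kym = spectral_integrate(clean, model, shift_range=shift_range,
                                 use_middle=use_middle)
        kym.y_step = j
        kym = filter_columns(kym, threshold_fraction)
        for tp in time_points:
            patch, _ = reference_patch(video_resized, j, tp, window=window,
                                       column_mask=kym.column_mask)
            idx, scores, _ = phase_correlate(patch, kym, top_k=top_k)
            table.add(tp, j, idx, scores)
            averaged[(tp, j)] = synchronized_average(clean, idx)
    cube, present = assemble_cycle(averaged, list(time_points),
                                   list(range(n_y)), model, grid)
    return cube, table, {"present": present}
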