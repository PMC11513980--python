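"""Synthetic instrument and sample simulator.

Everything the pipeline consumes can be generated here with known ground
truth: compound Raman spectra (Gaussian peaks on a smooth
autofluorescence baseline), the camera forward model of the
hyperspectral line-scanning light-sheet geometry (dispersion mapping,
beam blur along y, residual camera rotation, Poisson shot noise plus
Gaussian read noise, additive optical background), a static microplastic
scene, and a periodically beating 2D phantom scanned line-by-line in y
together with a conventional reference video.

The forward model is the exact physical inverse of what the `spectral`
module undoes, so round-trip tests close the loop without any real
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import ndimage

from .axis import make_shift_grid
from .errors import InvalidInputError, PlacementError
from .types import (
    CalibrationModel,
    FrameSeries,
    HyperspectralFrame,
    InstrumentConfig,
    Spectrum,
)

__all__ = [
    "CompoundSpectrumDef",
    "SPECTRAL_LIBRARY",
    "NoiseModel",
    "PhantomScene",
    "ReferenceVideo",
    "make_spectrum",
    "make_training_library",
    "default_calibration",
    "render_hyperspectral_frame",
    "render_scene_series",
    "simulate_heart_acquisition",
    "simulate_microplastics_scene",
    "make_edge_frame",
    "make_particle_frames",
    "effective_peak_shifts",
    "make_background_frame",
]

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class CompoundSpectrumDef:
    """Peak table defining one compound's Raman spectrum.

    ``peaks`` is a sequence of (center cm^-1, FWHM cm^-1, amplitude)
    triples; ``baseline_amplitude`` scales a broad smooth
    autofluorescence hump centered at ``baseline_center``.
    """

    name: str
    peaks: tuple = ()
    baseline_amplitude: float = 0.0
    baseline_center: float = 1500.0
    baseline_width: float = 1800.0

    def __post_init__(self):
        for c, w, a in self.peaks:
            if not (0.0 <= c <= 3600.0):
                raise InvalidInputError(f"{self.name}: peak center {c} outside 0-3600")
            if w <= 0 or a < 0:
                raise InvalidInputError(f"{self.name}: need FWHM > 0, amplitude >= 0")

    def evaluate(self, shifts):
        """Analytic intensity at arbitrary Raman shifts (cm^-1)."""
        s = np.asarray(shifts, dtype=float)
        out = np.zeros_like(s)
        for c, w, a in self.peaks:
            out += a * np.exp(-_FOUR_LN2 * (s - c) ** 2 / w**2)
        if self.baseline_amplitude:
            out += self.baseline_amplitude * np.exp(
                -0.5 * ((s - self.baseline_center) / self.baseline_width) ** 2
            )
        return out


# Reference peak positions: polymers from standard Raman tables; tissue
# constituents (collagen, carotenoids, lipids, protein, water) at the
# positions quoted for zebrafish muscle/wound spectra.
SPECTRAL_LIBRARY: Dict[str, CompoundSpectrumDef] = {
    d.name: d
    for d in [
        CompoundSpectrumDef("PS", peaks=((1001, 20, 1.0), (1031, 20, 0.55),
                                         (1602, 28, 0.65), (2904, 60, 0.75),
                                         (3054, 45, 0.85)),
                            baseline_amplitude=0.06),
        CompoundSpectrumDef("PMMA", peaks=((812, 26, 0.8), (988, 22, 0.3),
                                           (1450, 40, 0.6), (1730, 30, 0.55),
                                           (2950, 70, 1.0)),
                            baseline_amplitude=0.06),
        CompoundSpectrumDef("PA6", peaks=((1063, 25, 0.4), (1130, 30, 0.55),
                                          (1440, 40, 0.75), (1635, 30, 0.3),
                                          (2900, 70, 1.0), (3300, 60, 0.35)),
                            baseline_amplitude=0.06),
        CompoundSpectrumDef("agarose", peaks=((890, 35, 0.45), (1082, 40, 0.5),
                                              (1380, 50, 0.35), (2905, 90, 0.6)),
                            baseline_amplitude=0.12),
        CompoundSpectrumDef("dish", peaks=((560, 120, 0.25), (1090, 150, 0.3)),
                            baseline_amplitude=0.5, baseline_center=1200.0,
                            baseline_width=1400.0),
        CompoundSpectrumDef("collagen", peaks=((960, 30, 0.6), (1330, 40, 0.7),
                                               (1670, 40, 1.0)),
                            baseline_amplitude=0.15),
        CompoundSpectrumDef("carotenoids", peaks=((1160, 30, 1.0), (1525, 35, 0.9)),
                            baseline_amplitude=0.25),
        CompoundSpectrumDef("lipids", peaks=((1450, 40, 0.6), (2880, 70, 1.0)),
                            baseline_amplitude=0.1),
        CompoundSpectrumDef("protein", peaks=((2930, 80, 1.0),),
                            baseline_amplitude=0.1),
        CompoundSpectrumDef("water", peaks=((3240, 300, 1.0),),
                            baseline_amplitude=0.05),
    ]
}


def make_spectrum(defn: CompoundSpectrumDef, grid=None) -> Spectrum:
    """Sample a compound definition on a uniform shift grid."""
    grid = make_shift_grid() if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(grid, defn.evaluate(grid), label=defn.name)


def effective_peak_shifts(defn: CompoundSpectrumDef, resolution_fwhm_cm1,
                          lo=200.0, hi=3500.0):
    """Observable peak positions of a compound at finite spectral resolution.

    Peaks closer than the instrument resolution merge; this renders the
    definition on a fine grid, blurs it to ``resolution_fwhm_cm1`` and
    returns the surviving local-maximum positions — the right reference
    list for matching against peaks detected in real (blurred) frames.
    """
    from scipy.signal import find_peaks

    step = 2.0
    grid = np.arange(lo, hi + step, step)
    v = defn.evaluate(grid)
    v -= defn.baseline_amplitude * np.exp(
        -0.5 * ((grid - defn.baseline_center) / defn.baseline_width) ** 2
    )
    sigma = resolution_fwhm_cm1 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / step
    vb = ndimage.gaussian_filter1d(v, sigma)
    idx, _ = find_peaks(vb, prominence=0.05 * vb.max())
    return grid[idx]


@dataclass
class NoiseModel:
    """Camera noise: Poisson shot noise, Gaussian read noise, background.

    ``background_frame`` is an additive expected-count image (coverslip
    and mirror signatures); identical seeds give identical output.
    """

    read_noise_sd: float = 3.0
    shot_noise: bool = True
    background_frame: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.read_noise_sd < 0:
            raise InvalidInputError("read noise SD must be >= 0")

    def rng(self, stream: int = 0):
        return np.random.default_rng([int(self.seed), int(stream)])

    def apply(self, expected, rng=None):
        """Draw one noisy camera frame from expected counts."""
        rng = self.rng() if rng is None else rng
        exp = np.asarray(expected, dtype=float)
        if self.background_frame is not None:
            exp = exp + self.background_frame
        out = (rng.poisson(np.clip(exp, 0, None)).astype(float)
               if self.shot_noise else exp.copy())
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=exp.shape)
        return out


def make_background_frame(shape, coverslip_row=None, amplitude=8.0):
    """Structured additive background: coverslip band + mirror blob."""
    ny, nx = shape
    y = np.arange(ny)[:, None]
    x = np.arange(nx)[None, :]
    row = ny * 0.15 if coverslip_row is None else coverslip_row
    band = amplitude * np.exp(-0.5 * ((y - row) / (0.03 * ny + 1.0)) ** 2)
    blob = 0.5 * amplitude * np.exp(
        -0.5 * (((y - 0.7 * ny) / (0.12 * ny)) ** 2 + ((x - 0.5 * nx) / (0.2 * nx)) ** 2)
    )
    return (band + blob + 0.25 * amplitude) * np.ones((ny, nx))


def default_calibration(n_y=120, n_x=48, cfg: InstrumentConfig = None,
                        spectral_range_nm=200.0,
                        tilt_shift_prefactor=0.04,
                        galvo_gain=5.0) -> CalibrationModel:
    """Calibration covering the full ~200 nm window on an n_y-row camera.

    Row 0 sits 2 nm below the excitation line (shift ~ -45 cm^-1) and
    row n_y at excitation + (spectral_range - 2) nm, so the default
    -40..3400 cm^-1 grid is fully covered for a 660 nm laser.
    """
    cfg = cfg or InstrumentConfig()
    disp = spectral_range_nm / n_y
    y_ref = n_y / 2.0
    lam0 = cfg.excitation_wavelength - 2.0
    return CalibrationModel(
        lambda_ref=lam0 + disp * y_ref,
        dispersion=disp,
        galvo_gain=galvo_gain,
        tilt_shift_prefactor=tilt_shift_prefactor,
        y_ref=y_ref,
        x_ref=n_x / 2.0,
        excitation_nm=cfg.excitation_wavelength,
    )


class _ForwardModel:
    """Precomputed unit-concentration camera responses per compound.

    The pixel shift map factorizes as s(x', y) = f(y - k*(x' - x_ref)),
    so each compound's beam-blurred response image is computed once and
    a frame is just an einsum with the per-column concentration vector.
    """

    def __init__(self, compounds: Sequence[str], model: CalibrationModel,
                 cfg: InstrumentConfig, shape, galvo_y=None,
                 emitter_fwhm_um=None, library=None):
        library = library or SPECTRAL_LIBRARY
        ny, nx = shape
        self.shape = (ny, nx)
        self.compounds = list(compounds)
        g = model.galvo_ref if galvo_y is None else galvo_y
        k = model.tilt_shift_prefactor
        pad = abs(k) * nx + 2.0
        u = np.arange(-pad, ny + pad, 0.25)
        shifts_u = model.pixel_to_shift(model.x_ref, u, g)  # f(u) at x_ref
        y = np.arange(ny)[:, None]
        x = np.arange(nx)[None, :]
        upos = y - k * (x - model.x_ref)  # (ny, nx) de-tilted coordinate
        fwhm_um = cfg.beam_fwhm_center
        if emitter_fwhm_um is not None:
            fwhm_um = min(fwhm_um, emitter_fwhm_um)
        sigma_px = fwhm_um / cfg.y_pixel_pitch / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        du = u[1] - u[0]
        self.response = np.empty((len(self.compounds), ny, nx))
        for i, name in enumerate(self.compounds):
            prof = library[name].evaluate(shifts_u)       # on fine u axis
            if sigma_px > 1e-6:
                # blur on the fine axis, then sample at pixel positions:
                # avoids sub-pixel aliasing of peaks sharper than a pixel
                prof = ndimage.gaussian_filter1d(prof, sigma_px / du,
                                                 mode="constant")
            self.response[i] = np.interp(upos, u, prof, left=0.0, right=0.0)

    def ideal(self, concentrations: Dict[str, np.ndarray]):
        """Noise-free rate image for per-column concentrations (counts/s)."""
        ny, nx = self.shape
        C = np.zeros((len(self.compounds), nx))
        for i, name in enumerate(self.compounds):
            c = np.asarray(concentrations.get(name, 0.0), dtype=float)
            if c.ndim == 0:
                c = np.full(nx, float(c))
            if c.shape != (nx,):
                raise InvalidInputError(
                    f"concentration for {name} has shape {c.shape}, "
                    f"expected ({nx},)"
                )
            if np.any(c < 0):
                raise InvalidInputError("concentrations must be >= 0")
            C[i] = c
        return np.einsum("cyx,cx->yx", self.response, C)


def _rotate(img, deg):
    if abs(deg) < 1e-12:
        return img
    return ndimage.rotate(img, deg, axes=(1, 0), reshape=False, order=1,
                          mode="constant", cval=0.0, prefilter=False)


def render_hyperspectral_frame(
    line_concentrations: Dict[str, np.ndarray],
    model: CalibrationModel,
    cfg: InstrumentConfig,
    noise: NoiseModel,
    shape=(120, 48),
    gain: float = 1.0,
    stage_y: float = 0.0,
    timestamp: float = 0.0,
    galvo_y: Optional[float] = None,
    emitter_fwhm_um: Optional[float] = None,
    library=None,
    rng=None,
) -> HyperspectralFrame:
    """Image one illuminated line through the camera forward model.

    ``line_concentrations`` maps compound name -> per-column (x')
    concentration (scalar or length-nx vector).  The ideal spectrum of
    each column is placed on the y axis through the calibration model,
    blurred along y by the beam profile (or the emitter size, when the
    emitter is narrower than the beam), rotated by the residual camera
    tilt, scaled by exposure*gain, and corrupted by background + Poisson
    + Gaussian read noise.
    """
    fm = _ForwardModel(list(line_concentrations), model, cfg, shape,
                       galvo_y=galvo_y, emitter_fwhm_um=emitter_fwhm_um,
                       library=library)
    expected = gain * cfg.frame_exposure * _rotate(
        fm.ideal(line_concentrations), cfg.camera_tilt_deg
    )
    pixels = noise.apply(expected, rng=rng)
    return HyperspectralFrame(pixels, exposure=cfg.frame_exposure,
                              galvo_y=galvo_y if galvo_y is not None
                              else model.galvo_ref,
                              stage_y=stage_y, timestamp=timestamp)


# ----------------------------------------------------------------------
# Beating-heart phantom
# ----------------------------------------------------------------------

@dataclass
class PhantomScene:
    """Periodically beating 2D compound-concentration phantom.

    A blood-filled chamber (carotenoids + water) inside a contracting
    myocardium annulus (lipids + protein), embedded in static
    collagen/water tissue.  The chamber radius oscillates with integer
    period ``beat_period`` frames, so frame t and t + period are
    identical by construction.
    """

    shape: tuple = (10, 48)          # (n_y rows = stage steps, n_x columns)
    beat_period: int = 14            # frames per cardiac cycle
    beat_phase_0: int = 0            # phase of frame 0, in frames
    frame_rate: float = 28.6         # fps
    center: Optional[tuple] = None   # (row, col), defaults to field center
    radius: float = None             # mean chamber radius, px
    beat_amplitude: float = 0.35     # fractional radius modulation
    wall_thickness: float = 1.6      # px
    edge_softness: float = 0.8       # px, anti-aliasing of compartment edges

    def __post_init__(self):
        if self.beat_period <= 0:
            raise InvalidInputError("beat period must be positive")
        ny, nx = self.shape
        if self.center is None:
            self.center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
        if self.radius is None:
            self.radius = 0.30 * min(ny, nx / 2.5)

    @property
    def compounds(self):
        return ("water", "carotenoids", "lipids", "protein", "collagen")

    def phase(self, frame_index: int) -> int:
        """Ground-truth cardiac phase (in frames) of a global frame index."""
        return int((frame_index + self.beat_phase_0) % self.beat_period)

    def _radius_at(self, frame_index):
        ph = (frame_index + self.beat_phase_0) % self.beat_period
        return self.radius * (
            1.0 + self.beat_amplitude * np.cos(2.0 * np.pi * ph / self.beat_period)
        )

    def concentrations(self, frame_index: int) -> Dict[str, np.ndarray]:
        """Compound concentration maps (n_y, n_x) at a global frame index."""
        ny, nx = self.shape
        y = np.arange(ny)[:, None]
        x = np.arange(nx)[None, :]
        r = np.hypot(y - self.center[0], (x - self.center[1]) / 2.0)
        rt = self._radius_at(frame_index)

        def soft_disk(radius):
            return 1.0 / (1.0 + np.exp((r - radius) / self.edge_softness))

        chamber = soft_disk(rt - self.wall_thickness / 2.0)
        outer = soft_disk(rt + self.wall_thickness / 2.0)
        wall = np.clip(outer - chamber, 0.0, None)
        tissue = 1.0 - outer
        return {
            "water": 0.8 * chamber + 0.4 * tissue,
            "carotenoids": 1.0 * chamber,
            "lipids": 1.2 * wall,
            "protein": 0.8 * wall,
            "collagen": 1.0 * tissue,
        }

    def motion_mask(self, threshold=0.05):
        """Columns x row mask of pixels that move over one cycle."""
        stack = np.stack([self._total_power_map(t) for t in range(self.beat_period)])
        sd = stack.std(axis=0)
        return sd > threshold * stack.mean()

    def _total_power_map(self, t, library=None):
        library = library or SPECTRAL_LIBRARY
        grid = make_shift_grid()
        conc = self.concentrations(t)
        out = np.zeros(self.shape)
        for name, c in conc.items():
            out += c * float(np.trapezoid(library[name].evaluate(grid), grid))
        return out


@dataclass
class ReferenceVideo:
    """Conventional (spectrally integrated, full-field) video of the scene."""

    frames: np.ndarray        # (t, ny_video, nx_video)
    frame_rate: float
    y_scale: float            # video rows per scan y step
    x_scale: float            # video columns per scan x' column
    phases: Optional[np.ndarray] = None   # ground truth, frames


def simulate_heart_acquisition(
    scene: PhantomScene,
    schedule: Optional[dict] = None,
    cfg: Optional[InstrumentConfig] = None,
    model: Optional[CalibrationModel] = None,
    noise: Optional[NoiseModel] = None,
    target_peak_counts: float = 300.0,
    straddle_frames: int = 3,
    n_video_frames: int = 100,
    video_phase_offset: int = 0,
    video_oversample: int = 2,
):
    """Line-scan the beating phantom and record a reference video.

    Per y step the stage dwells ``seconds_per_step`` while the camera
    runs continuously, giving round(dwell/exposure) hyperspectral frames
    of that scene row; the camera and stage are unsynchronized, so the
    first ``straddle_frames`` frames of each step still image the
    previous row.  A ``n_video_frames``-frame conventional video of the
    whole field is rendered at ``video_oversample`` x the scan pixel
    pitch (it must be resized to the scan geometry downstream).

    Returns ``(series_by_step, video, truth)`` where ``truth`` is a dict
    with per-step ground-truth phases, per-frame imaged row, the video
    phases, and the scene motion mask.
    """
    cfg = cfg or InstrumentConfig(camera_tilt_deg=0.5)
    schedule = dict(schedule or {})
    n_y = int(schedule.get("n_y_steps", scene.shape[0]))
    step_um = float(schedule.get("step_um", 5.0))
    seconds_per_step = float(schedule.get("seconds_per_step", 35.0))
    if n_y > scene.shape[0]:
        raise InvalidInputError("schedule has more y steps than scene rows")
    noise = noise or NoiseModel()
    nx = scene.shape[1]
    frame_shape = schedule.get("frame_shape", (120, nx))
    model = model or default_calibration(frame_shape[0], nx, cfg)
    n_frames = int(round(seconds_per_step / cfg.frame_exposure))

    fm = _ForwardModel(scene.compounds, model, cfg, frame_shape,
                       galvo_y=model.galvo_ref)
    # fix the photon budget: brightest pixel of the t=0 ideal frame maps
    # to target_peak_counts per exposure
    conc0 = scene.concentrations(0)
    row0 = {k: v[0] for k, v in conc0.items()}
    ref_max = fm.ideal(row0).max()
    for j in range(min(3, n_y)):
        m = fm.ideal({k: v[j] for k, v in conc0.items()}).max()
        ref_max = max(ref_max, m)
    gain = target_peak_counts / (ref_max * cfg.frame_exposure)

    rng = noise.rng(stream=1)
    series = []
    phases = []
    rows_imaged = []
    t_global = 0
    for j in range(n_y):
        frames = np.empty((n_frames, *frame_shape), dtype=np.float32)
        ph = np.empty(n_frames, dtype=int)
        rows = np.empty(n_frames, dtype=int)
        stage = np.empty(n_frames)
        ts = np.empty(n_frames)
        for i in range(n_frames):
            row = j - 1 if (j > 0 and i < straddle_frames) else j
            conc = scene.concentrations(t_global)
            line = {k: v[row] for k, v in conc.items()}
            expected = gain * cfg.frame_exposure * _rotate(
                fm.ideal(line), cfg.camera_tilt_deg
            )
            frames[i] = noise.apply(expected, rng=rng)
            ph[i] = scene.phase(t_global)
            rows[i] = row
            stage[i] = row * step_um
            ts[i] = t_global * cfg.frame_exposure
            t_global += 1
        series.append(FrameSeries(frames, exposure=cfg.frame_exposure,
                                  galvo_y=model.galvo_ref, stage_y=stage,
                                  timestamps=ts))
        phases.append(ph)
        rows_imaged.append(rows)

    # conventional reference video at higher sampling
    ny_v = scene.shape[0] * video_oversample
    nx_v = nx * video_oversample
    vframes = np.empty((n_video_frames, ny_v, nx_v), dtype=np.float32)
    vphases = np.empty(n_video_frames, dtype=int)
    vrng = noise.rng(stream=2)
    for t in range(n_video_frames):
        pmap = scene._total_power_map(t + video_phase_offset)
        up = ndimage.zoom(pmap, video_oversample, order=1, prefilter=False)
        vmax = up.max() if up.max() > 0 else 1.0
        expected = target_peak_counts * up / vmax
        vframes[t] = vrng.poisson(expected) + vrng.normal(
            0.0, noise.read_noise_sd, size=expected.shape
        )
        vphases[t] = scene.phase(t + video_phase_offset)
    video = ReferenceVideo(vframes, frame_rate=1.0 / cfg.frame_exposure,
                           y_scale=float(video_oversample),
                           x_scale=float(video_oversample), phases=vphases)
    truth = {
        "phases_by_step": phases,
        "rows_by_step": rows_imaged,
        "video_phases": vphases,
        "motion_mask": scene.motion_mask(),
        "gain": gain,
    }
    return series, video, truth


# ----------------------------------------------------------------------
# Static microplastics scene
# ----------------------------------------------------------------------

def simulate_microplastics_scene(
    counts: Dict[str, int],
    field_shape=(60, 48),
    radius_range=(1.5, 3.0),
    seed: int = 0,
    max_tries_per_particle: int = 500,
    agarose_level: float = 0.5,
    dish_level: float = 0.3,
):
    """Non-overlapping polymer disks in agarose over a dish signature.

    Returns ``(scene_maps, label_map, class_names)``: concentration maps
    per compound, an integer ground-truth label map (0 = background,
    1..n = particle classes in ``class_names`` order).
    """
    ny, nx = field_shape
    rng = np.random.default_rng(seed)
    class_names = list(counts)
    label_map = np.zeros((ny, nx), dtype=int)
    scene = {name: np.zeros((ny, nx)) for name in class_names}
    scene["agarose"] = np.full((ny, nx), agarose_level)
    scene["dish"] = np.full((ny, nx), dish_level)
    placed = []  # (y, x, r)
    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    for ci, name in enumerate(class_names, start=1):
        for _ in range(int(counts[name])):
            for attempt in range(max_tries_per_particle):
                r = rng.uniform(*radius_range)
                cy = rng.uniform(r, ny - 1 - r)
                cx = rng.uniform(r, nx - 1 - r)
                if all(np.hypot(cy - py, cx - px) > r + pr + 1.0
                       for py, px, pr in placed):
                    break
            else:
                raise PlacementError(
                    f"could not place particle {len(placed) + 1} "
                    f"({name}) after {max_tries_per_particle} tries"
                )
            placed.append((cy, cx, r))
            disk = np.hypot(yy - cy, xx - cx) <= r
            scene[name][disk] = 1.0
            scene["agarose"][disk] = 0.0
            label_map[disk] = ci
    return scene, label_map, class_names


def render_scene_series(scene_maps, model, cfg, noise, frame_shape=None,
                        gain=50.0, emitter_fwhm_um=None) -> FrameSeries:
    """Stage-scan a static scene: one hyperspectral frame per scene row."""
    names = list(scene_maps)
    n_y, nx = next(iter(scene_maps.values())).shape
    frame_shape = frame_shape or (120, nx)
    fm = _ForwardModel(names, model, cfg, frame_shape,
                       emitter_fwhm_um=emitter_fwhm_um)
    rng = noise.rng(stream=3)
    frames = np.empty((n_y, *frame_shape), dtype=np.float32)
    for j in range(n_y):
        line = {k: v[j] for k, v in scene_maps.items()}
        expected = gain * cfg.frame_exposure * _rotate(
            fm.ideal(line), cfg.camera_tilt_deg
        )
        frames[j] = noise.apply(expected, rng=rng)
    return FrameSeries(frames, exposure=cfg.frame_exposure,
                       stage_y=np.arange(n_y, dtype=float),
                       timestamps=cfg.frame_exposure * np.arange(n_y))


# ----------------------------------------------------------------------
# Calibration fixtures
# ----------------------------------------------------------------------

def make_edge_frame(model, cfg, shape=(120, 48), plateau=200.0,
                    noise: Optional[NoiseModel] = None) -> HyperspectralFrame:
    """Broadband fluorescence imaged through the longpass filter.

    The galvo is steered so the filter's transmission edge falls near
    the frame center; per column, the recorded intensity follows a
    smooth step at the cutoff wavelength (with a gentle emission
    roll-off toward the red end).  The frame records the galvo setting.
    """
    noise = noise or NoiseModel(read_noise_sd=2.0)
    ny, nx = shape
    if model.galvo_gain == 0:
        galvo = model.galvo_ref
    else:  # put the cutoff at the reference row
        galvo = model.galvo_ref + (cfg.longpass_cutoff - model.lambda_ref) / model.galvo_gain
    y = np.arange(ny)[:, None]
    x = np.arange(nx)[None, :]
    lam = model.pixel_to_wavelength(x, y, galvo)
    edge = 1.0 / (1.0 + np.exp(-(lam - cfg.longpass_cutoff) / 0.6))
    rolloff = np.exp(-np.clip(lam - cfg.longpass_cutoff, 0, None) / 400.0)
    pixels = noise.apply(plateau * edge * rolloff, rng=noise.rng(stream=4))
    return HyperspectralFrame(pixels, exposure=cfg.frame_exposure,
                              galvo_y=galvo)


def make_particle_frames(model, cfg, compounds=("PS", "PMMA"),
                         columns=(8, 20, 34, 44), shape=(120, 48),
                         gain=12000.0, emitter_fwhm_um=6.0,
                         noise: Optional[NoiseModel] = None):
    """Isolated-emitter frames for fine calibration, one per compound.

    Each frame contains point-like particles of one compound at the
    given x' columns.  Returns ``(frames, frame_compounds)``.
    """
    noise = noise or NoiseModel(read_noise_sd=1.0)
    nx = shape[1]
    frames = []
    rng = noise.rng(stream=5)
    for ci, name in enumerate(compounds):
        conc = np.zeros(nx)
        conc[list(columns)] = 1.0
        fm = _ForwardModel([name], model, cfg, shape,
                           emitter_fwhm_um=emitter_fwhm_um)
        expected = gain * cfg.frame_exposure * fm.ideal({name: conc})
        frames.append(HyperspectralFrame(noise.apply(expected, rng=rng),
                                         exposure=cfg.frame_exposure))
    return frames, list(compounds)


# ----------------------------------------------------------------------
# CNN training library
# ----------------------------------------------------------------------

def make_training_library(
    n_per_class: int,
    grid=None,
    classes=("PS", "PMMA", "PA6", "agarose", "dish"),
    seed: int = 0,
    noise_sd: float = 0.05,
    amplitude_jitter: float = 0.25,
    center_jitter_cm1: float = 5.0,
    baseline_scale: float = 0.8,
    resolution_fwhm_cm1: float = 60.0,
    library=None,
):
    """Labeled synthetic Raman spectra for classifier training.

    Per draw the class peak amplitudes are jittered log-normally, the
    centers by a few cm^-1, a random smooth autofluorescence baseline
    (hump + slope + curvature) is added, the spectrum is blurred to the
    instrument's spectral resolution, and Gaussian noise applied.
    Returns a list of labeled :class:`Spectrum`.
    """
    library = library or SPECTRAL_LIBRARY
    grid = make_shift_grid() if grid is None else np.asarray(grid, dtype=float)
    step = grid[1] - grid[0]
    sigma_bins = resolution_fwhm_cm1 / (2 * np.sqrt(2 * np.log(2))) / step
    rng = np.random.default_rng(seed)
    out = []
    for name in classes:
        defn = library[name]
        for _ in range(n_per_class):
            s = np.zeros_like(grid)
            for c, w, a in defn.peaks:
                aj = a * np.exp(rng.normal(0.0, amplitude_jitter))
                cj = c + rng.normal(0.0, center_jitter_cm1)
                wj = w * np.exp(rng.normal(0.0, 0.1))
                s += aj * np.exp(-_FOUR_LN2 * (grid - cj) ** 2 / wj**2)
            s = ndimage.gaussian_filter1d(s, sigma_bins)
            # random smooth autofluorescence: hump + linear + quadratic
            bamp = (defn.baseline_amplitude + 0.1) * baseline_scale * rng.uniform(0.2, 2.0)
            bc = rng.uniform(800.0, 2400.0)
            bw = rng.uniform(900.0, 2200.0)
            u = (grid - grid.mean()) / (grid.max() - grid.min())
            s = s + bamp * (np.exp(-0.5 * ((grid - bc) / bw) ** 2)
                            + rng.normal(0.0, 0.3) * u
                            + rng.normal(0.0, 0.3) * u**2 + 0.2)
            scale = np.exp(rng.normal(0.0, 0.4))   # overall intensity varies
            s = scale * (s + rng.normal(0.0, noise_sd, size=grid.shape))
            out.append(Spectrum(grid, s, label=name))
    return out
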