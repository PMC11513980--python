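"""Shared fixtures: instrument, calibration, and the expensive
simulations (beating-heart phantom run, CNN training, calibration
parameter-recovery trials) are session-scoped so every module reuses
one computation."""

import warnings

import numpy as np
import pytest

import opmraman as om
from opmraman import cardiosync as cs
from opmraman import classify as cl
from opmraman import synthetic as syn


@pytest.fixture(scope="session")
def instrument():
    return om.InstrumentConfig(camera_tilt_deg=0.5)


@pytest.fixture(scope="session")
def cal_model(instrument):
    return syn.default_calibration(120, 48, instrument)


@pytest.fixture(scope="session")
def shift_grid():
    return om.make_shift_grid()


@pytest.fixture(scope="session")
def heart_run(instrument, cal_model, shift_grid):
    """Full beating-phantom acquisition + phase-synchronized reconstruction.

    10 y steps x 560 frames (40 cardiac cycles per step), period 14
    frames, 17 reconstructed time points, top-40 averaging.
    """
    scene = syn.PhantomScene(shape=(10, 48))
    noise = syn.NoiseModel(seed=0)
    series, video, truth = syn.simulate_heart_acquisition(
        scene,
        {"n_y_steps": 10, "seconds_per_step": 560 * instrument.frame_exposure},
        instrument, cal_model, noise,
    )
    time_points = list(range(20, 37))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cube, table, info = cs.reconstruct_cycle(
            series, video, cal_model, shift_grid, time_points=time_points,
            rotation_deg=-instrument.camera_tilt_deg,
        )
    return {
        "scene": scene, "series": series, "video": video, "truth": truth,
        "cube": cube, "table": table, "info": info,
        "time_points": time_points, "model": cal_model, "grid": shift_grid,
    }


def phase_errors(run):
    """Circular distance between selected-frame phases and query phases."""
    scene = run["scene"]
    truth = run["truth"]
    period = scene.beat_period
    errs = []
    for (tp, j), e in run["table"].entries.items():
        q = truth["video_phases"][tp]
        tph = truth["phases_by_step"][j][e["indices"]]
        d = np.abs((tph - q + period // 2) % period - period // 2)
        errs.extend(d.tolist())
    return np.asarray(errs)


@pytest.fixture(scope="session")
def cnn_run():
    """CNN trained on the 5-class synthetic library: 1,000 spectra per
    class, 200 epochs (the reduced protocol; the accuracy bar is the
    same as at full scale)."""
    lib = syn.make_training_library(1000, seed=1)
    cfg = cl.ClassifierConfig(seed=1, epochs=200)
    model, metrics = cl.train_classifier(lib, cfg)
    return {"model": model, "metrics": metrics, "cfg": cfg, "library": lib}


@pytest.fixture(scope="session")
def fine_calibration_errors(instrument):
    """Relative tilt-shift-prefactor errors over 20 random ground-truth
    models, each recovered from noisy particle frames."""
    from opmraman import calibrate as cal

    rng = np.random.default_rng(7)
    errs = []
    for trial in range(20):
        k_true = rng.uniform(0.02, 0.08)
        model = syn.default_calibration(120, 48, instrument,
                                        tilt_shift_prefactor=k_true)
        model = model.replace(lambda_ref=model.lambda_ref + rng.uniform(-1, 1))
        noise = syn.NoiseModel(read_noise_sd=1.0, seed=trial)
        frames, compounds = syn.make_particle_frames(model, instrument,
                                                     noise=noise)
        res = om.fwhm_nm_to_cm1(
            6.0 / instrument.y_pixel_pitch * model.dispersion, 1600.0,
            model.excitation_nm)
        peaks = [(c, s) for c in compounds
                 for s in syn.effective_peak_shifts(syn.SPECTRAL_LIBRARY[c], res)]
        model0 = model.replace(lambda_ref=model.lambda_ref + 1.8 * model.dispersion,
                               tilt_shift_prefactor=0.0)
        fit = cal.fine_calibrate(frames, peaks, model0,
                                 frame_compounds=compounds)
        errs.append(abs(fit.tilt_shift_prefactor - k_true) / k_true)
    return np.asarray(errs)


@pytest.fixture(scope="session")
def averaged_noise_frames(cal_model):
    """40 noisy renders of one static line plus the noiseless truth."""
    cfg = om.InstrumentConfig()
    line = {"collagen": np.ones(48), "water": 0.5 * np.ones(48)}
    clean = syn.render_hyperspectral_frame(
        line, cal_model, cfg, syn.NoiseModel(read_noise_sd=0, shot_noise=False),
        gain=300).pixels
    noise = syn.NoiseModel(read_noise_sd=3.0, seed=5)
    rng = noise.rng(9)
    frames = np.stack([
        syn.render_hyperspectral_frame(line, cal_model, cfg, noise, gain=300,
                                       rng=rng).pixels
        for _ in range(40)
    ])
    return clean, frames
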