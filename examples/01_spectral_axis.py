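"""Spectral-axis arithmetic of a 660 nm hyperspectral line scanner.

Computes the Raman-shift coverage of the ~200 nm camera window, the
spectral resolution implied by the 10-20 um beam, and the beam-center
irradiance at the powers used in practice.
"""

import opmraman as om

cfg = om.InstrumentConfig()
print(f"excitation: {cfg.excitation_wavelength:.0f} nm")

# a 200 nm window starting at the excitation line
top = om.wavelength_to_shift(cfg.excitation_wavelength + 200.0,
                             cfg.excitation_wavelength)
print(f"200 nm window reaches {top:.0f} cm^-1 of Raman shift")

# the beam width sets the spectral resolution: 6-11 nm FWHM
for dl in (6.0, 11.0):
    r3000 = om.fwhm_nm_to_cm1(dl, 3000.0, cfg.excitation_wavelength)
    r1600 = om.fwhm_nm_to_cm1(dl, 1600.0, cfg.excitation_wavelength)
    print(f"{dl:4.0f} nm FWHM -> {r3000:5.0f} cm^-1 at 3000, "
          f"{r1600:5.0f} cm^-1 at 1600 cm^-1")

# acquisition timing: continuous readout at 35 ms exposure
print(f"35 ms exposure -> {om.frames_per_second(0.035):.1f} fps, "
      f"{om.frames_per_step(35.0, 0.035)} frames per 35 s stage dwell")

# Gaussian-beam peak irradiance at the sample
for mw in (186.0, 248.0, 310.0):
    i0 = om.beam_peak_power_density(mw, cfg.beam_fwhm_center)
    print(f"{mw:5.0f} mW in a {cfg.beam_fwhm_center:.0f} um beam -> "
          f"{i0:.2f} mW/um^2 at the center")

# The shift coverage and resolutions tell you which Raman bands (e.g.
# the CH-stretch region near 2900 cm^-1) the instrument resolves; the
# irradiance numbers bound the photodamage budget.
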