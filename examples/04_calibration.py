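"""Post-acquisition mass calibration of a distorted synthetic acquisition.

Simulates 100 profile scans of an analyte plus four internal calibrants on
a mass axis distorted by up to ~0.35 Th (the kind of drift an aging
quadrupole shows), averages them, fits the mass-axis polynomial and line
shape from the calibrant peaks, and reports the analyte's mass error
before and after calibration.
"""

import numpy as np

from specacc import (
    Formula,
    SimulationConfig,
    Species,
    average_acquisitions,
    build_calibration,
    calibrate_spectrum,
    default_calibrants,
    ion_formula_mz,
    simulate_acquisition_series,
)
from specacc.scoring import _observed_mono_centroid

analyte = Formula.parse("C16H31NO3Na+")
exact = ion_formula_mz(analyte)
cals = [c for c in default_calibrants()
        if c.name in ("atrazine", "cyclophosphamide", "metoprolol",
                      "benzylbutyl_phthalate")]

distortion = (0.025, 1.05e-3, 0.0)  # raw = true + 0.025 + 1.05e-3 * true
config = SimulationConfig(
    species=tuple([Species(c.ion, 60.0) for c in cals] + [Species(analyte, 100.0)]),
    distortion=distortion,
    noise_sigma=1.5,
    baseline=5.0,
    seed=11,
)
scans = simulate_acquisition_series(config, 100)
averaged = average_acquisitions(scans)

raw_centroid = _observed_mono_centroid(averaged, config.distort(exact), 0.5)
print(f"Analyte {analyte.hill()}, exact m/z {exact:.4f}")
print(f"Raw centroid:        {raw_centroid:.4f}  "
      f"(dm = {(raw_centroid - exact) * 1000:+.1f} mDa)")

model = build_calibration(averaged, {c.name: c.ion_mz for c in cals})
print("\nCalibrant residuals after the quadratic mass-axis fit (mDa):")
for name, r in model.residuals_mda.items():
    print(f"  {name:<22} {r:+6.2f}")
print(f"Fitted line shape: FWHM(m) = {model.shape.fwhm_a:.4f} "
      f"+ {model.shape.fwhm_b:.6f} m  "
      f"(R ~ {1 / model.shape.fwhm_b:.0f} at the intercept limit)")

calibrated = calibrate_spectrum(averaged, model)
cal_centroid = _observed_mono_centroid(calibrated, exact, 0.5)
print(f"\nCalibrated centroid: {cal_centroid:.4f}  "
      f"(dm = {(cal_centroid - exact) * 1000:+.1f} mDa)")
print("A ~350 mDa axis error collapses to under a millidalton — accurate "
      "mass from a low-resolution instrument.")
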