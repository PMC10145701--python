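"""Calibrate the kappa angle from binocular samples — no calibration points.

Runs the differential-evolution search (population 35, mutation 0.5,
crossover 1, termination error 1e-9) on nine exact samples and compares
the recovered kappa with the simulation truth.
"""

import numpy as np

import kappacal as kc

scene = kc.remote_scene()
samples = kc.generate_dataset(scene, n_samples=9, rng=0)

result = kc.calibrate(samples, scene.screen_corners, kc.theoretical_de_config(seed=1))

k = result.kappa
print(f"calibrated kappa  : ({k.alpha_left:.3f}, {k.beta_left:.3f}, "
      f"{k.alpha_right:.3f}, {k.beta_right:.3f}) deg")
print(f"simulation truth  : (5.000, 1.500, -5.000, 1.500) deg")
print(f"generations used  : {result.iterations_used}")
print(f"final objective   : {result.final_error:.2e} (converged={result.converged})")
err = np.abs(k.as_array() - scene.kappa_truth.as_array())
print(f"max component err : {err.max():.2e} deg — exact data pins kappa far below 0.01 deg")
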