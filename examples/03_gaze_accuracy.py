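"""Turn a kappa estimate into on-screen points of regard and gaze accuracy.

Compares three gaze pipelines on one synthetic dataset whose true kappa
(3, 1, -4, 2) deg deviates from the population average: the calibrated
kappa, the constant population-average kappa, and the kappa-free
optical-axis intersection (POA).
"""

import dataclasses

import kappacal as kc
from kappacal.baselines import constant_kappa

truth = kc.KappaAngles(3.0, 1.0, -4.0, 2.0)
scene = kc.remote_scene(truth)
samples = kc.generate_dataset(scene, n_samples=9, rng=2)
screen = kc.screen_model(scene.screen_corners)

cfg = dataclasses.replace(
    kc.theoretical_de_config(seed=3), bounds=((1, 5), (0, 3), (-6, -2), (0, 3))
)
calibrated = kc.calibrate(samples, scene.screen_corners, cfg).kappa

d = kc.viewer_distance(samples, screen)
truths = [s.gaze_point for s in samples]
for label, kappa, poa in [
    ("calibrated kappa", calibrated, False),
    ("constant (5,1.5,-5,1.5)", constant_kappa(), False),
    ("no kappa (POA)", kc.KappaAngles(0, 0, 0, 0), True),
]:
    est = [kc.estimate_por(s, kappa, screen, use_optical_axis=poa) for s in samples]
    acc_x = kc.gaze_accuracy(est, truths, d, "x", screen)
    acc_y = kc.gaze_accuracy(est, truths, d, "y", screen)
    print(f"{label:26s} accuracy X {acc_x:6.3f} deg   Y {acc_y:6.3f} deg")
print(f"(viewer distance D = {d:.0f} mm; smaller is better — the calibrated")
print(" kappa restores near-exact gaze while fixed/absent kappa biases it)")
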