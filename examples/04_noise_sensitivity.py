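"""How measurement noise propagates into the calibrated kappa angle.

Re-noises one fixed 9-sample remote dataset and recalibrates repeatedly
(20 repeats per level here; the full protocol uses 100).  Reports the
per-eye component RMSE and the binocular-component RMSE: the constraint
determines the binocular horizontal kappa (alphaL - alphaR)/2 sharply,
while a common rotation of both visual axes stays nearly coplanar with
the baseline, so per-eye components wander inside the solver bounds.
"""

from kappacal.evaluate import run_experiment

df = run_experiment("noise_oa", "remote", seed=0, sds=[0.0, 0.1, 0.3], n_repeats=20)
cols = ["sd", "alphaL", "alphaR", "horizontal", "binocular_horizontal"]
print(df[cols].round(3).to_string(index=False))
print()
print("columns: optical-axis angle-noise SD (deg); RMSE of the per-eye")
print("horizontal components; their pooled value; and the RMSE of the")
print("binocular horizontal kappa — note how the binocular component stays")
print("an order of magnitude better determined under noise.")
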