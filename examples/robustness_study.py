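"""Robustness of the confounding-effect estimator to outlying clusters.

Repeats the published estimation experiment at desk scale: Poisson
outcomes for 200 clusters, outlier effects gamma* = 2 + 0.5 W, and an
increasing fraction of contaminated clusters.  The robust truncated-normal
fit should stay nearly unbiased while the plain normal MLE drifts.
"""

from rppclc import SimStudyConfig, run_estimation_study

print(f"{'outliers':>9} {'|bias| robust':>14} {'|bias| MLE':>11}")
for k, prop in enumerate([0.0, 0.1, 0.2, 0.3]):
    cfg = SimStudyConfig(seed=40 + k, reps=100, outlier_prop=prop, outlier_c=2.0)
    res = run_estimation_study(cfg)
    print(
        f"{prop:9.2f} {res.metrics['rppclc']['abs_bias_nu']:14.4f} "
        f"{res.metrics['mle']['abs_bias_nu']:11.4f}"
    )
print(
    "\nBias of nu_hat (truth 0.25) over 100 replicates: the robust fit "
    "ignores the\ncontaminated clusters via its null intervals; the MLE "
    "absorbs them and is pulled away."
)
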