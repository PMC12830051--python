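"""Between-cluster covariate effects from summaries alone (CRE design).

When cluster effects are correlated with the cluster means of a patient
covariate (gamma* = xi * Xbar + tau), feeding Xbar through the model as an
observed cluster covariate estimates the between-cluster effect xi without
any patient-level data — and stays stable when tau is contaminated by
outliers, unlike the plain (non-robust) summary fit.
"""

from rppclc import SimStudyConfig, run_cre_study

print(f"{'contamination':>13} {'MSE robust':>11} {'MSE plain':>10}")
for k, prop in enumerate([0.0, 0.1, 0.2, 0.3]):
    cfg = SimStudyConfig(seed=60 + k, reps=100, outlier_prop=prop, outlier_c=2.0)
    res = run_cre_study(cfg)
    print(
        f"{prop:13.2f} {res.metrics['rppclc']['mse_nu']:11.5f} "
        f"{res.metrics['mle']['mse_nu']:10.5f}"
    )
print(
    "\nMean squared error of xi_hat (truth 0.25) over 100 replicates: the "
    "robust fit's\nMSE is flat in the contamination level; the plain fit's "
    "grows with it."
)
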