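"""Replication harness: bias of the estimators under the three pleiotropy
regimes of the main simulation design (scaled down for a quick run).

Each scenario is the null (no causal effect, true K = 0); the table shows
that CD-Egger's mean stays near 0 even under directional pleiotropy, where
CD-Ratio's spread vastly exceeds its nominal standard error.
"""

from cdmr import SimScenario, run_study

SCENARIOS = {
    "no pleiotropy": dict(mu_alpha=0.0, sigma_alpha=0.0),
    "balanced (sigma=0.1)": dict(mu_alpha=0.0, sigma_alpha=0.1),
    "directional (mu=0.4)": dict(mu_alpha=0.4, sigma_alpha=0.1),
}

for label, params in SCENARIOS.items():
    scn = SimScenario(m=22, n=20_000, beta_yx=0.0, n_reps=100, seed=7, **params)
    res = run_study(scn, methods=("ratio", "egger"))
    print(f"--- {label} (true K = 0, 100 replicates, n = 20,000) ---")
    print(
        res.summary[["method", "mean_K", "sd_K", "mean_se", "freq_inconclusive"]]
        .round(4)
        .to_string(index=False)
    )
    print()

print(
    "mean_K near 0 = unbiased under the null; sd_K >> mean_se flags an "
    "estimator whose nominal precision is not trustworthy in that regime."
)
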