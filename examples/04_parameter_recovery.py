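"""Monte-Carlo check that the estimators recover a known causal effect.

Replicates a 50-SNP scenario with and without directional pleiotropy and
prints the bias/coverage table for IVW, MR-Egger and the weighted median —
the robustness hierarchy the estimators are designed around.
"""

from mrkit import EstimatorConfig, SyntheticScenario, recovery_report
from mrkit.synthetic import Pleiotropy

clean = SyntheticScenario(n_snp=50, beta_causal=0.1)
dirty = SyntheticScenario(
    n_snp=50, beta_causal=0.1,
    pleiotropy=Pleiotropy("directional", mu=0.03, tau=0.005, frac=0.4))

cfg = EstimatorConfig(n_boot=50)
for label, scenario in (("no pleiotropy", clean),
                        ("40% directional pleiotropy", dirty)):
    rep = recovery_report(scenario, n_reps=100, seed=8,
                          methods=("ivw", "egger", "weighted_median"),
                          estimator_config=cfg)
    print(f"\n--- {label} (true effect 0.1, 100 replicates) ---")
    print(rep.to_string(float_format="%.4f"))

print("\nWith valid instruments all three are unbiased and IVW is the most "
      "efficient; under directional pleiotropy IVW absorbs the full bias, "
      "the weighted median about half, and Egger trades bias for variance.")
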