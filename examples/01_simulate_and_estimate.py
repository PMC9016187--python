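"""Simulate a study-sized two-sample MR dataset and estimate the effect.

Builds the 23-instrument case-control scenario (autoimmune exposure, rare
binary outcome scanned on the observed scale), pushes it through the full
filtering pipeline and prints the five causal estimates.
"""

import numpy as np

from mrkit import (AnalysisConfig, EstimatorConfig, build_instruments,
                   generate, paper_like_scenario, run_all_estimators)

TRUE_EFFECT = 2.5e-4  # log-odds per exposure unit

scenario = paper_like_scenario(beta_causal=TRUE_EFFECT, seed=17)
exposure, outcome, truth = generate(scenario)

config = AnalysisConfig(exposure_path="", outcome_path="", seed=17)
instruments, counts, log = build_instruments(exposure, outcome, config)

print("SNP counts by stage:", counts)
print(f"mean instrument F: {np.mean([i.f_stat for i in instruments]):.1f}")
analysis = run_all_estimators(instruments, EstimatorConfig(seed=17))
print(analysis.to_frame().to_string(index=False, float_format="%.6g"))
print(f"\ntrue OR: {np.exp(TRUE_EFFECT):.6f} — every estimator should "
      "bracket it; IVW is the most precise, the modes the least.")
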