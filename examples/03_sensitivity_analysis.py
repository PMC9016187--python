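"""Sensitivity diagnostics on a dataset with one planted outlier SNP.

Generates 20 instruments with a true effect of 0.1 and shifts one SNP's
outcome effect by 10 standard errors, then shows how each diagnostic
reacts: Cochran's Q inflates, MR-PRESSO names the culprit, and the
leave-one-out table pinpoints its influence.
"""

import json

from mrkit import (SyntheticScenario, generate, harmonize, run_sensitivity,
                   SensitivityConfig)

scenario = SyntheticScenario(n_snp=20, beta_causal=0.1,
                             outliers=((7, 10.0),), seed=5)
exposure, outcome, truth = generate(scenario)
instruments, _ = harmonize(exposure, outcome)

report = run_sensitivity(instruments, SensitivityConfig(k_sim=1000, seed=5))
print(json.dumps(report.to_json_dict(), indent=1))

planted = truth.snp_ids[7]
flagged = report.presso.outlier_ids
print(f"\nplanted outlier: {planted}; MR-PRESSO flagged: {flagged}")
print(f"corrected IVW after removal: "
      f"{report.presso.corrected_estimate.beta:.4f} (true effect 0.1)")
print("Q's small p-value reflects the heterogeneity the outlier injects; "
      "the leave-one-out stability flag shows whether any single SNP "
      "drives the pooled estimate.")
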