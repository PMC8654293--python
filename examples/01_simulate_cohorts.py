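"""Generate a paired exposure/outcome study with known ground truth.

The exposure cohort carries a protein driven by cis SNPs; the disjoint
outcome cohort carries disease labels caused by the protein's genetic value.
"""

import numpy as np

from cismr import SimulationConfig, generate_paired_study

cfg = SimulationConfig(seed=7, n_outcome=10_000, n_cases=1_000)
study = generate_paired_study(cfg)

print(f"exposure cohort: {len(study.exposure.sample_ids)} individuals, "
      f"{len(study.exposure.snp_ids)} SNPs")
print(f"outcome cohort:  {len(study.outcome.sample_ids)} individuals, "
      f"{study.case_status.sum()} cases "
      f"({study.case_status.mean():.1%} vs target "
      f"{cfg.n_cases / cfg.n_outcome:.1%})")
print(f"true causal effect: OR {np.exp(study.truth.true_b):.2f} per protein SD")
print(f"causal SNPs: {', '.join(study.truth.causal_snp_ids)}")
print(f"realized h2 (protein variance from cis SNPs): "
      f"{study.truth.realized_h2:.2f} (target {cfg.h2_target})")
# The two cohorts share SNPs and LD but no individuals — the two-sample
# design that makes instrument and outcome errors independent.
assert set(study.exposure.sample_ids).isdisjoint(study.outcome.sample_ids)
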