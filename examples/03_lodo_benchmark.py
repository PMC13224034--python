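"""Leave-one-domain-out comparison of alignment methods with paired tests.

Runs the LODO protocol for the non-adapted baseline and the adversarial
variant over several seeds on a synthetic three-cohort benchmark, then
compares them with the paired toolkit: median AUUC difference, bootstrap
95% CI, two-sided Wilcoxon signed-rank p, and Cliff's delta.  A CI that
spans zero and a negligible delta mean the adaptation gain is within
sampling noise.
"""

import numpy as np

from dauplift import (
    SyntheticSpec, TrainConfig, generate_cohorts, paired_comparison, run_lodo,
)

data, _ = generate_cohorts(SyntheticSpec(
    n_per_domain=(300, 300, 300), d=10, treatment_prob=0.5,
    effect_amplitude=1.5, missing_block_fraction=0.1, seed=1))

cfg = TrainConfig(epochs=25, patience=8)
seeds = [0, 1, 2, 3, 4]
noda = run_lodo(data, "noda", cfg, seeds=seeds)
dann = run_lodo(data, "dann", TrainConfig(method="dann", lambda_d=0.4,
                                          epochs=25, patience=8), seeds=seeds)

for name, res in [("NoDA", noda), ("DANN", dann)]:
    print(f"{name}: mean AUUC {res.mean_auuc:+.3f} +- {res.ci95_halfwidth:.3f} "
          f"(sd {res.sd:.3f}, n = {res.n_runs} seed x fold runs)")

a, b = dann.auuc_by_run(), noda.auuc_by_run()
keys = sorted(a)
comp = paired_comparison(np.array([a[k] for k in keys]),
                         np.array([b[k] for k in keys]), seed=0)
print(f"DANN - NoDA: median diff {comp.median_diff:+.3f}, "
      f"bootstrap 95% CI [{comp.boot_ci[0]:+.3f}, {comp.boot_ci[1]:+.3f}], "
      f"Wilcoxon p = {comp.wilcoxon_p:.3f}, Cliff's delta = {comp.cliffs_delta:+.3f}")
print("CI spanning zero -> no statistically robust adaptation gain here.")
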