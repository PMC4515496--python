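"""Severity-class separation on a small synthetic cohort.

Generates 3 phantoms per severity class at the reference class-mean
intensities, quantifies each, and prints the per-class HRI-diff statistics —
a miniature of the severity study the pipeline is built for.
"""

import numpy as np

from hriq import RunConfig, SOMConfig, analyze_image, generate_cohort
from hriq.phantom import REFERENCE_CLASS_MEANS

classes = list(REFERENCE_CLASS_MEANS)
cohort = generate_cohort(
    3, [REFERENCE_CLASS_MEANS[c] for c in classes],
    base_seed=0, noise_cv=0.1, labels=classes,
)

print(f"{'class':<10}{'true diff':>10}{'mean HRI':>10}{'sd':>7}  grades")
for cls in classes:
    subset = [p for p in cohort if p.label == cls]
    diffs, grades = [], []
    for ph in subset:
        report = analyze_image(ph.image, RunConfig(som=SOMConfig(seed=ph.spec.seed)))
        diffs.append(report.hri_diff)
        grades.append(report.severity)
    print(f"{cls:<10}{subset[0].true_hri_diff:>10.3f}"
          f"{np.mean(diffs):>10.3f}{np.std(diffs):>7.3f}  {grades}")
# Mean HRI-diff rises monotonically normal -> mild -> moderate, mirroring
# the increasing liver echogenicity that defines steatosis severity.
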