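"""Regional amyloid differences and hemispheric lateralization tests.

Reproduces the two statistical analyses that motivate the architecture on a
synthetic cohort with hub-concentrated topological asymmetry.
"""

import numpy as np

from rbfgcn import (
    SyntheticCohortConfig,
    generate_cohort,
    lateralization_report,
    regional_difference,
)

config = SyntheticCohortConfig(
    n_per_class=(60, 60, 60), m=148,
    lateralization_effect=1.5, lateralization_hubs=7, seed=3,
)
networks, _ = generate_cohort(config)
by_label = {lab: [n for n in networks if n.label == lab]
            for lab in ("NC", "MCI", "AD")}

# Region-specific amyloid burden: NC-vs-AD differences dominate
for a, b in (("NC", "AD"), ("MCI", "AD"), ("NC", "MCI")):
    diff = regional_difference(by_label[b], by_label[a]).values
    top = int(np.argmax(np.abs(diff)))
    print(f"{a} vs {b}: mean |diff| {np.abs(diff).mean():.3f}, "
          f"peak {diff[top]:+.3f} at region {top + 1}")

# Left/right pairing of homologous regions: amyloid + six graph measures
report = lateralization_report(networks, seed=0)
print(f"\namyloid left-right asymmetry: p = {report.amyloid_test.p_value:.2e}")
for name, test in report.measure_tests.items():
    flag = "*" if test.p_value < 0.05 else " "
    print(f"  {name:18s} W={test.statistic:9.1f}  p={test.p_value:.2e} {flag}")
print("(* = significant lateralization at 0.05; the difference matrix "
      f"A_l - A_r has max |entry| {np.abs(report.difference_matrix).max():.1f})")
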