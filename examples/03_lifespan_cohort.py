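"""Lifespan analysis on a synthetic age-structured cohort.

Generates a cohort in which the leading functional eigenvalue share grows
and structure-function liberality shrinks with age, then recovers those
trends with the functional-diversity and aligned/deviated-component
statistics, exactly the quantities correlated with age in lifespan studies.
"""

import numpy as np

import scfcmap as sm

truth = sm.SyntheticTruth(seed=31, planted_weights=np.eye(50)[0],
                          planted_spectrum=sm.default_spectrum(50),
                          noise_sd=0.3, age_slopes=(0.001, -0.006))
cohort = sm.gen_cohort(60, (4, 85), truth, seed=32, n_nodes=50)
subjects = [(s.subject_id, s.age, s.sc, s.fc) for s in cohort.subjects]
table = sm.cohort_table(subjects, l_a=10, l_d=10)

print(table.head(3).to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print()
assoc = sm.cohort_age_associations(table)
for _, row in assoc.iterrows():
    print(f"{row['metric']:>14} vs age: r = {row['r']:+.3f}, p = {row['p']:.2g}")
print()
print("the leading-mode share rises and both functional diversity and the")
print("liberality index fall with age; the deviated-component norm carries the")
print("decline while the aligned norm is preserved")

sweep = sm.sensitivity_sweep(subjects, window_sizes=(5, 10, 15))
print(f"\nliberality-age r across (l_a, l_d) windows: "
      f"{sweep['r'].min():.3f} to {sweep['r'].max():.3f} (sign is window-robust)")
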