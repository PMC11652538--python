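"""Early-warning detection on a simulated expression time course.

Generates a 200-gene study whose 20-gene DNB module destabilizes from
time point 10 of 16, calibrates the warning threshold from 30 null
subjects, and prints the ranking-score trace and the called signal.
"""

import numpy as np

from rankwarn import (SimulationConfig, compute_baseline, compute_threshold,
                      detect_warning, score_series, simulate_factor_study,
                      simulate_null_study)

# threshold: pool the ranking scores of null (asymptomatic-like) subjects
null_scores = []
for i in range(30):
    null = simulate_null_study(SimulationConfig(seed=1000 + i))
    base = compute_baseline(null.normal_matrix)
    null_scores.append(score_series(null.course, base, m=50).ranking_scores)
threshold = compute_threshold(np.concatenate(null_scores), alpha=0.05)
print(f"threshold theta = {threshold.theta:.4f} "
      f"(mean {threshold.mean_normal:.4f} + 1.645 x sd "
      f"{threshold.sd_normal:.4f} of {threshold.n_normal_scores} "
      "normal scores)")

# one subject with a planted transition at index 10
study = simulate_factor_study(SimulationConfig(seed=1))
baseline = compute_baseline(study.normal_matrix)
series = score_series(study.course, baseline, m=50, subject_id="subject01")

print("\n t   deltaS   above-threshold?")
for t, (label, ds) in enumerate(zip(series.time_labels,
                                    series.ranking_scores)):
    mark = " <-- warning" if ds > threshold.theta else ""
    print(f"{label:>3}  {ds:+.4f}{mark}")

call = detect_warning(series, threshold)
print(f"\nearliest signal at index {call.signal_index} "
      f"(true transition index: {study.truth_transition_index})")
print("the ranking score stays near zero while the system is stable and")
print("jumps as soon as the DNB module starts fluctuating coherently")
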