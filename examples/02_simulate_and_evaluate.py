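"""Simulate a cohort and replay the incremental accuracy study.

Generates 200 synthetic patients (log-normal true rates, dispersed birth
volumes, 3% multiplicative measurement noise), then presents each
estimator with the first k scans for k = 2..n and scores its rate against
the patient's all-scan 2-parameter reference fit.  Errors are mean
absolute deviations in percentage points per year, binned by k.
"""

from pkdgrowth import (
    SimConfig,
    assessments_to_frame,
    incremental_assessments,
    simulate_cohort,
    summarize,
)

patients = simulate_cohort(SimConfig(n_patients=200, seed=11))
cohort = [p.trajectory for p in patients]
rows = incremental_assessments(cohort)
print(f"{len(cohort)} patients -> {len(rows)} assessments (sum of n_i - 1)\n")

print(f"{'k':>3} {'n':>5} {'MIC':>6} {'avgMIC':>7} {'1-par':>6} {'2-par':>6} {'blend':>6}")
for cell in sorted(summarize(rows, "k_bins"), key=lambda c: int(c.group.rstrip("+"))):
    m = cell.mean_abs_error
    print(
        f"{cell.group:>3} {cell.n:>5} {m['mic_latest']:6.2f} {m['mic_average']:7.2f} "
        f"{m['lsf1']:6.2f} {m['lsf2']:6.2f} {m['blend_mic_lsf2']:6.2f}"
    )

df = assessments_to_frame(rows)
k2 = df[df.k == 2]
print(
    "\nWith only 2 scans the 2-parameter fit interpolates the noise "
    f"({k2['abs_error_pct_lsf2'].mean():.2f} vs MIC {k2['abs_error_pct_mic_latest'].mean():.2f} %/yr); "
    "from 4 scans on it clearly beats the single-scan MIC formula."
)
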