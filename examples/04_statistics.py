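"""The statistical toolkit on evaluation outputs.

Paired t-test for within-patient error reduction, Fisher's exact test for
a sex-by-alignment contingency table, the exact conditional Poisson rate
comparison, and Benjamini-Hochberg adjustment of a family of p-values.
"""

from pkdgrowth import (
    SimConfig,
    assessments_to_frame,
    benjamini_hochberg,
    fisher_exact_2x2,
    incremental_assessments,
    paired_t_test,
    poisson_exact_rate_test,
    simulate_cohort,
)

cohort = [p.trajectory for p in simulate_cohort(SimConfig(n_patients=150, seed=3))]
df = assessments_to_frame(incremental_assessments(cohort))

# does the 2-parameter fit reduce the error versus single-scan MIC at k=4?
k4 = df[df.k == 4]
t = paired_t_test(
    k4["abs_error_pct_mic_latest"].to_numpy(), k4["abs_error_pct_lsf2"].to_numpy()
)
print(
    f"k=4, MIC vs 2-parameter abs. error: t={t.statistic:.2f}, "
    f"p={t.p_value:.2e} (n={t.n[0]} patients)"
)

# a 2x2 association: males vs females in ideal vs substantial alignment
table = [[1, 6], [15, 7]]
f = fisher_exact_2x2(table)
print(f"Fisher exact on {table}: odds ratio {f.statistic:.3f}, p={f.p_value:.3f}")

# equal event rates given different exposures?
p = poisson_exact_rate_test(9, 22, 1, 7)
print(f"Poisson exact 9/22 vs 1/7 events per patient: p={p.p_value:.3f}")

raw = [t.p_value, f.p_value, p.p_value]
adj = benjamini_hochberg(raw)
print("BH-adjusted family:", [f"{a:.3g}" for a in adj])
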