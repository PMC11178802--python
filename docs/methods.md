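# Methods

## Growth model

Height-adjusted total kidney volume is modelled as a single exponential,
`httkv(t) = httkv0 · (1 + r)^t`, with `t` decimal age in years (days /
365.25 when derived from dates) and `r` the annual fractional growth
rate. Rates are fractions everywhere inside the package (0.036 = 3.6
%/yr); percent appears only in output CSVs (4 decimals) and evaluation
error columns. No logistic or biphasic alternatives are modelled.

The Mayo Imaging Classification inverts the model from one scan under the
assumption `httkv0 = 150 mL/m`. Class bands (1.5, 3, 4.5, 6 %/yr) and the
alignment thresholds (0.75, 1.5 %/yr) are definitional constants, so they
are compared with exact floating comparison, closed on the left; no
epsilon is applied.

## Estimators

All least-squares fitting is done in log-volume space by default: the
model is exactly linear there (`ln httkv = a + b·t`, `r = e^b − 1`),
closed forms exist for both the pinned-intercept fit
(`b = Σ tᵢyᵢ / Σ tᵢ²`, `yᵢ = ln(vᵢ/150)`) and the free fit (simple linear
regression), and multiplicative measurement error becomes additive.
`fit_space="linear"` instead minimises squared residuals in raw volume
space by Levenberg–Marquardt, initialised from the log-space solution;
both spaces agree exactly on noiseless data. Fits are unweighted — each
timepoint contributes once because per-sequence volumes are averaged
before fitting (below).

The averaging method averages per-scan *rates*, not class labels. The
MIC/2-parameter blend averages only the rate; its reported intercept is
the geometric mean of the component intercepts, a deliberate heuristic so
that the blend has a plottable trajectory at all.

Two scan ages closer than 1e−9 years (~0.03 s) are treated as one
timepoint; a design whose total age spread is below that tolerance raises
a degenerate-design error, and the method-selection rule then falls back
to the single-scan MIC with a logged warning instead of failing, so the
evaluation harness never drops assessments silently. `k` is 1-based and
chronological in user-facing APIs ("scan k" = the k-th earliest).

## Evaluation harness

For each patient the reference rate is the 2-parameter fit on all scans.
One assessment row is emitted per (patient, k) for k = 2..n; the k = n
row — where the 2-parameter fit coincides with the reference and scores a
structural zero error — is included by default so that the row count is
exactly Σ(nᵢ − 1), with an `exclude_terminal_assessment` switch for
sensitivity analyses (inclusion flatters the 2-parameter fit at high k).
Optional k = 1 rows carry the index-scan MIC alone. Absolute errors are
stored in %/yr. Summaries report the mean and *sample* standard deviation
(n − 1); groups are genotype pooled to PKD1/PKD2/Other, sex, follow-up
span at assessment time in bins [0,3), [3,5), [5,7), [7,9), [9,12),
[12,15), [15,∞) years (closed on the left so no span is double-counted),
and scan count with 10+ pooled. Patients with a degenerate reference fit
are excluded and logged, never imputed.

## Statistical toolkit

The numerical cores delegate to scipy (`ttest_rel`, `mannwhitneyu`,
`fisher_exact`, `binomtest`) and statsmodels (`fdr_bh`); the test suite
verifies them against independent exhaustive-enumeration oracles.
Conventions, where the field leaves a choice: two-sided p-values for the
exact tests use the minimum-likelihood rule (sum of outcomes no more
probable than the observed one); the Poisson comparison is the exact
conditional test, X₁ | (X₁+X₂) ~ Binomial(X₁+X₂, n₁/(n₁+n₂)) under equal
rates; Mann–Whitney switches from exact enumeration to the tie-corrected
continuity-corrected normal approximation when nₐ·n_b > 400 or ties are
present; Benjamini–Hochberg accepts an explicit `family` label vector so
each analysis block (one table, one subgroup panel) forms its own
multiplicity family.

## Synthetic cohort generator

The simulator reproduces the *structure* of a longitudinal ADPKD imaging
cohort, not any particular patient set. Per patient: age at first scan ~
Normal(42, 12²) truncated to [18, 70]; follow-up span ~ Uniform(8, 16)
years with rescans every Normal(2, 0.5²) years (floored at 0.25), the
schedule redrawn until it has ≥ 4 scans — mirroring typical inclusion
criteria (≥ 4 studies over ≥ 8 years); true rate r ~ log-normal with
median 3.6 %/yr and log-sd 0.45; true birth volume ~ log-normal with
median 150 mL/m and log-sd `sigma0` (default 0.5), the median shifted
×1.3 for males and ×1.3 for PKD2 carriers so covariates couple to MIC
misalignment; measurements carry multiplicative log-normal noise with
log-sd `noise_cv` (default 0.03). Sex (58% male), genotype (42% PKD1 /
30% PKD2 / 28% other, with truncating fractions 0.33 and 0.64) and
hypertension (81%) match typical published cohort fractions; the
distributional *families* and dispersions beyond those printed medians
and fractions are modelling choices, all overridable per field or via a
YAML mapping.

Randomness: one substream per patient keyed by `(seed, patient_index)`
via numpy's SeedSequence, so patient i is identical regardless of cohort
size and cohorts are bitwise reproducible.

What passing tests on this generator do **not** show about real data: a
log-normal rate distribution is strictly positive, whereas real cohorts
contain occasional shrinking kidneys; measurement error in practice has
scanner- and sequence-specific structure rather than being i.i.d.
multiplicative; scan schedules correlate with clinical status; and the
birth-volume dispersion (`sigma0`) is a mechanism knob, not an estimate —
so the simulated error *magnitudes* are not forecasts, only the ordering
and mechanism (MIC error driven by birth-volume misalignment, 2-parameter
error by noise amplification at short spans) are.

## Problem sizes and tolerances

The acceptance checks run on 500-patient cohorts (10 seed replicates for
the stochastic accuracy-ordering check, 2 000 draws per test for type-I
calibration), sizes at which the Monte-Carlo error of a cohort mean is a
few hundredths of a %/yr. Monotonicity of the 2-parameter fit's error in
k from 4 upward is asserted on the across-replicate mean with a 0.05 %/yr
slack per step, k ≥ 10 pooled. Noiseless recovery is asserted at 1e−9
relative; grid-search oracle agreement at the oracle's final grid spacing
(1e−5 in log space). Calibration null designs use sample sizes (30 pairs;
25 + 25; 2×200 binomial; Poisson(50) counts) where exact-test
discreteness is mild, since exact tests are conservative by construction
on tiny samples.

## Known limitations

Single-exponential growth only; no confidence intervals on fitted rates;
no mixed-effects pooling across patients; the sequence-discrepancy QC
threshold (CV > 0.10) is a configurable convention, not a validated cut;
eGFR, imaging appearance and cyst-level structure are out of scope.
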