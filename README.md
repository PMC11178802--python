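# pkdgrowth

Estimation and evaluation of the annual kidney-volume growth rate in
autosomal dominant polycystic kidney disease (ADPKD) from serial CT/MRI
measurements.

## The problem

Disease progression in typical ADPKD is staged by the Mayo Imaging
Classification (MIC), which assumes height-adjusted total kidney volume
(htTKV, mL/m) grows exponentially from 150 mL/m at birth:

```
htTKV(t) = htTKV_0 · (1 + r)^t
```

A single scan at age `t` then implies an annual fractional growth rate
`r = (htTKV / 150)^(1/t) − 1`, binned into classes 1A (< 1.5 %/yr), 1B
[1.5, 3), 1C [3, 4.5), 1D [4.5, 6) and 1E (≥ 6 %/yr); classes 1C–1E mark
rapid progressors for whom tolvaptan is typically considered. But real
patients do not all start at 150 mL/m, so when *several* scans are
available it is not obvious how to combine them. `pkdgrowth` implements
and compares the candidate estimators on the first `k` scans of a series:

| method | description | needs |
|---|---|---|
| `mic_latest` | MIC formula on scan `k` alone | 1 scan |
| `mic_average` | mean of the per-scan MIC rates of scans 1..k | 2 scans |
| `lsf1` | least squares of ln htTKV on age, intercept pinned at ln 150 | 2 scans |
| `lsf2` | ordinary least squares of ln htTKV on age, intercept free | 2 scans |
| `blend_mic_lsf2` | mean of the `mic_latest` and `lsf2` rates | 2 scans |

The long-follow-up reference ("ground truth") rate is `lsf2` on all
available scans. `recommend_rate` encodes the scan-count rule the
evaluation supports: MIC with 1–2 scans, the blend with exactly 3, the
2-parameter fit from 4 scans on.

The package also ships the incremental evaluation harness (present each
patient with 2, 3, … scans, score every method against the reference,
summarise absolute errors by genotype / sex / follow-up span / scan
count), index-scan alignment grouping (ideal < 0.75 %/yr, slight
[0.75, 1.5), substantial ≥ 1.5 %/yr), the statistical toolkit (paired t,
Mann–Whitney, Fisher exact, exact conditional Poisson rate test,
Benjamini–Hochberg), a seeded synthetic-cohort simulator, CSV I/O with
per-pulse-sequence volume averaging and QC, and a thin CLI.

## Worked example

`examples/01_single_patient_fits.py` fits a patient scanned four times
over nine years:

```
method           rate %/yr  httkv0 mL/m  Mayo
mic_latest           3.416        150.0    1C
mic_average          3.237        150.0    1C
lsf1                 3.256        150.0    1C
lsf2                 4.894         73.4    1D
blend_mic_lsf2       4.155        104.9    1C

recommended with 4 scans: lsf2 -> 4.894 %/yr (class 1D)
```

This patient's extrapolated birth volume (73 mL/m) is well below the
assumed 150, so the single-scan formula credits too much of today's
volume to the starting point and underestimates growth — enough to move
the patient across the 1C/1D rapid-progressor boundary. The other
examples simulate a cohort and reproduce the characteristic accuracy
pattern (`02`), group patients by MIC alignment and track Mayo-class
changes across scans (`03`), and exercise the statistical tests (`04`).
From a shell, the same pipeline is:

```bash
pkdgrowth simulate --n 50 --seed 7 --out-prefix cohort
pkdgrowth fit cohort_trajectories.csv --method auto --out fits.csv
pkdgrowth evaluate cohort_trajectories.csv --metadata cohort_metadata.csv
```

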