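# tremorflux

Temporal-fluctuation analysis of wearable-sensor tremor signals for
discriminating Parkinsonian (PD-like) from essential-tremor (ET-like)
patterns.

A 10-s tri-axial angular-rate recording (125 samples/s) is band-pass
filtered to the 3–10 Hz tremor band with a 10th-order Butterworth filter
(zero-phase, cascaded biquads), one axis is mapped to the two-delay
difference plane

```
f(n) = ( s(n + d1) − s(n),  s(n + d2) − s(n) ),    0 < d1 < d2
```

and the cloud is summarized by the area of its Gaussian 95% confidence
ellipse — the **temporal fluctuation** `TF = π · χ²₀.₉₅(2) · √det(Σ)`.
Comparing tasks gives the **fluctuation ratio**

```
RF = log10( 100 · TF_resting / TF_kinetic )
```

with a threshold-zero decision rule: `RF > 0 → PD`, `RF < 0 → ET`
(RF is zero exactly when the resting fluctuation is 1% of the kinetic
fluctuation, for any logarithm base). The package also provides the
Yule–Walker AR(7) peak-frequency characterization of ten equal
subsequences, cohort statistics (pooled-variance two-sample t-tests,
min/max separation margins, delay-unit sweeps) and confusion-matrix
metrics, plus a seeded synthetic cohort generator so the whole pipeline
is testable without patient data.

## Command-line usage

All tabular I/O is headered CSV. A cohort directory holds one file per
subject-task (`<subject>_<task>.csv`, columns `t,gx,gy,gz`) plus a
`labels.csv` manifest (`subject_id,label`).

```sh
# generate a 32 PD-like + 20 ET-like synthetic cohort
tremorflux simulate --n-pd 32 --n-et 20 --seed 1 --out cohort/

# per-subject fluctuation ratio and predicted label (x-axis, d1=5, d2=20)
tremorflux rf --data cohort/ --out rf.csv

# per-subject, per-task temporal fluctuation
tremorflux tf --data cohort/ --axis x --d1 5 --d2 20

# AR peak-frequency profiles (10 subsequence peaks + mean per recording)
tremorflux features --data cohort/

# delay-unit sweep: 8 lag pairs × 3 axes → p-values and separation margins
tremorflux sweep --data cohort/

# confusion metrics against the manifest labels
tremorflux evaluate --data cohort/

# band-pass a single recording
tremorflux filter cohort/pd001_kinetic.csv filtered.csv --low 3 --high 10
```

Filter (`--low/--high/--order/--zero-phase|--causal`), embedding
(`--d1/--d2/--axis`), ellipse (`--coverage`) and ratio (`--log-base`)
parameters are exposed on every relevant subcommand and logged to
standard error for auditability. Same inputs + same seed give
byte-identical outputs.

## Package layout

| module | contents |
| --- | --- |
| `tremorflux.recording` | `TremorRecording` data model, CSV read/write |
| `tremorflux.preprocessing` | `FilterSpec`, `bandpass`, `filter_recording` |
| `tremorflux.spectral` | subsequence partitioning, Yule–Walker AR PSD, peak frequencies |
| `tremorflux.fluctuation` | delay embedding, ellipse area (TF), RF, classification, cohort statistics |
| `tremorflux.synthetic` | seeded PD-like/ET-like cohort generator |
| `tremorflux.cli` | `tremorflux` console entry point |
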