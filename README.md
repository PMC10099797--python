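# hdomri

Quantitative deuterium (²H) brain-water MRI analysis: relaxometry of HDO
signals acquired during oral heavy-water (D₂O) loading, and the
enrichment accounting that goes with it.

After a person drinks D₂O to ~1.5% body-water enrichment (~100× the
0.015% natural abundance of deuterium), the HDO signal in the brain
becomes imageable at ultra-high field with multi-echo gradient-echo (MEGE)
sequences.  Quantifying it — per-tissue T1 and T2\* of HDO in CSF, grey
and white matter, and the time course of enrichment during loading — is
what this package does.  It is written for MR physicists and imaging
scientists building ²H/DMI protocols who need tested building blocks:
a forward signal model, voxel-wise map fitting, ROI summaries, dose
book-keeping, and protocol-precision simulation.

## Model

The spoiled gradient-echo signal at repetition time TR, echo time TE and
flip angle α is

```
S(TR, TE) = A · sin α · (1 − E₁) / (1 − cos α · E₁) · exp(−R2* · TE),   E₁ = exp(−R1 · TR)
```

Maps are estimated in two stages, as is standard when no separate B1 map
exists: (1) the echo-summed TR series is fitted per voxel to the
saturation-recovery factor for (A′, α, R1), and the flip-angle map is
smoothed over a 5×5×5 neighbourhood; (2) with α fixed, the full (TR, TE)
grid is fitted per voxel for (A, R1, R2\*) by bounded least squares.
Enrichment is quantified two ways that should agree: cumulative
D₂O dose over total body water (Watson equations), and HDO signal scaled
by the natural-abundance baseline.  See `docs/methods.md` for assumptions,
bounds, noise models and known limitations.

A synthetic digital brain phantom (nested-ellipsoid CSF/GM/WM geometry,
smooth B1 field, Rician noise at configurable SNR, programmed dose-uptake
curves) generates study-like data for every stage, so the whole pipeline
is testable offline.

## Worked example

How much would one extra long-TR measurement improve CSF T1 precision?

```
$ hdomri protocol simulate --tissue csf --reps 500 --seed 1 --add-tr 1500
{"tissue": "csf", "snr": 80.0, "n_reps": 500, "seed": 1,
 "T1_sd_ms": 101.92, "T1_sd_plain_ms": 451.99, "T1_bias_ms": -4.03,
 "scan_duration_s": 3446.8,
 "extended_T1_sd_ms": 46.82, "sd_ratio": 0.459,
 "extended_scan_duration_s": 5174.8}
```

Reading: under the 5-TR scheme (TR 68–816 ms, 8/4/2/1/1 averages, six
echoes, α = 60°), the Monte-Carlo robust SD of fitted CSF T1 (true value
510 ms) is ≈ 102 ms — the same scale as the between-visit spread seen in
vivo.  Appending a single TR = 1500 ms acquisition cuts it to ≈ 47 ms, an
SD ratio of 0.46: one long-TR sample roughly **halves** the CSF T1
uncertainty, at the cost of ~1700 s more encoding time.  The plain SD is
much larger than the robust SD because a few replicates are degenerate
(flat recovery within noise); both are reported.

The same tissue summary machinery reproduces the published group table
from per-visit values:

```python
>>> from hdomri import reference_data as ref, two_sample_ttest
>>> from hdomri.maps_roi import summarize_values
>>> summarize_values(ref.D2_T1_MS["CSF"], rounding="d2")
(510.0, 113.7, 6)                      # mean ms, sample SD, n visits
>>> two_sample_ttest(ref.D2_T1_MS["CSF"], ref.D2_T1_MS["GM"])
{'t': 3.715, 'df': 10.0, 'p': 0.0040}  # CSF T1 > GM T1, p < 0.007
```

CLI entry points: `hdomri phantom`, `fit-b1`, `fit-relax`, `roi`,
`loading dose-model`, `loading timecourse`, `protocol simulate`,
`run-all` (full pipeline from a YAML config).

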