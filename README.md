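# hiquant

Quantification tools for preclinical studies of neonatal hypoxic-ischemic
(H-I) brain injury and its treatment. The package turns the raw measurements
such a study produces — multi-echo T2-weighted MRI, extracellular evoked
field potentials from acute cortical slices, and qPCR Ct tables — into the
outcome measures the analysis needs: quantitative T2 maps, ischemic-core and
penumbra volumes, lost-tissue estimates, input-output (I-O) curve areas,
paired-pulse facilitation, and ΔΔCt fold changes. A synthetic-data module
generates MRI phantoms and fEPSP sweeps with known ground truth, so every
stage is testable (and demonstrable) without scanner or rig data.

It is written for imaging/electrophysiology scientists who want a scripted,
reproducible replacement for vendor or one-off analysis code. All tabular
outputs are tidy/long CSV, ready for external repeated-measures ANOVA.

## Methods in brief

**T2 relaxometry.** Each voxel of a multi-echo acquisition is fitted with the
mono-exponential decay *S*(TE) = *S*₀·exp(−TE/T2). The default estimator is
nonlinear least squares on the exponential, initialized from the log-linear
OLS solution (log-linear alone is biased under Rician magnitude noise). Fit
failures are data (`valid=False`), not exceptions.

**Hierarchical region split.** Within a manually outlined edema mask, the T2
histogram is smoothed, its two most prominent modes found, and the region is
split at the valley between them; the recursion continues until regions are
unimodal, too small, or too deep. A terminal region is labelled **ischemic
core** if the T2 at its histogram mode exceeds 56 ms, otherwise **penumbra**;
any voxel with T2 below 33 ms is relabelled uninjured. Both thresholds are
strict and configurable.

**Volumetrics.** Class volumes are voxel counts × voxel volume (mm³).
Lost tissue — atrophy not explained by core and penumbra — is the
hemisphere subtraction max(0, V_contra − V_ipsi) about a sagittal midline.

**Evoked potentials.** Sweeps are measured baseline-to-trough in fixed
latency windows after artifact blanking: volley burst (VB) 1–4 ms,
monosynaptic FP1 4–6 ms, polysynaptic FP2 (6, 10] ms. I-O curves over a
0–650 µA series are summarised by trapezoidal area (mV·µA); paired-pulse
facilitation is PPF = 100·(A₂ − A₁)/A₁ on FP1.

**Expression.** Fold change 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_housekeeping
referenced to the mean ΔCt of a control group; group summaries are geometric
means.

## Worked example

The demo simulates a complete two-group study (sham-treated vs low-frequency
TMS after H-I): multi-echo phantoms at two timepoints with a 30% core-volume
reduction imposed in the treated group at 48 h, border-site vs contralateral
I-O cohorts with 1.5× potentiation in the untreated group, paired pulses,
and a Ct table with a +1 cycle Gria2 shift in the injured groups.

```bash
hiquant demo --seed 1 --out demo_ws
```

prints (abridged):

```json
{
  "border_auc_ratio": {"lf_tms": 0.874, "sham_tms": 1.425},
  "core_reduction_lf_tms_48h_pct": 34.2,
  "gria2_fold_geomean": {"hi": 0.506, "hi_tms": 0.489, "sham": 1.0},
  "mean_core_volume_mm3": {
    "lf_tms":   {"24h": 1.094, "48h": 0.720},
    "sham_tms": {"24h": 1.094, "48h": 1.094}
  },
  "tms_protocol_pulses": 1200
}
```

Reading it: the segmentation recovers the treated group's smaller 48 h core
(0.72 vs 1.09 mm³; 34% instead of the nominal 30% reflects voxelization of
the shrunken ellipsoid), the border/contralateral AUC ratio shows the
potentiation in the untreated group (1.43) and its absence under treatment
(0.87, i.e. ≈1 within cohort noise), injured-group Gria2 folds sit at ≈0.5
for the +1 cycle shift, and a 1 Hz × 20 min stimulation protocol delivers
1200 pulses. The workspace holds every intermediate file (phantoms, label
volumes, `volumes.csv`, `summary.csv`, I-O curve tables, fold tables) plus a
provenance sidecar; re-running with the same seed reproduces it
bit-identically.

The same stages are available piecewise: `hiquant simulate phantom`,
`fit-t2`, `segment`, `volumes`, `hiquant ephys measure|io`, `ddct`, and
`hiquant run --config cohort.yaml` for a full cohort.

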