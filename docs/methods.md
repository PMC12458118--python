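# Methods notes

This note documents the models, conventions, numerical choices, and known
limitations behind each stage of the package, and what the synthetic-data
generators do and do not emulate.

## T2 relaxometry

Model: per-voxel mono-exponential transverse decay, S(TE) = S0·exp(−TE/T2),
with T2 in ms and S0 in arbitrary signal units. No noise-floor offset term
and no multi-compartment or stimulated-echo correction is included; the fit
is the plain exponential a vendor parametric-map tool produces.

Estimators:

* `loglinear` — OLS of ln S on TE. Exact on noiseless data; requires all
  intensities positive; biased low-signal behaviour under Rician noise.
* `nonlinear` (default) — least squares on the exponential. For fixed decay
  rate r = 1/T2 the amplitude is profiled out in closed form
  (S0 = Σ S·e / Σ e², e = exp(−r·TE)), reducing the problem to a 1-D
  minimization in r, solved by a vectorized golden-section search bracketed
  at [r₀/3, 3r₀] around the log-linear start r₀ and contracted 90 times
  (≈1e−19 relative, i.e. machine precision). On noiseless data the
  refinement converges back to the log-linear solution, so the two methods
  agree exactly there.

Validity: a voxel is `valid=False` (never an exception) when the log-linear
start is unavailable (non-positive intensity) or the decay-rate estimate is
non-positive (e.g. constant signal). R² is computed on the signal scale.
An `omit_first_echo` switch supports the common multi-echo practice of
dropping a contaminated first echo; all echoes are used by default.

## Hierarchical region split

The segmentation recursively splits the masked T2 map at histogram valleys.
The detector is specified exactly (so an independent re-implementation can
agree bit-for-bit):

* **Histogram.** Fixed-width bins (default 1 ms) centered on a grid anchored
  at the region minimum — the first bin's center *is* the minimum value.
  This makes a degenerate single-value region's mode equal that value
  exactly, which the strict 56 ms boundary semantics require; edge-anchored
  bins would bias every mode by half a bin width.
* **Smoothing.** Discrete Gaussian kernel (default bandwidth 2 ms, truncated
  at 4 bandwidths, normalized to unit sum), zero-padded sliding dot product.
  Raw counts are kept alongside; only they conserve mass.
* **Modes.** Plateau-aware local maxima; boundary bins are eligible
  (out-of-range neighbours count as −∞, plateaus contribute their middle
  bin). A mode qualifies if its side-scan prominence — height above the
  higher of the two walk-down bases, ignoring an empty side — is at least
  `bimodality_min_prominence` (default 0.05) of the smoothed maximum.
* **Valley.** The first (lowest-T2) global minimum of the smoothed counts
  strictly between the two most prominent modes; ties in prominence break
  by height then lower T2. Fewer than two qualifying modes ⇒ unimodal ⇒
  leaf.
* **Recursion.** Split {T2 ≤ valley} / {T2 > valley} (the valley bin's value
  goes to the lower child); stop on unimodality, a child smaller than
  `min_region_voxels` (default 30), or depth `max_depth` (default 6). The
  stopping knobs exist because a histogram of finite noisy data essentially
  always has micro-valleys; defaults were chosen so the published regime
  (two to three tissue populations 15–30 ms apart, ≥10² voxels each) always
  terminates at the intended granularity.
* **Classification.** Leaves only: mode > 56 ms ⇒ core, else penumbra;
  then a voxelwise override relabels any voxel with T2 < 33 ms as uninjured.
  Both inequalities are strict: mode exactly 56 ms is penumbra, T2 exactly
  33 ms keeps its leaf class. Intermediate (non-leaf) nodes are never
  classified.

The analysis domain is the manual edema outline intersected with valid fits;
the outline exists to keep skull-stripping errors and CSF out of the
histogram, so no further masking is attempted.

## Volumetrics

Volumes are exact voxel counts × voxel volume. Lost tissue is
max(0, V_contralateral − V_ipsilateral) about a single sagittal midline
plane; the clip prevents edema swelling from reading as negative loss, and a
`swelling` flag records when clipping happened. Inter-timepoint registration
is out of scope — the midline and masks are supplied per volume. If a label
volume is supplied, voxels holding a nonzero tissue class count as present
tissue even where the brain mask omits them, so a mask that excluded the
lesion cannot inflate the loss estimate.

## Evoked field potentials

Amplitude convention: baseline-to-trough of the negative deflection, clamped
at zero (zero = component absent), with `peak_to_peak` available as an
option. Baseline is the mean over the 5 ms before the stimulus; samples
within 0.5 ms after every stimulus are replaced by the baseline before any
measurement (truncated stimulus artifact). Windows: VB [1, 4] ms,
FP1 [4, 6] ms, FP2 (6, 10] ms post-stimulus — FP2's lower edge is open
(latency strictly over 6 ms). Latency is the trough time; it is NaN when
the amplitude clamps to zero.

I-O curve areas use trapezoidal quadrature over the recorded current range:
with 14 points and a plateauing curve, anything fancier adds assumptions
without information. PPF uses the FP1 (monosynaptic) amplitudes; the
component choice is switchable. The border-vs-contralateral contrast reports
per-side mean AUC and their ratio — the descriptive statistic a downstream
ANOVA consumes; the ANOVA itself is out of scope.

## Synthetic data

**Phantom.** Two mirror-image ellipsoidal hemispheres; an ellipsoidal core
inside a concentric penumbra shell in the ipsilateral hemisphere; per-voxel
T2 drawn once per voxel from class-specific Gaussians truncated at 1 ms
(defaults 30/45/70 ms ± 1.5/2.5/3.0 ms for uninjured/penumbra/core, matching
the <33 ms uninjured and >56 ms core conventions); mono-exponential signals
at TE = 10…100 ms (10 echoes); Rician noise sqrt((S+n₁)² + n₂²) with
independent Gaussian channels, default σ = 2% of S0 (SNR 50) — the standard
model for magnitude reconstructions. Voxels are 0.12×0.12×0.5 mm. Atrophy
is emulated by deleting a posterior wedge of ipsilateral voxels — the
simplest geometry for which the hemisphere-subtraction contract is exact.
Not emulated: real anatomy, partial-volume effects, B0/B1 artifacts,
multi-compartment T2, inter-timepoint motion.

**fEPSP sweeps.** Components are negative Gaussian pulses truncated at
3 widths. Compact support is deliberate: tails cannot contaminate the
pre-stimulus baseline or a neighbouring window, so noiseless measurements
recover generator parameters exactly (the price is a ~1% amplitude
discontinuity at the support edge, irrelevant to trough measures).
Amplitudes follow amp(I) = amp_max/(1 + exp(−k·(I − I₅₀))) with defaults
I₅₀ = 200 µA, k = 0.015/µA — near zero at 0 µA and plateauing below 650 µA.
Absolute amplitudes (1.0/0.6/0.3 mV for FP1/FP2/VB) and the sigmoid
parameters are free simulator choices; no published values exist for them.
`potentiation_factor` scales FP1/FP2 saturation (post-hypoxic LTP),
`facilitation_factor` scales the second response of a pair, `cnqx` zeroes
FP1/FP2 only, `ttx` zeroes VB too. Each series additionally draws one
lognormal slice-responsiveness factor (CV 0.12, unit mean, applied to all
components): slice preparations genuinely vary, and a cohort without
between-slice variability would make confidence intervals on cohort
statistics degenerate. Recording noise (default 0.02 mV) is added last.
Because amplitudes are measured as window minima, noise inflates near-zero
amplitudes by roughly its extreme-value statistic; at the default settings
this biases cohort AUC ratios by ~1–2%, well inside slice-to-slice spread.

**Ct tables.** Housekeeping Ct ≈ 18 cycles plus a per-sample loading offset
(SD 0.4, fold-neutral by construction), target Ct offset by a base ΔCt of 5
plus the group shift, independent technical noise (SD 0.15) per well.

What passing tests show — and do not. Recovery tests prove the estimators
invert the stated forward models at realistic noise; they cannot certify
behaviour under artifacts the generators omit (motion, susceptibility,
electrode drift, amplification-efficiency differences in qPCR).

## Reproducibility and problem sizes

One integer seed drives every stochastic stage; derived child seeds stay
below 2³¹. Demo and pipeline outputs are bit-identical across runs
(uncompressed NIfTI, deterministic CSV/JSON serialization; configs store
workspace-relative paths so provenance hashes are location-independent).
Default problem sizes — 64×64×12 phantom grids, 20-phantom recovery
cohorts, 2 000-replicate noise studies, 8 slices per side in ephys cohorts —
were chosen to put Monte-Carlo error well below the tolerances being
checked while keeping any single check in the seconds-to-a-minute range.

## Known limitations

* The region-split stopping rule (prominence + region size + depth) is one
  reasonable formalisation of "split at the valley between the two modes";
  other detectors would move boundaries by at most the smoothing scale.
* Whether historical implementations classified only terminal leaves, and
  whether the 56 ms rule applied during or after recursion, is not
  determinable; this package classifies leaves after full recursion.
* Lost-tissue estimation assumes an intact contralateral hemisphere and a
  vertical midline; head tilt must be corrected upstream.
* ΔΔCt assumes equal amplification efficiency of target and housekeeping
  genes (no Pfaffl correction).
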