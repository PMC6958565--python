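# Methods

This note documents the models, conventions and numerical choices
behind `cranioflow`, and what the synthetic validation does and does
not demonstrate about real PC-MRI data.

## Forward model: cardiac-gated velocity cines

A scene is a set of non-overlapping circular lumens on a 128×256 image
(0.55 mm pixels, 5 mm slice), each carrying a periodic volumetric flow
waveform sampled at 32 uniform time points per cardiac cycle. Lumen
pixels hold the uniform velocity `flow / rasterized_area` (cm/s),
signed by the flow direction; the conversion is 1 cm/s × 1 mm² =
0.6 ml/min. Rasterization is pixel-center-in-circle; an optional
partial-volume mode averages lumen and background signal in the
one-pixel boundary ring (off by default, matching protocols designed
to avoid partial-volume effects). Stored velocities are wrapped into
(−venc, +venc] exactly as phase encoding wraps them; default venc is
80 cm/s for blood planes, 10 cm/s at the aqueduct and 5 cm/s at C2–C3.

Noise is additive Gaussian on velocity, everywhere in the image —
a proxy for phase noise, applied before wrapping. Defaults: 0.5 cm/s
(blood planes), 0.1 (aqueduct), 0.05 (C2–C3). These correspond to
high-but-plausible magnitude SNR at 3 T and were chosen once so that
the weakest configured flow signals (near-static venous flow, small
CSF oscillations) remain above the segmentation detection floors; the
repeatability experiment (below) measures what they imply for flow
precision. Magnitude images are schematic (bright lumens on a dim
background) and are not used by the processing chain.

Sign convention: cranio-caudal flow is positive everywhere. Arteries
carry `direction_sign = −1` (caudo-cranial inflow), veins and systolic
CSF flush +1; the sign is applied when averaging, so all downstream
flow curves are positive along their physiological direction and
composite sums need no per-vessel bookkeeping.

### Waveforms

Two families are implemented. The **sinusoid** gives closed-form
oracles: a sampled sinusoid with mean M and amplitude A has PI exactly
2A/M, and a zero-mean sinusoid of amplitude a (ml/s) has CSF stroke
volume aT/π. The **gamma-variate pulse** (`(u/tp)^k e^{k(1−u/tp)}`
over a flat diastolic baseline, peak position and exponent
configurable) models arterial systole. In both families the sampled
pulse is de-meaned before the baseline is added, so the cycle mean of
the samples equals the specified mean flow exactly, and the amplitude
is re-normalized so the sampled peak deviation equals the specified
amplitude.

### Cohort generation

Per-subject composite metrics — four mean flows, four pulsatility
indices, two blood stroke volumes, two CSF stroke volumes, heart
rate — are drawn from group-level normal distributions (defaults in
`cohort_defaults.py`: normative young/elderly means and SDs). Draws are
bounded below by the lowest normative observed value per metric
(flows, CSF stroke volumes) and heart rate is gated to 45–100 bpm;
out-of-bound draws are redrawn (hard cap 100). The bounds matter:
unbounded normals occasionally produce flows with velocities below any
detection limit, which no healthy cohort contains.

Each drawn subject is realized as four plane scenes. Composite flows
are split over vessels by fixed fractions (ICAs 72% / VAs 28%
extracranially; ICAs 76% / BA 24% intracranially; jugulars 55/45;
sagittal/straight sinus 70/30) with fixed lumen areas. Blood waveforms
are gamma pulses; the arterial and venous pulse amplitudes are pinned
by the range-based PIs (amplitude = PI × mean / sampled-range-factor),
which leaves two degrees of freedom to hit the drawn blood stroke
volume: the **venous lag** and the **pulse width**. For any one shape,
the attainable stroke volume is an interval in the lag (at zero lag the
α-scaled venous pulse maximally cancels the arterial pulse); a
narrow-to-broad shape menu is scanned for the first shape whose
interval contains the target and the lag is then solved by bisection
*on the same discrete forward model the rasterizer uses*, so realized
and target stroke volumes agree to solver precision. This mirrors real
between-subject waveform variability; a single fixed shape —
in particular a pure sinusoid — rigidly couples PI and stroke volume
and cannot realize the normative combinations. CSF waveforms are
zero-mean sinusoids with amplitude 60π·SV/T (ml/min) and fixed small
lags relative to arterial systole.

Ground-truth metrics are computed from the noise-free waveform samples
with the same quantification operators as the pipeline, so
pipeline-vs-truth comparisons isolate imaging and segmentation effects
from temporal discretization.

## Velocity processing

**Aliasing.** A pixel-frame is flagged aliased when its velocity sign
opposes the ROI's flow direction *and* its magnitude exceeds
0.75·venc (threshold configurable; the sign rule alone would flag slow
counter-flowing noise). The correction is
`(2·venc − |v|) × (−|v|/v)` — the exact inverse of a single wrap, valid
for true speeds in (venc, 2·venc). An acquisition is marked for
rejection (repeat with doubled venc) when more than half of the ROI is
flagged in any frame; the rule is strict (exactly 50% is accepted).
Zero velocities are undefined under the formula and left unchanged.

**Segmentation.** A deterministic region-growing stand-in for
semi-automated lumen delineation. From a seed pixel, 4-connected
neighbours are admitted on either of two flow signatures:

* *oscillatory* (CSF-like): Pearson correlation ≥ 0.7 between the
  pixel's velocity waveform and the running ROI-mean waveform, with
  temporal SD above a pulsatility floor (1.5 × the image-wide median
  temporal SD, a robust background-noise estimate);
* *sustained* (blood-like): absolute temporal-mean velocity above
  5 background standard errors (σ̂/√n_frames).

Growth proceeds in rounds (all qualifying frontier pixels admitted
together, previously rejected neighbours retried against the updated
mean) to a fixed point. The dual criterion is deliberate: venous flow
in elderly subjects can be nearly pulseless (PI ≈ 0.03–0.1), so no
pulsatility-only rule can segment it at realistic SNR, while static
background cannot exhibit a sustained through-plane mean. The
correlation path keeps anti-phase or independently oscillating
neighbours apart; the sustained path would merge *touching* same-sign
lumens, which the scene layouts (and anatomy, at these plane
prescriptions) avoid. Thresholds are configuration, not constants.

**Averaging.** The ROI flow curve is the per-frame arithmetic mean of
`direction_sign × velocity` times the ROI area (pixel count × pixel
area) — linear in the data, so noise averages down as 1/√n_pixels.

## Quantification conventions

* All cycle integrals use the trapezoidal rule with periodic closure
  (sample 32 wraps to sample 1), which on a uniform grid equals
  dt × Σq.
* Blood stroke volume = range of the cyclically integrated
  arteriovenous volume curve V(t). A warning is raised if the input is
  unbalanced (|cycle mean| > 1% of peak); α-corrected input is balanced
  by construction.
* CSF stroke volume = mean of the two directional lobe areas of the
  signed curve; unidirectional input is computed but flagged.
* PI uses the raw 32-sample extrema — no interpolation or smoothing, so
  results are exactly reproducible. Consequence: on noisy data the
  range carries a small positive bias (extreme-value statistics), worth
  a few percent of PI at default noise for weakly pulsatile composite
  curves; mean-based metrics are unbiased.
* One PI per arterial tree and one per venous tree, computed on the
  composite curves (pooled-tree convention); no per-vessel PIs are
  reported.
* α is computed per subject; group-level α is the mean of per-subject
  ratios, which differs from the ratio of group-mean flows (for the
  normative young values, 716/449 = 1.59 versus a per-subject mean of
  1.67) — the report works with per-subject values throughout.
* "ml/cc" in reports reads milliliters per cardiac cycle.

## Statistics

Per metric and group, values strictly outside
[mean − 1.5·IQR, mean + 1.5·IQR] are excluded in a single pass
(quartiles by linear interpolation). The mean-centred interval is the
documented convention here; it is nonstandard — a gross outlier drags
the centre and can exclude inlying values — and a Tukey median-centred
variant is available as a config switch (off by default). Exclusion is
per-metric, not listwise.

Two-sample comparisons are gated by Shapiro–Wilk at 0.05 on each
sample: both normal → Student t (paired or independent); otherwise
Wilcoxon signed-rank / Mann–Whitney U; all two-sided, significance at
0.05, no multiple-testing correction (each p stands alone and the
report footer says so). Degenerate cases: constant samples count as
non-normal; identical paired samples return p = 1. Pearson correlations
are classified by |r|: [0.30, 0.50) weak, [0.50, 0.70) moderate,
[0.70, 0.90) strong, ≥ 0.90 very strong.

## Validation design and problem sizes

The acceptance layer runs, at sizes chosen to keep the default test
run to a few minutes: worked flow ratios on noise-free group-mean
subjects (full imaging pipeline, one subject per group); exact
aliasing round-trip on a 10⁴-velocity grid; arteriovenous conservation
over 100 seeded subjects; closed-form PI and CSF-SV identities;
repeatability over 20 noise realizations of one vessel scene
(normalized SD ≈ 0.03%, far below the 5% bound, because ~90 lumen
pixels × 32 frames average the velocity noise down); and a 16+19
cohort recovery study over 20 seeded replicates — group means within
2 SE of the configured parameters, and the expected young-vs-elderly
significance pattern (lower arterial inflow and intracranial venous
outflow, higher intracranial blood SV, spinal CSF SV and all
pulsatility indices in the elderly) reproduced in ≥ 90% of
(comparison, replicate) pairs. The aggregate criterion is the right
one at these effect sizes: the spinal CSF SV effect (d ≈ 0.8 at
n = 16/19) has ~70% per-replicate power, so demanding every comparison
in ≥ 90% of replicates would fail for any correct implementation.

## What passing does and does not show

The generator validates the *processing chain*, not the physics: it
emulates uniform in-plane lumen velocity (no laminar profile), additive
Gaussian velocity noise (no eddy-current or Maxwell-term phase offsets,
no baseline drift), stationary circular lumens (no vessel wall motion,
compliance or through-plane motion), perfect gating, and waveforms from
a two-family parametric menu. Segmentation results on real data depend
on properties (signal inhomogeneity, neighbouring tissue motion,
partial-volume fat/CSF) that the phantom does not contain; the
semi-automated algorithm it stands in for is not reproduced, only its
contract. Aliasing correction assumes single wrapping (|v| < 2·venc).
Cohort draws treat metrics as independent normals apart from the
realizability constraints, so cross-metric correlations in real cohorts
(e.g. flow–PI coupling) are not emulated beyond what the waveform
construction imposes.

## Known limitations

* Background phase-offset correction is out of scope; stored stacks are
  assumed velocity-calibrated (a reader option converts integer phase
  via v = venc·phase/π).
* PI-vs-SV realizability clips extreme draws (a per-subject stroke
  volume outside the attainable interval for every shape in the menu is
  realized at the nearest attainable value); at the normative
  parameters this affects a small tail of subjects and shifts group
  means by ≪ 1 SE.
* The outlier rule follows the documented mean-centred convention even
  where it behaves pathologically on adversarial data; use the median
  variant for robustness.
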