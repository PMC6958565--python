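# cranioflow

Cerebral blood and CSF flows interact inside the rigid skull: every
cardiac cycle, pulsatile arterial inflow displaces venous blood and
cerebrospinal fluid, and the balance of these flows shifts with aging
and in disorders such as hydrocephalus. Cine phase-contrast MRI
(PC-MRI) measures these flows non-invasively: cardiac-gated velocity
images are acquired perpendicular to the vessels (and to the aqueduct
and the C2–C3 subarachnoid space), and each region of interest is
reduced to a 32-sample volumetric flow waveform over one cardiac cycle.

`cranioflow` is a Python library for this analysis chain, aimed at
researchers who want to prototype or validate PC-MRI flow processing
without scanner data. It provides:

* a **synthetic cine generator** — pulsatile vessel/CSF cross-sections
  rasterized into velocity + magnitude stacks with velocity aliasing,
  Gaussian velocity noise and full ground truth, including a two-group
  (young/elderly) cohort generator parameterized by normative values;
* **velocity processing** — aliasing detection and exact unwrap
  correction, and deterministic region-growing lumen segmentation based
  on flow signatures (waveform correlation for oscillatory CSF,
  sustained mean velocity for blood);
* **flow quantification** — flow curves (mean velocity × ROI area),
  composite flows, the α venous correction, arteriovenous flow, blood
  and CSF stroke volumes, pulsatility indices;
* **cohort statistics** — outlier screening, Shapiro-gated parametric /
  nonparametric two-group and paired comparisons, Pearson correlation
  with strength classification, and a summary report;
* a thin **CLI** (`cranioflow simulate | quantify | analyze | run`) plus
  narrative scripts in `examples/`.

## The quantities computed

With composite arterial inflow ACBF(t) (sum of both internal carotids
and either both vertebral arteries, extracranially, or the basilar
artery, intracranially) and measured venous outflow VCBF(t) (jugular
veins, or sagittal + straight sinus):

* **α venous correction**: α = mean(ACBF) / mean(VCBF); the theoretical
  venous flow α·VCBF(t) balances arterial inflow, accounting for
  unmeasured peripheral drainage.
* **Arteriovenous flow**: AV(t) = ACBF(t) − α·VCBF(t); its cyclic
  trapezoidal integral V(t) is the intracranial blood volume shift and
  the **blood stroke volume** is max V − min V (ml per cardiac cycle).
* **CSF stroke volume**: mean of the two directional lobe areas of the
  oscillatory CSF flow curve.
* **Pulsatility index**: PI = (max − min) / mean of the raw 32-sample
  flow curve.

## Worked example

```python
from cranioflow.pipeline import RunConfig, quantify_scene
from cranioflow.synthetic import make_cohort

scenes, truth = make_cohort(n_young=1, n_elderly=1, seed=42)
metrics, _ = quantify_scene(scenes[0], RunConfig())
print(f"ExtraACBF {metrics.extra_acbf:.0f} ml/min  (truth {truth.iloc[0].extra_acbf:.0f})")
print(f"alpha_extra {metrics.alpha_extra:.2f}   spinal CSF SV {metrics.spinal_csf_sv:.2f} ml")
```

prints

```
ExtraACBF 755 ml/min  (truth 755)
alpha_extra 1.30   spinal CSF SV 0.37 ml
```

i.e. the pipeline re-measures this subject's arterial inflow to within
a fraction of a percent of the generated truth; α = 1.30 means the
jugular veins carry 1/1.30 ≈ 77% of the arterial inflow, and 0.37 ml of
CSF oscillates through the cervical canal each beat. The scripts in
`examples/` walk through each capability (scene simulation, aliasing
correction, subject quantification, a cohort study, repeatability) and
print commented output.

End-to-end from a shell:

```bash
cranioflow run --out results/demo --seed 7
```

writes `metrics.csv`, per-curve CSVs, a markdown cohort report, the
aliasing/outlier logs and the resolved YAML config.

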