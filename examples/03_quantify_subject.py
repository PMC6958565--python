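"""Quantify one synthetic subject end to end and compare with ground truth.

The subject's four planes (extracranial and intracranial vessels,
aqueduct, C2-C3) are simulated at the default noise level, segmented
from the vessel seeds, and reduced to the full metric set: composite
mean flows, alpha venous-correction factors, blood and CSF stroke
volumes, pulsatility indices.
"""

from cranioflow.pipeline import RunConfig, quantify_scene
from cranioflow.synthetic import make_cohort

scenes, truth = make_cohort(n_young=1, n_elderly=1, seed=42)
scene = scenes[0]  # a young subject
metrics, _ = quantify_scene(scene, RunConfig())

print(f"subject {scene.subject_id} (heart rate {metrics.heart_rate:.0f} bpm)")
print(f"{'metric':<20}{'measured':>10}{'truth':>10}")
for name, value in metrics.as_dict().items():
    print(f"{name:<20}{value:>10.3f}{truth.iloc[0][name]:>10.3f}")
# Measured values track ground truth to ~1% for flows and ~2-5% for the
# extrema-based pulsatility indices; alpha balances arterial inflow
# against measured venous drainage (alpha > 1 means unmeasured
# peripheral veins carry part of the outflow).
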