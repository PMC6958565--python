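"""Benchmark computations on synthetic study conditions.

Self-contained evaluation runs used by the test suite and the
reproduction script: quantification of noise-free "group-mean" subjects
(one subject per group, every parameter fixed at its normative mean)
and the measurement-repeatability experiment (normalized SD of the mean
flow estimate across independent noise realizations of one vessel
scene, with segmentation rerun each time).
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .cohort_defaults import NORMATIVE_GROUPS
from .pipeline import RunConfig, quantify_scene
from .quantify import SubjectMetrics, flow_curve
from .synthetic import (
    AcquisitionSpec,
    VesselSpec,
    make_cohort,
    rasterize_cine,
)
from .velocity import dealias_stack, mean_velocity_curve, segment_roi
from .waveforms import WaveformSpec

__all__ = ["group_mean_subject_metrics", "worked_ratios", "flow_repeatability"]

_ALL_PLANES = ("extracranial_vessels", "intracranial_vessels", "aqueduct", "c2c3")


def group_mean_subject_metrics(seed: int = 0) -> Dict[str, SubjectMetrics]:
    """Quantify one noise-free subject per group fixed at the normative
    group means (zero between-subject variance).

    The full imaging pipeline runs: waveform synthesis, cine
    rasterization, segmentation and flow quantification; the returned
    metrics are measured, not copied from the configuration.
    """
    params = {g: {k: (mu, 0.0) for k, (mu, _) in NORMATIVE_GROUPS[g].items()}
              for g in NORMATIVE_GROUPS}
    scenes, _ = make_cohort(1, 1, seed=seed, group_params=params,
                            noise={p: 0.0 for p in _ALL_PLANES})
    cfg = RunConfig(group_params=params, seed=seed)
    out: Dict[str, SubjectMetrics] = {}
    for scene in scenes:
        metrics, _ = quantify_scene(scene, cfg)
        out[scene.group] = metrics
    return out


def worked_ratios(seed: int = 0) -> Dict[str, float]:
    """Percentage flow ratios of the normative group-mean subjects.

    Computed from pipeline-measured metrics: the aqueductal/spinal CSF
    stroke-volume ratio per group, the sinus (IntraVCBF/IntraACBF) and
    jugular (ExtraVCBF/ExtraACBF) drainage fractions per group, and the
    elderly sinus-vs-jugular flow deficit.
    """
    m = group_mean_subject_metrics(seed)
    young, old = m["HYV"], m["HEV"]
    return {
        "aqueductal_over_spinal_sv_young_pct":
            100.0 * young.aqueductal_csf_sv / young.spinal_csf_sv,
        "aqueductal_over_spinal_sv_elderly_pct":
            100.0 * old.aqueductal_csf_sv / old.spinal_csf_sv,
        "sinus_drainage_fraction_young_pct":
            100.0 * young.intra_vcbf / young.intra_acbf,
        "sinus_drainage_fraction_elderly_pct":
            100.0 * old.intra_vcbf / old.intra_acbf,
        "jugular_drainage_fraction_young_pct":
            100.0 * young.extra_vcbf / young.extra_acbf,
        "jugular_drainage_fraction_elderly_pct":
            100.0 * old.extra_vcbf / old.extra_acbf,
        "elderly_sinus_vs_jugular_deficit_pct":
            100.0 * (old.extra_vcbf - old.intra_vcbf) / old.extra_vcbf,
    }


def flow_repeatability(
    n_realizations: int = 20,
    seed: int = 0,
    mean_flow: float = 600.0,
    pulse_amplitude: float = 255.0,
    noise_sigma: float = 0.5,
) -> Tuple[float, np.ndarray]:
    """Normalized SD (%) of the mean-flow estimate across independent
    noise realizations of one default vessel scene.

    A sinusoidal artery (mean 600 ml/min, venc 80 cm/s, default
    geometry and noise) is re-imaged ``n_realizations`` times with fresh
    noise; segmentation and quantification are rerun on each
    realization.  Returns (100 * SD / mean of the estimates, estimates).
    """
    rng = np.random.default_rng(seed)
    noise_seeds = rng.integers(0, 2 ** 31 - 1, size=n_realizations)
    vessel = VesselSpec("ICA_L", (64, 128), 28.0, -1,
                        WaveformSpec(mean_flow, pulse_amplitude))
    estimates = []
    for s in noise_seeds:
        acq = AcquisitionSpec(venc=80.0, noise_sigma=noise_sigma, seed=int(s))
        stack, _ = rasterize_cine([vessel], acq)
        clean = dealias_stack(stack, vessel.direction_sign)
        roi = segment_roi(clean, vessel.center, direction_sign=vessel.direction_sign)
        curve, area = mean_velocity_curve(clean, roi)
        estimates.append(flow_curve(curve, area, acq.cardiac_period).mean())
    estimates = np.asarray(estimates)
    nsd = 100.0 * estimates.std(ddof=1) / estimates.mean()
    return float(nsd), estimates
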