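"""Derived hydro-hemodynamic quantities from per-ROI velocity curves.

Implements the quantification chain used in cerebral PC-MRI studies:
flow-curve reconstruction (mean velocity × ROI area), composite arterial
and venous cerebral blood flows, the alpha venous-correction factor that
balances measured venous drainage against arterial inflow, arteriovenous
flow and its cyclic integral (the blood stroke volume), oscillatory CSF
stroke volumes, and the pulsatility index PI = (max − min) / mean.

Units: velocity cm/s, area mm², flow ml/min, stroke volume ml per
cardiac cycle, period s.  All cycle integrals use the trapezoidal rule
with periodic closure (the last sample wraps to the first), which on a
uniform grid equals dt times the sample sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "FlowCurve",
    "SubjectMetrics",
    "flow_curve",
    "compose_flows",
    "alpha_correction",
    "arteriovenous_flow",
    "blood_stroke_volume",
    "csf_stroke_volume",
    "pulsatility_index",
    "subject_metrics",
    "metrics_from_truth_curves",
    "COMPOSITE_VESSELS",
]

#: 1 cm/s across 1 mm² = 0.01 ml/s = 0.6 ml/min
FLOW_ML_MIN_PER_CMS_MM2 = 0.6

#: vessels entering each composite flow
COMPOSITE_VESSELS = {
    ("extra", "arterial"): ("ICA_L", "ICA_R", "VA_L", "VA_R"),
    ("intra", "arterial"): ("ICA_L", "ICA_R", "BA"),
    ("extra", "venous"): ("IJV_L", "IJV_R"),
    ("intra", "venous"): ("SSS", "StrS"),
}


@dataclass
class FlowCurve:
    """A volumetric flow waveform (ml/min) over one cardiac cycle."""

    samples: np.ndarray
    cardiac_period: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("flow samples must be finite")
        if self.cardiac_period <= 0:
            raise ValueError("cardiac_period must be > 0")

    @property
    def n(self) -> int:
        return len(self.samples)

    def mean(self) -> float:
        return float(self.samples.mean())


def flow_curve(mean_velocity: np.ndarray, area: float, cardiac_period: float,
               label: str = "") -> FlowCurve:
    """Reconstruct a flow curve as mean velocity × ROI area.

    ``mean_velocity`` in cm/s, ``area`` in mm²; the result is in ml/min.
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    samples = np.asarray(mean_velocity, dtype=float) * area * FLOW_ML_MIN_PER_CMS_MM2
    return FlowCurve(samples=samples, cardiac_period=cardiac_period, label=label)


def _check_compatible(a: FlowCurve, b: FlowCurve) -> None:
    if a.n != b.n:
        raise ValueError(f"sample counts differ: {a.n} vs {b.n}")
    if not np.isclose(a.cardiac_period, b.cardiac_period):
        raise ValueError("cardiac periods differ")


def compose_flows(curves: Mapping[str, FlowCurve], level: str) -> Tuple[FlowCurve, FlowCurve]:
    """Sum per-vessel curves into the arterial and measured venous
    composites for one level (``"extra"`` or ``"intra"``).

    Extracranial: ACBF = both ICAs + both VAs, VCBF = both IJVs.
    Intracranial: ACBF = both ICAs + BA, VCBF = SSS + straight sinus.
    """
    if level not in ("extra", "intra"):
        raise ValueError("level must be 'extra' or 'intra'")
    out = []
    for side in ("arterial", "venous"):
        needed = COMPOSITE_VESSELS[(level, side)]
        for vessel in needed:
            if vessel not in curves:
                raise ValueError(f"missing vessel {vessel} for {level} {side} composite")
        first = curves[needed[0]]
        total = np.zeros(first.n)
        for vessel in needed:
            _check_compatible(first, curves[vessel])
            total = total + curves[vessel].samples
        out.append(FlowCurve(total, first.cardiac_period, label=f"{level}_{side}"))
    return out[0], out[1]


def alpha_correction(acbf: FlowCurve, vcbf_measured: FlowCurve) -> Tuple[float, FlowCurve]:
    """Venous correction factor and theoretical venous flow curve.

    alpha = mean(ACBF) / mean(measured VCBF) accounts for venous drainage
    not captured by the measured veins; the theoretical VCBF is the
    measured curve scaled by alpha, so its cycle mean balances the
    arterial inflow exactly.
    """
    _check_compatible(acbf, vcbf_measured)
    mv = vcbf_measured.mean()
    if mv <= 0:
        raise ValueError("measured venous mean flow must be > 0")
    alpha = acbf.mean() / mv
    theoretical = FlowCurve(alpha * vcbf_measured.samples, vcbf_measured.cardiac_period,
                            label=f"{vcbf_measured.label}_theoretical")
    return alpha, theoretical


def arteriovenous_flow(acbf: FlowCurve, theoretical_vcbf: FlowCurve) -> FlowCurve:
    """Pointwise ACBF minus theoretical VCBF (zero-mean by construction)."""
    _check_compatible(acbf, theoretical_vcbf)
    return FlowCurve(acbf.samples - theoretical_vcbf.samples, acbf.cardiac_period,
                     label="arteriovenous")


def _cyclic_cumulative_volume(curve: FlowCurve) -> np.ndarray:
    """Cumulative volume V(t) in ml by cyclic trapezoidal integration.

    Returns n+1 points starting at V=0; the last point is the full-cycle
    integral (≈ 0 for a balanced arteriovenous curve).
    """
    q = curve.samples / 60.0  # ml/s
    dt = curve.cardiac_period / curve.n
    q_wrapped = np.concatenate([q, q[:1]])
    increments = 0.5 * (q_wrapped[:-1] + q_wrapped[1:]) * dt
    return np.concatenate([[0.0], np.cumsum(increments)])


def blood_stroke_volume(av_flow: FlowCurve) -> float:
    """Blood stroke volume: range of the cumulative arteriovenous volume.

    The arteriovenous flow is integrated over the cycle (trapezoidal,
    periodic closure); the stroke volume is max(V) − min(V), the total
    cerebral blood volume change within the cycle.  Warns if the input
    is not balanced (|cycle mean| > 1% of the peak flow magnitude).
    """
    peak = float(np.abs(av_flow.samples).max())
    if peak > 0 and abs(av_flow.mean()) > 0.01 * peak:
        warnings.warn(
            "arteriovenous flow is not balanced: |cycle mean| exceeds 1% of peak",
            stacklevel=2,
        )
    volume = _cyclic_cumulative_volume(av_flow)
    return float(volume.max() - volume.min())


def csf_stroke_volume(csf_flow: FlowCurve) -> float:
    """CSF stroke volume: mean of the two directional lobe areas.

    The signed oscillatory curve is split into its positive (cranio-
    caudal) and negative lobes; each lobe is integrated over the cycle
    and the stroke volume is the mean of the two absolute areas.  Warns
    when the curve never changes sign (oscillatory CSF is expected).
    """
    q = csf_flow.samples
    if q.min() >= 0 or q.max() <= 0:
        warnings.warn("CSF flow curve is unidirectional; stroke volume may be meaningless",
                      stacklevel=2)
    pos = FlowCurve(np.clip(q, 0, None), csf_flow.cardiac_period)
    neg = FlowCurve(np.clip(-q, 0, None), csf_flow.cardiac_period)
    area_pos = _cyclic_cumulative_volume(pos)[-1]
    area_neg = _cyclic_cumulative_volume(neg)[-1]
    return float(0.5 * (area_pos + area_neg))


def pulsatility_index(curve: FlowCurve) -> float:
    """PI = (max − min) / mean over the raw samples (no interpolation)."""
    m = curve.mean()
    if m == 0:
        raise ValueError("pulsatility index undefined for zero-mean flow")
    return float((curve.samples.max() - curve.samples.min()) / m)


# ---------------------------------------------------------------------------
# per-subject assembly


@dataclass
class SubjectMetrics:
    """The per-subject derived parameter set.

    Mean flows in ml/min, stroke volumes in ml per cardiac cycle, PIs and
    alpha factors dimensionless, heart rate beats/min.  Fields are None
    when the corresponding acquisition plane is missing.
    """

    extra_acbf: Optional[float] = None
    intra_acbf: Optional[float] = None
    extra_vcbf: Optional[float] = None
    intra_vcbf: Optional[float] = None
    alpha_extra: Optional[float] = None
    alpha_intra: Optional[float] = None
    extra_blood_sv: Optional[float] = None
    intra_blood_sv: Optional[float] = None
    spinal_csf_sv: Optional[float] = None
    aqueductal_csf_sv: Optional[float] = None
    extra_arterial_pi: Optional[float] = None
    intra_arterial_pi: Optional[float] = None
    extra_venous_pi: Optional[float] = None
    intra_venous_pi: Optional[float] = None
    heart_rate: Optional[float] = None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def metric_names(cls):
        return [f.name for f in fields(cls)]


_LEVEL_PLANE = {"extra": "extracranial_vessels", "intra": "intracranial_vessels"}


def subject_metrics(
    plane_curves: Mapping[str, Mapping[str, FlowCurve]],
    cardiac_period: float,
) -> SubjectMetrics:
    """Assemble the full metric set from per-plane, per-vessel flow curves.

    ``plane_curves`` maps plane label → {vessel label → FlowCurve}.  One
    arterial and one venous PI are computed per level on the composite
    curves (pooled-tree convention).  Missing planes leave their fields
    None rather than failing the whole record.
    """
    m = SubjectMetrics(heart_rate=60.0 / cardiac_period)

    for level in ("extra", "intra"):
        plane = _LEVEL_PLANE[level]
        if plane not in plane_curves:
            continue
        acbf, vcbf = compose_flows(plane_curves[plane], level)
        alpha, vcbf_th = alpha_correction(acbf, vcbf)
        av = arteriovenous_flow(acbf, vcbf_th)
        setattr(m, f"{level}_acbf", acbf.mean())
        setattr(m, f"{level}_vcbf", vcbf.mean())
        setattr(m, f"alpha_{level}", alpha)
        setattr(m, f"{level}_blood_sv", blood_stroke_volume(av))
        setattr(m, f"{level}_arterial_pi", pulsatility_index(acbf))
        setattr(m, f"{level}_venous_pi", pulsatility_index(vcbf))

    if "aqueduct" in plane_curves and "AQUEDUCT" in plane_curves["aqueduct"]:
        m.aqueductal_csf_sv = csf_stroke_volume(plane_curves["aqueduct"]["AQUEDUCT"])
    if "c2c3" in plane_curves and "C2C3_SAS" in plane_curves["c2c3"]:
        m.spinal_csf_sv = csf_stroke_volume(plane_curves["c2c3"]["C2C3_SAS"])
    return m


def metrics_from_truth_curves(scene) -> SubjectMetrics:
    """Ground-truth metrics of a synthetic scene via the same operations.

    Uses the scene's noise-free waveform samples, so pipeline output can
    be compared against truth free of sampling-grid disagreement.
    """
    from .synthetic import truth_curves_for_scene

    curves = truth_curves_for_scene(scene)
    plane_curves = {
        plane: {
            label: FlowCurve(samples, scene.cardiac_period, label=label)
            for label, samples in vessel_curves.items()
        }
        for plane, vessel_curves in curves.items()
    }
    return subject_metrics(plane_curves, scene.cardiac_period)
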