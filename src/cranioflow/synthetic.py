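"""Synthetic cardiac-gated velocity cine generator with known ground truth.

Builds 2D+time phase-contrast acquisitions of pulsatile vessel / CSF
cross-sections: circular lumens rasterized into a velocity image series,
with the stored velocity wrapped into the encoding window (aliasing) and
optional Gaussian velocity noise.  Every scene carries its ground truth
(per-vessel flow curves, lumen areas and derived metrics) so downstream
segmentation and quantification can be validated pixel-for-pixel.

Velocities are cm/s, areas mm², flows ml/min, times s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .waveforms import WaveformSpec, sample_waveform

__all__ = [
    "VesselSpec",
    "AcquisitionSpec",
    "GroundTruth",
    "SubjectScene",
    "apply_phase_wrap",
    "rasterize_cine",
    "make_cohort",
    "PLANE_VENC",
    "PLANE_NOISE_SIGMA",
    "PLANE_VESSELS",
]

#: volumetric-flow conversion: 1 cm/s across 1 mm² = 0.6 ml/min
FLOW_ML_MIN_PER_CMS_MM2 = 0.6

#: default velocity-encoding limit (cm/s) per acquisition plane
PLANE_VENC = {
    "extracranial_vessels": 80.0,
    "intracranial_vessels": 80.0,
    "aqueduct": 10.0,
    "c2c3": 5.0,
}

#: default additive velocity-noise std (cm/s) per plane; chosen so the
#: per-pixel waveform correlation of the weakest CSF oscillation stays
#: above the segmentation admission threshold (see docs/methods.md)
PLANE_NOISE_SIGMA = {
    "extracranial_vessels": 0.5,
    "intracranial_vessels": 0.5,
    "aqueduct": 0.1,
    "c2c3": 0.05,
}

#: vessels measured on each acquisition plane
PLANE_VESSELS = {
    "extracranial_vessels": ("ICA_L", "ICA_R", "VA_L", "VA_R", "IJV_L", "IJV_R"),
    "intracranial_vessels": ("ICA_L", "ICA_R", "BA", "SSS", "StrS"),
    "aqueduct": ("AQUEDUCT",),
    "c2c3": ("C2C3_SAS",),
}

VESSEL_LABELS = (
    "ICA_L", "ICA_R", "VA_L", "VA_R", "BA",
    "IJV_L", "IJV_R", "SSS", "StrS",
    "AQUEDUCT", "C2C3_SAS",
)

_CSF_LABELS = frozenset({"AQUEDUCT", "C2C3_SAS"})

_BPM_RANGE = (45.0, 100.0)

#: physiological lower bounds on drawn per-subject metrics (the lowest
#: normative observed value per metric): composite flows or CSF stroke
#: volumes below these would fall under the flow-signal detection limit
#: and do not occur in healthy adults; such draws are redrawn
METRIC_LOWER_BOUNDS = {
    "aqueductal_csf_sv": 0.01,
    "spinal_csf_sv": 0.08,
    "extra_acbf": 396.0,
    "intra_acbf": 329.0,
    "extra_vcbf": 171.0,
    "intra_vcbf": 171.0,
}


@dataclass(frozen=True)
class VesselSpec:
    """One circular lumen on an acquisition plane.

    ``direction_sign`` follows the cranio-caudal-positive convention:
    +1 for cranio-caudal flow (venous drainage, systolic CSF flush),
    -1 for caudo-cranial flow (arterial inflow).
    """

    label: str
    center: Tuple[int, int]  # (row, col) pixel coordinates
    lumen_area: float  # mm²
    direction_sign: int
    waveform: WaveformSpec

    def __post_init__(self) -> None:
        if self.label not in VESSEL_LABELS:
            raise ValueError(f"unknown vessel label {self.label!r}")
        if self.lumen_area <= 0:
            raise ValueError("lumen_area must be > 0")
        if self.direction_sign not in (-1, 1):
            raise ValueError("direction_sign must be +1 or -1")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Cine acquisition geometry and encoding parameters."""

    venc: float  # cm/s
    matrix: Tuple[int, int] = (128, 256)  # (rows, cols)
    pixel_spacing: float = 0.55  # mm
    slice_thickness: float = 5.0  # mm
    cardiac_period: float = 0.89  # s
    n_frames: int = 32
    noise_sigma: float = 0.0  # cm/s
    seed: int = 0
    plane_label: str = "extracranial_vessels"

    def __post_init__(self) -> None:
        if self.venc <= 0:
            raise ValueError("venc must be > 0")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if self.cardiac_period <= 0:
            raise ValueError("cardiac_period must be > 0")
        bpm = 60.0 / self.cardiac_period
        if not _BPM_RANGE[0] <= bpm <= _BPM_RANGE[1]:
            warnings.warn(
                f"cardiac period {self.cardiac_period:.3f} s ({bpm:.0f} BPM) is outside "
                f"the physiological gate {_BPM_RANGE[0]:.0f}-{_BPM_RANGE[1]:.0f} BPM",
                stacklevel=2,
            )

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area, mm²."""
        return self.pixel_spacing ** 2


@dataclass
class GroundTruth:
    """True (pre-noise, pre-wrap) description of a rasterized scene."""

    flow_curves: Dict[str, np.ndarray]  # ml/min, positive along the vessel's direction
    lumen_areas: Dict[str, float]  # rasterized area, mm²
    lumen_masks: Dict[str, np.ndarray]  # bool (rows, cols)
    direction_signs: Dict[str, int]
    cardiac_period: float


def apply_phase_wrap(true_velocity, venc: float):
    """Wrap a velocity into the phase-encoding window (-venc, +venc].

    Velocities within ±venc are stored unchanged; beyond that they alias
    by multiples of 2·venc and appear directed opposite to the flow.
    Accepts scalars or arrays.
    """
    if venc <= 0:
        raise ValueError("venc must be > 0")
    v = np.asarray(true_velocity, dtype=float)
    wrapped = np.where(
        np.abs(v) <= venc,
        v,
        ((v + venc) % (2.0 * venc)) - venc,
    )
    # values that land exactly on -venc after wrapping belong to +venc
    wrapped = np.where((np.abs(v) > venc) & (wrapped == -venc), venc, wrapped)
    if np.isscalar(true_velocity):
        return float(wrapped)
    return wrapped


def _disk_mask(shape: Tuple[int, int], center: Tuple[int, int], radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px ** 2


def rasterize_cine(
    vessels: Sequence[VesselSpec],
    acq: AcquisitionSpec,
    partial_volume: bool = False,
) -> Tuple["CineStack", GroundTruth]:
    """Render vessel cross-sections into a velocity + magnitude cine stack.

    Each lumen is a pixel-center-in-circle disk.  Lumen pixels carry the
    uniform velocity ``flow / rasterized_area`` (signed by the vessel's
    flow direction), so the mean ROI velocity times ROI area reproduces
    the specified flow curve exactly in the absence of noise.  Stored
    velocities are wrapped into (-venc, +venc] like a real phase image.

    With ``partial_volume=True`` the one-pixel boundary ring of each lumen
    mixes 50% lumen and 50% background signal, emulating the partial
    volume effect the acquisition protocol is designed to avoid.

    Raises
    ------
    ValueError
        If two lumens overlap (the offending pair is named) or a lumen
        does not fit inside the matrix.
    """
    from .velocity import CineStack  # local import to avoid a cycle

    rows, cols = acq.matrix
    occupied = np.zeros((rows, cols), dtype=bool)
    owner: Dict[str, np.ndarray] = {}
    for vs in vessels:
        radius_px = np.sqrt(vs.lumen_area / np.pi) / acq.pixel_spacing
        r0, c0 = vs.center
        if (r0 - radius_px < 0 or r0 + radius_px >= rows
                or c0 - radius_px < 0 or c0 + radius_px >= cols):
            raise ValueError(f"lumen {vs.label} does not fit inside the {rows}x{cols} matrix")
        mask = _disk_mask((rows, cols), vs.center, radius_px)
        if not mask.any():
            raise ValueError(f"lumen {vs.label} rasterizes to zero pixels")
        clash = occupied & mask
        if clash.any():
            for other, omask in owner.items():
                if (omask & mask).any():
                    raise ValueError(f"overlapping lumens: {other} and {vs.label}")
        occupied |= mask
        owner[vs.label] = mask

    rng = np.random.default_rng(acq.seed)
    n = acq.n_frames
    velocity = np.zeros((n, rows, cols), dtype=float)
    magnitude = np.full((n, rows, cols), 100.0)

    flow_curves: Dict[str, np.ndarray] = {}
    areas: Dict[str, float] = {}
    signs: Dict[str, int] = {}
    for vs in vessels:
        mask = owner[vs.label]
        area = mask.sum() * acq.pixel_area
        flow = sample_waveform(vs.waveform, n, acq.cardiac_period)
        vel = flow / (area * FLOW_ML_MIN_PER_CMS_MM2)  # cm/s along flow direction
        velocity[:, mask] = (vs.direction_sign * vel)[:, None]
        magnitude[:, mask] = 400.0
        if partial_volume:
            ring = _ring(mask)
            velocity[:, ring] = 0.5 * (vs.direction_sign * vel)[:, None]
            magnitude[:, ring] = 250.0
        flow_curves[vs.label] = flow
        areas[vs.label] = float(area)
        signs[vs.label] = vs.direction_sign

    if acq.noise_sigma > 0:
        velocity = velocity + rng.normal(0.0, acq.noise_sigma, velocity.shape)
        magnitude = magnitude + rng.normal(0.0, 5.0, magnitude.shape)
    velocity = apply_phase_wrap(velocity, acq.venc)

    stack = CineStack(
        velocity=velocity,
        magnitude=magnitude,
        venc=acq.venc,
        cardiac_period=acq.cardiac_period,
        pixel_area=acq.pixel_area,
        plane_label=acq.plane_label,
    )
    truth = GroundTruth(
        flow_curves=flow_curves,
        lumen_areas=areas,
        lumen_masks=owner,
        direction_signs=signs,
        cardiac_period=acq.cardiac_period,
    )
    return stack, truth


def _ring(mask: np.ndarray) -> np.ndarray:
    """One-pixel 4-connected outer boundary of a boolean mask."""
    grown = mask.copy()
    grown[1:, :] |= mask[:-1, :]
    grown[:-1, :] |= mask[1:, :]
    grown[:, 1:] |= mask[:, :-1]
    grown[:, :-1] |= mask[:, 1:]
    return grown & ~mask


# ---------------------------------------------------------------------------
# cohort generation


#: fixed lumen cross-sections, mm² (adult averages)
DEFAULT_LUMEN_AREAS = {
    "ICA_L": 28.0, "ICA_R": 28.0, "VA_L": 13.0, "VA_R": 13.0, "BA": 17.0,
    "IJV_L": 50.0, "IJV_R": 50.0, "SSS": 45.0, "StrS": 12.0,
    "AQUEDUCT": 10.0, "C2C3_SAS": 150.0,
}

#: fraction of each composite flow carried by each vessel
FLOW_SPLITS = {
    "extra_arterial": {"ICA_L": 0.36, "ICA_R": 0.36, "VA_L": 0.14, "VA_R": 0.14},
    "intra_arterial": {"ICA_L": 0.38, "ICA_R": 0.38, "BA": 0.24},
    "extra_venous": {"IJV_L": 0.45, "IJV_R": 0.55},
    "intra_venous": {"SSS": 0.70, "StrS": 0.30},
}

#: pixel centers per plane (row, col) on the default 128x256 matrix
VESSEL_CENTERS = {
    "extracranial_vessels": {
        "ICA_L": (50, 90), "ICA_R": (50, 166),
        "VA_L": (80, 100), "VA_R": (80, 156),
        "IJV_L": (45, 60), "IJV_R": (45, 196),
    },
    "intracranial_vessels": {
        "ICA_L": (60, 100), "ICA_R": (60, 156),
        "BA": (50, 128), "SSS": (100, 128), "StrS": (80, 128),
    },
    "aqueduct": {"AQUEDUCT": (64, 128)},
    "c2c3": {"C2C3_SAS": (64, 128)},
}

#: phase offsets (fraction of cycle): arterial systole at 0; venous and
#: CSF waves lag arterial inflow (venous lag is re-solved per subject)
DEFAULT_PHASES = {"arterial": 0.0, "venous": 0.1, "aqueduct": 0.12, "c2c3": 0.06}

#: blood waveform family for synthetic cohorts: gamma-variate systolic
#: pulses over a diastolic baseline, from narrow/sharp to broad/smooth.
#: A pulse family (rather than a single sinusoid) is required to realize
#: the normative pulsatility indices and blood stroke volumes jointly:
#: range-based PIs constrain the waveform extrema while the stroke
#: volume constrains the cyclic integral, and for any one fixed shape
#: the two are rigidly coupled.  Pulse width is the subject-level degree
#: of freedom absorbing the residual constraint, mirroring
#: between-subject waveform variability.
BLOOD_SHAPE_MENU = (
    {"shape": "gamma", "systolic_fraction": 0.20, "sharpness": 8.0},
    {"shape": "gamma", "systolic_fraction": 0.25, "sharpness": 6.0},
    {"shape": "gamma", "systolic_fraction": 0.30, "sharpness": 4.0},
    {"shape": "gamma", "systolic_fraction": 0.38, "sharpness": 3.0},
    {"shape": "gamma", "systolic_fraction": 0.48, "sharpness": 2.0},
    {"shape": "gamma", "systolic_fraction": 0.60, "sharpness": 1.2},
)


def _range_factor(shape_kw: Mapping, phase: float, n_frames: int, period: float) -> float:
    """Sampled peak-to-peak range of the unit-amplitude blood pulse."""
    w = sample_waveform(WaveformSpec(0.0, 1.0, phase_offset=phase, **shape_kw),
                        n_frames, period)
    return float(w.max() - w.min())


@dataclass
class SubjectScene:
    """All four acquisition planes of one synthetic subject."""

    subject_id: str
    group: str
    planes: Dict[str, Tuple[List[VesselSpec], AcquisitionSpec]]
    cardiac_period: float


def _blood_spec(mean_flow: float, amplitude: float, phase: float,
                shape_kw: Mapping) -> WaveformSpec:
    return WaveformSpec(mean_flow, amplitude, phase_offset=phase, **shape_kw)


def _solve_blood_waveforms(
    m_a: float, m_v: float, pi_a: float, pi_v: float,
    target_sv: float, n_frames: int, period: float,
) -> Tuple[Mapping, float]:
    """Choose a pulse shape and venous lag realizing a blood stroke volume.

    The arteriovenous flow is the arterial pulse minus the alpha-scaled,
    lagged venous pulse; its cyclically integrated volume range is the
    blood stroke volume.  Pulse amplitudes are pinned by the range-based
    PIs, so for one shape the attainable SV is an interval in the venous
    lag; the narrow-to-broad shape menu is scanned for the first shape
    whose interval contains the target, then the lag is solved on the
    same discrete forward model the rasterizer uses (waveform sampling,
    trapezoidal cyclic integration).  If no shape attains the target the
    closest attainable combination is used.

    Returns (shape keywords, venous phase lag).
    """
    from scipy.optimize import brentq

    from .quantify import FlowCurve, blood_stroke_volume

    alpha = m_a / m_v
    phis = np.linspace(0.0, 0.5, 26)
    best = None  # (abs deviation, shape, phi)
    for shape_kw in BLOOD_SHAPE_MENU:
        art = sample_waveform(
            _blood_spec(m_a, pi_a * m_a / _range_factor(shape_kw, 0.0, n_frames, period),
                        0.0, shape_kw),
            n_frames, period)

        def sv_of(phi: float) -> float:
            amp_v = pi_v * m_v / _range_factor(shape_kw, phi, n_frames, period)
            ven = sample_waveform(_blood_spec(m_v, amp_v, phi, shape_kw), n_frames, period)
            return blood_stroke_volume(FlowCurve(art - alpha * ven, period))

        svs = np.array([sv_of(p) for p in phis])
        if svs.min() <= target_sv <= svs.max():
            for i in range(len(phis) - 1):
                lo, hi = svs[i], svs[i + 1]
                if min(lo, hi) <= target_sv <= max(lo, hi):
                    if lo == hi:
                        return shape_kw, float(phis[i])
                    phi = brentq(lambda p: sv_of(p) - target_sv,
                                 phis[i], phis[i + 1], xtol=1e-6)
                    return shape_kw, float(phi)
        dev = np.abs(svs - target_sv)
        cand = (float(dev.min()), shape_kw, float(phis[dev.argmin()]))
        if best is None or cand[0] < best[0]:
            best = cand
    return best[1], best[2]


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   lo: float = 0.0, hi: float = np.inf, max_redraws: int = 100) -> float:
    """Normal draw constrained to (lo, hi); redraw up to ``max_redraws``."""
    if sd == 0:
        return float(np.clip(mean, lo if lo > 0 else mean, hi))
    for _ in range(max_redraws):
        x = float(rng.normal(mean, sd))
        if lo < x < hi:
            return x
    raise RuntimeError(f"could not draw a value in ({lo}, {hi}) from N({mean}, {sd})")


def _build_subject_scene(
    subject_id: str,
    group: str,
    draws: Mapping[str, float],
    noise: Mapping[str, float],
    seed_seq: Sequence[int],
    matrix: Tuple[int, int] = (128, 256),
) -> SubjectScene:
    """Assemble the four plane scenes realizing a subject's drawn metrics."""
    period = 60.0 / draws["heart_rate"]
    planes: Dict[str, Tuple[List[VesselSpec], AcquisitionSpec]] = {}

    def _acq(plane: str, seed: int) -> AcquisitionSpec:
        return AcquisitionSpec(
            venc=PLANE_VENC[plane],
            matrix=matrix,
            cardiac_period=period,
            noise_sigma=noise.get(plane, PLANE_NOISE_SIGMA[plane]),
            seed=int(seed),
            plane_label=plane,
        )

    for i, (plane, level) in enumerate(
        [("extracranial_vessels", "extra"), ("intracranial_vessels", "intra")]
    ):
        m_a = draws[f"{level}_acbf"]
        m_v = draws[f"{level}_vcbf"]
        acq = _acq(plane, seed_seq[i])
        shape_kw, phase_v = _solve_blood_waveforms(
            m_a, m_v, draws[f"{level}_arterial_pi"], draws[f"{level}_venous_pi"],
            draws[f"{level}_blood_sv"], acq.n_frames, period)
        # pulse amplitudes from the range-based PIs (composite range = PI x mean)
        amp_a = draws[f"{level}_arterial_pi"] * m_a \
            / _range_factor(shape_kw, 0.0, acq.n_frames, period)
        amp_v = draws[f"{level}_venous_pi"] * m_v \
            / _range_factor(shape_kw, phase_v, acq.n_frames, period)
        specs: List[VesselSpec] = []
        for vessel, frac in FLOW_SPLITS[f"{level}_arterial"].items():
            specs.append(VesselSpec(
                label=vessel,
                center=VESSEL_CENTERS[plane][vessel],
                lumen_area=DEFAULT_LUMEN_AREAS[vessel],
                direction_sign=-1,
                waveform=_blood_spec(m_a * frac, amp_a * frac,
                                     DEFAULT_PHASES["arterial"], shape_kw),
            ))
        for vessel, frac in FLOW_SPLITS[f"{level}_venous"].items():
            specs.append(VesselSpec(
                label=vessel,
                center=VESSEL_CENTERS[plane][vessel],
                lumen_area=DEFAULT_LUMEN_AREAS[vessel],
                direction_sign=1,
                waveform=_blood_spec(m_v * frac, amp_v * frac, phase_v, shape_kw),
            ))
        planes[plane] = (specs, acq)

    for i, (plane, vessel, sv_key) in enumerate(
        [("aqueduct", "AQUEDUCT", "aqueductal_csf_sv"), ("c2c3", "C2C3_SAS", "spinal_csf_sv")],
        start=2,
    ):
        amp = draws[sv_key] * 60.0 * np.pi / period  # ml/min, zero-mean sinusoid
        specs = [VesselSpec(
            label=vessel,
            center=VESSEL_CENTERS[plane][vessel],
            lumen_area=DEFAULT_LUMEN_AREAS[vessel],
            direction_sign=1,
            waveform=WaveformSpec(0.0, amp, phase_offset=DEFAULT_PHASES[plane]),
        )]
        planes[plane] = (specs, _acq(plane, seed_seq[i]))

    return SubjectScene(subject_id=subject_id, group=group, planes=planes, cardiac_period=period)


def make_cohort(
    n_young: int,
    n_elderly: int,
    seed: int,
    group_params: Mapping[str, Mapping[str, Tuple[float, float]]] | None = None,
    noise: Mapping[str, float] | None = None,
    matrix: Tuple[int, int] = (128, 256),
):
    """Draw a synthetic two-group cohort of subject scenes.

    Per-subject composite metrics (mean flows, PIs, stroke volumes, heart
    rate) are drawn from group-level normal distributions — by default the
    normative young/elderly values in :mod:`cranioflow.cohort_defaults` —
    and realized as four-plane cine scenes whose ground-truth metrics
    equal the draws (up to temporal discretization).  Deterministic under
    ``seed``.

    Returns
    -------
    (scenes, truth_table)
        ``scenes``: list of :class:`SubjectScene`;
        ``truth_table``: :class:`pandas.DataFrame` of ground-truth metrics,
        one row per subject, with ``subject_id`` and ``group`` columns.
    """
    import pandas as pd

    from .quantify import metrics_from_truth_curves

    if n_young < 1 or n_elderly < 1:
        raise ValueError("both group sizes must be >= 1")
    if group_params is None:
        from .cohort_defaults import NORMATIVE_GROUPS
        group_params = NORMATIVE_GROUPS
    noise = dict(noise or {})

    rng = np.random.default_rng(seed)
    scenes: List[SubjectScene] = []
    rows = []
    for group, n_subj in (("HYV", n_young), ("HEV", n_elderly)):
        params = group_params[group]
        for k in range(n_subj):
            draws = {}
            for key, (mean, sd) in params.items():
                if key == "heart_rate":
                    lo, hi = _BPM_RANGE
                else:
                    lo, hi = METRIC_LOWER_BOUNDS.get(key, 0.0), np.inf
                draws[key] = _draw_positive(rng, mean, sd, lo=lo, hi=hi)
            seed_seq = rng.integers(0, 2 ** 31 - 1, size=4)
            sid = f"{group}{k + 1:02d}"
            scene = _build_subject_scene(sid, group, draws, noise, seed_seq, matrix)
            scenes.append(scene)
            row = {"subject_id": sid, "group": group}
            row.update(metrics_from_truth_curves(scene).as_dict())
            rows.append(row)
    truth_table = pd.DataFrame(rows)
    return scenes, truth_table


def truth_curves_for_scene(scene: SubjectScene) -> Dict[str, Dict[str, np.ndarray]]:
    """Noise-free per-plane, per-vessel flow curves (ml/min) for a scene."""
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for plane, (specs, acq) in scene.planes.items():
        out[plane] = {
            vs.label: sample_waveform(vs.waveform, acq.n_frames, acq.cardiac_period)
            for vs in specs
        }
    return out
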