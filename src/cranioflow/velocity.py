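"""From stored phase/velocity cines to per-ROI mean-velocity waveforms.

Covers the three processing concerns that precede flow quantification:

* aliasing — detection of velocity-wrapped pixels and the standard
  2·venc unwrap correction;
* segmentation — a deterministic region-growing surrogate for
  semi-automated lumen delineation, admitting pixels whose velocity
  waveform tracks the ROI-mean waveform;
* averaging — reduction of a cine to a signed mean-velocity curve plus
  the ROI area.

The sign convention is cranio-caudal = positive everywhere; applying
``direction_sign`` here means venous drainage and arterial inflow both
come out as positive flow downstream.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "CineStack",
    "RoiMask",
    "SegmentationParams",
    "AliasingReport",
    "detect_aliasing",
    "correct_aliasing",
    "dealias_stack",
    "segment_roi",
    "mean_velocity_curve",
]

logger = logging.getLogger(__name__)

PLANE_LABELS = ("extracranial_vessels", "intracranial_vessels", "aqueduct", "c2c3")


@dataclass
class CineStack:
    """One cardiac-gated velocity + magnitude cine for one plane.

    ``velocity`` and ``magnitude`` are (n_frames, rows, cols) arrays;
    stored velocities are cm/s, signed, inside (-venc, +venc].
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    venc: float
    cardiac_period: float
    pixel_area: float  # mm²
    plane_label: str = "extracranial_vessels"

    def __post_init__(self) -> None:
        if self.velocity.ndim != 3:
            raise ValueError("velocity must be a (n_frames, rows, cols) array")
        if self.velocity.shape != self.magnitude.shape:
            raise ValueError("velocity and magnitude shapes differ")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be > 0")
        if self.plane_label not in PLANE_LABELS:
            raise ValueError(f"unknown plane_label {self.plane_label!r}")

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.velocity.shape[1:]


@dataclass
class RoiMask:
    """Pixel set of one vessel or CSF territory with its flow direction."""

    label: str
    mask: np.ndarray  # bool (rows, cols)
    direction_sign: int

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        if self.direction_sign not in (-1, 1):
            raise ValueError("direction_sign must be +1 or -1")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SegmentationParams:
    """Region-growing admission thresholds.

    A candidate pixel is admitted on either of two flow signatures:

    * oscillatory (CSF-like): Pearson correlation of its velocity
      waveform with the running ROI-mean waveform >= ``r_min`` *and*
      temporal velocity SD above the pulsatility floor;
    * sustained (blood-like): absolute temporal-mean velocity above the
      mean-velocity floor, i.e. a steady through-plane flow component
      that static background cannot show.

    ``pulsatility_floor`` is an absolute SD threshold in cm/s; if None it
    is set adaptively to ``floor_factor`` times the image-wide median
    temporal SD (a robust estimate of the background noise level).  The
    mean-velocity floor is ``mean_snr_floor`` background standard errors
    of a temporal mean (sigma_hat / sqrt(n_frames)).
    """

    r_min: float = 0.7
    pulsatility_floor: float | None = None
    floor_factor: float = 1.5
    mean_snr_floor: float = 5.0
    max_pixels: int = 5000


@dataclass
class AliasingReport:
    """Fraction of aliased pixels per frame and the repeat-scan verdict."""

    fraction_per_frame: np.ndarray
    reject: bool  # True: >50% of ROI aliased in some frame; repeat with double venc


def detect_aliasing(
    stack: CineStack, roi: RoiMask, threshold: float = 0.75
) -> AliasingReport:
    """Flag velocity-wrapped pixels inside an ROI.

    A pixel-frame is considered aliased when its velocity sign opposes
    the ROI's flow direction *and* its magnitude exceeds
    ``threshold * venc``.  The acquisition is marked for rejection when
    more than half of the ROI pixels are aliased in any frame (such data
    would need re-acquisition with doubled venc).
    """
    v = stack.velocity[:, roi.mask]  # (n_frames, n_pixels)
    opposed = np.sign(v) == -roi.direction_sign
    flagged = opposed & (np.abs(v) > threshold * stack.venc)
    fraction = flagged.mean(axis=1)
    return AliasingReport(fraction_per_frame=fraction, reject=bool((fraction > 0.5).any()))


def correct_aliasing(v_error, venc: float):
    """Unwrap an aliased velocity: (2·venc - |v|) with the sign flipped.

    Exact for true speeds between venc and 2·venc.  Zero inputs are
    undefined under this formula and returned unchanged (logged).
    Accepts scalars or arrays.
    """
    if venc <= 0:
        raise ValueError("venc must be > 0")
    v = np.asarray(v_error, dtype=float)
    zero = v == 0
    if zero.any():
        logger.warning("correct_aliasing: %d zero-velocity pixels left unchanged", zero.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = (2.0 * venc - np.abs(v)) * (-np.abs(v) / v)
    corrected = np.where(zero, v, corrected)
    if np.isscalar(v_error):
        return float(corrected)
    return corrected


def dealias_stack(stack: CineStack, direction_sign: int, threshold: float = 0.75) -> CineStack:
    """Return a copy of the stack with wrap-flagged pixels corrected.

    Flagging uses the same rule as :func:`detect_aliasing`, applied to
    every pixel with the given expected flow direction.
    """
    v = stack.velocity
    flagged = (np.sign(v) == -direction_sign) & (np.abs(v) > threshold * stack.venc)
    if not flagged.any():
        return stack
    out = v.copy()
    out[flagged] = correct_aliasing(v[flagged], stack.venc)
    return CineStack(
        velocity=out,
        magnitude=stack.magnitude,
        venc=stack.venc,
        cardiac_period=stack.cardiac_period,
        pixel_area=stack.pixel_area,
        plane_label=stack.plane_label,
    )


class SeedNotPulsatileError(ValueError):
    """Raised when the segmentation seed shows no pulsatile signal."""


def segment_roi(
    stack: CineStack,
    seed_pixel: Tuple[int, int],
    params: SegmentationParams = SegmentationParams(),
    label: str = "ROI",
    direction_sign: int = 1,
    sd_map: np.ndarray | None = None,
) -> RoiMask:
    """Grow a lumen mask from a seed pixel by flow-signal similarity.

    Starting from the seed, 4-connected neighbours are admitted when
    they carry a flow signature per :class:`SegmentationParams`: either
    an oscillatory waveform that tracks the running ROI-mean waveform
    (r >= ``r_min`` with temporal SD above the pulsatility floor) or a
    sustained through-plane mean velocity above the mean-velocity floor.
    Growth proceeds in rounds — all qualifying frontier pixels of a
    round are admitted together and previously unqualified neighbours
    are retried against the updated mean — until a fixed point.
    Deterministic.

    The stack should be de-aliased first; wrapped pixels anti-correlate
    with the lumen waveform and oppose its mean, so they are excluded.

    Raises
    ------
    SeedNotPulsatileError
        If the seed pixel itself shows neither flow signature (static
        background).
    """
    rows, cols = stack.shape
    r0, c0 = seed_pixel
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"seed pixel {seed_pixel} outside image bounds {stack.shape}")

    v = stack.velocity  # (n, rows, cols)
    if sd_map is None:
        sd_map = v.std(axis=0)
    mean_map = v.mean(axis=0)
    sigma_hat = float(np.median(sd_map))
    floor = params.pulsatility_floor
    if floor is None:
        floor = max(params.floor_factor * sigma_hat, 1e-12)
    mean_floor = max(params.mean_snr_floor * sigma_hat / np.sqrt(stack.n_frames), 1e-12)

    sustained = np.abs(mean_map) > mean_floor
    pulsatile = sd_map > floor
    if not (pulsatile[r0, c0] or sustained[r0, c0]):
        raise SeedNotPulsatileError(f"no pulsatile signal at seed {seed_pixel}")

    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0, c0] = True
    while mask.sum() < params.max_pixels:
        frontier = _frontier(mask)
        if not frontier.any():
            break
        mean_curve = v[:, mask].mean(axis=1)
        cand = v[:, frontier]  # (n, k)
        r = _pearson_with(mean_curve, cand)
        admit2d = np.zeros_like(mask)
        admit2d[frontier] = ((r >= params.r_min) & pulsatile[frontier]) | sustained[frontier]
        if not admit2d.any():
            break
        mask |= admit2d
    return RoiMask(label=label, mask=mask, direction_sign=direction_sign)


def _frontier(mask: np.ndarray) -> np.ndarray:
    grown = mask.copy()
    grown[1:, :] |= mask[:-1, :]
    grown[:-1, :] |= mask[1:, :]
    grown[:, 1:] |= mask[:, :-1]
    grown[:, :-1] |= mask[:, 1:]
    return grown & ~mask


def _pearson_with(ref: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Pearson r between a reference waveform and each column of candidates."""
    ref_c = ref - ref.mean()
    cand_c = candidates - candidates.mean(axis=0)
    num = ref_c @ cand_c
    den = np.sqrt((ref_c ** 2).sum() * (cand_c ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    return np.where(den > 0, r, -1.0)


def mean_velocity_curve(stack: CineStack, roi: RoiMask) -> Tuple[np.ndarray, float]:
    """Signed mean-velocity waveform over an ROI plus its area.

    Returns the per-frame arithmetic mean of ``direction_sign * velocity``
    over the ROI pixels (cm/s, positive along the ROI's flow direction)
    and the ROI area in mm².
    """
    if roi.mask.shape != stack.shape:
        raise ValueError("ROI shape does not match stack")
    curve = roi.direction_sign * stack.velocity[:, roi.mask].mean(axis=1)
    area = roi.n_pixels * stack.pixel_area
    return curve, area
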