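"""Pulsatile flow waveforms sampled over one cardiac cycle.

Volumetric flow is carried in ml/min throughout; a cardiac cycle is
sampled at a fixed number of uniformly spaced time points (32 by default,
matching retrospectively gated cine phase-contrast acquisitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WaveformSpec", "sample_waveform"]

#: shapes understood by :func:`sample_waveform`
WAVEFORM_SHAPES = ("sinusoid", "gamma")


@dataclass(frozen=True)
class WaveformSpec:
    """Parametric description of a periodic volumetric flow waveform.

    Parameters
    ----------
    mean_flow:
        Cycle-averaged volumetric flow in ml/min.  May be ~0 for
        oscillatory CSF flow.
    pulse_amplitude:
        Peak deviation from the cycle mean, ml/min (>= 0).
    systolic_fraction:
        Fraction of the cycle occupied by the systolic upstroke; only
        meaningful for the ``gamma`` shape.
    phase_offset:
        Shift of the waveform expressed as a fraction of the cycle in
        [0, 1).
    shape:
        ``"sinusoid"`` (closed-form testable) or ``"gamma"`` (gamma-variate
        systolic pulse riding on a diastolic baseline).
    sharpness:
        Gamma-variate exponent; larger values narrow the systolic peak
        relative to the cycle.  Ignored for the sinusoid.
    """

    mean_flow: float
    pulse_amplitude: float
    systolic_fraction: float = 0.3
    phase_offset: float = 0.0
    shape: str = "sinusoid"
    sharpness: float = 3.0

    def __post_init__(self) -> None:
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be >= 0")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if not 0.0 <= self.phase_offset < 1.0:
            raise ValueError("phase_offset must lie in [0, 1)")
        if self.shape not in WAVEFORM_SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {WAVEFORM_SHAPES}")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be > 0")


def _gamma_variate(u: np.ndarray, t_peak: float, k: float = 3.0) -> np.ndarray:
    """Gamma-variate pulse g(u) = (u/tp)^k exp(k(1-u/tp)), peak 1 at u=tp."""
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (u / t_peak) ** k * np.exp(k * (1.0 - u / t_peak))
    return np.where(u <= 0, 0.0, g)


def sample_waveform(spec: WaveformSpec, n_frames: int = 32, cardiac_period: float = 1.0) -> np.ndarray:
    """Sample one cardiac cycle of a flow waveform at uniform time points.

    Returns ``n_frames`` volumetric flow values (ml/min).  The arithmetic
    mean of the samples equals ``spec.mean_flow`` exactly (the pulse is
    de-meaned before the baseline is added), so cycle-mean flow survives
    temporal discretization.

    Raises
    ------
    ValueError
        If ``cardiac_period <= 0`` or ``n_frames < 8``.
    """
    if cardiac_period <= 0:
        raise ValueError("cardiac_period must be positive")
    if n_frames < 8:
        raise ValueError("n_frames must be >= 8")

    u = (np.arange(n_frames) / n_frames - spec.phase_offset) % 1.0
    if spec.shape == "sinusoid":
        pulse = np.sin(2.0 * np.pi * u)
    else:  # gamma-variate systolic pulse + flat diastolic baseline
        t_peak = spec.systolic_fraction / 2.0
        pulse = _gamma_variate(u, t_peak, spec.sharpness)
    pulse = pulse - pulse.mean()
    peak = np.abs(pulse).max()
    if peak > 0 and spec.pulse_amplitude > 0:
        pulse = pulse * (spec.pulse_amplitude / peak)
    else:
        pulse = np.zeros(n_frames)
    return spec.mean_flow + pulse
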