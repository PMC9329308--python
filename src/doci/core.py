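"""Gated integration of time-resolved stacks into DOCI images.

A DOCI image is computed per spectral channel by integrating each pixel's
detected time course over two temporal gates — a steady-state gate late in
the excitation pulse and a decay gate after pulse turn-off — and taking the
ratio decay/steady.  The ratio cancels absolute intensity, so the map
carries relative-lifetime contrast rather than brightness contrast.  No
per-pixel exponential fitting is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decay import PulseTiming

__all__ = [
    "DOCIImage",
    "gated_aggregate",
    "compute_doci",
    "compute_all_channels",
    "default_min_steady",
]

# Pixels whose steady-state integral is exactly zero carry no signal at all;
# they are masked even when no explicit threshold is requested.
_TINY_STEADY = 1e-30


@dataclass
class DOCIImage:
    """Per-channel DOCI map with a validity mask.

    ``values`` are dimensionless decay/steady ratios, >= 0 wherever
    ``valid_mask`` is true and 0 by convention elsewhere.  ``valid_mask`` is
    false exactly where the steady-state aggregate fell below
    ``threshold_used``.
    """

    channel: float
    values: np.ndarray
    valid_mask: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must have the same shape")


def gated_aggregate(
    frames: np.ndarray,
    time_grid: np.ndarray,
    gate: tuple[float, float],
) -> np.ndarray:
    """Trapezoidal per-pixel integral of ``frames`` over the gate ``[a, b)``.

    ``frames`` has shape (time, ...) aligned with ``time_grid``.  The
    trapezoid spans the samples inside the gate; when the grid contains a
    sample at the gate's right edge it closes the final trapezoid, so
    adjacent gates tile the time axis without double counting.

    Raises
    ------
    ValueError
        If the gate covers fewer than one sample interval.
    """
    t = np.asarray(time_grid, dtype=float)
    frames = np.asarray(frames)
    if frames.shape[0] != t.size:
        raise ValueError("frames and time_grid length mismatch")
    a, b = float(gate[0]), float(gate[1])
    if not b > a:
        raise ValueError("gate must be a non-empty interval [a, b)")
    i0 = int(np.searchsorted(t, a, side="left"))
    i1 = int(np.searchsorted(t, b, side="left"))
    if i1 < t.size and np.isclose(t[i1], b):
        i1 += 1  # close the last trapezoid at the gate edge
    if i1 - i0 < 2:
        raise ValueError(f"gate [{a}, {b}) covers no sample interval")
    return np.trapezoid(frames[i0:i1], t[i0:i1], axis=0)


def default_min_steady(read_sigma: float, timing: PulseTiming) -> float:
    """Low-signal threshold: 5x the read-noise scale of the steady integral.

    The trapezoidal integral of pure Gaussian read noise over a gate of
    width W sampled at dt has standard deviation ~ sigma*sqrt(W*dt); pixels
    below five times that carry no usable steady-state signal.
    """
    return 5.0 * float(read_sigma) * np.sqrt(timing.steady_width * timing.sample_dt)


def compute_doci(
    stack,
    timing: PulseTiming | None = None,
    min_steady: float | None = None,
) -> DOCIImage:
    """Compute the DOCI map of one time-resolved stack.

    Parameters
    ----------
    stack : TimeResolvedStack
        Frames (time, row, col) with their time grid and timing.
    timing : PulseTiming, optional
        Overrides the stack's stored timing.
    min_steady : float, optional
        Steady-state aggregate (counts*ns) below which a pixel is masked
        invalid.  Default masks only pixels with no steady signal at all.
        Low signal is a mask state, never an error.

    Negative decay aggregates (possible under read noise) are clipped to 0,
    so valid DOCI values are always >= 0.
    """
    timing = timing if timing is not None else stack.timing
    steady = gated_aggregate(stack.frames, stack.time_grid, timing.steady_gate)
    decay = gated_aggregate(stack.frames, stack.time_grid, timing.decay_gate)

    thr = max(float(min_steady), _TINY_STEADY) if min_steady is not None else _TINY_STEADY
    valid = steady >= thr
    values = np.zeros_like(steady, dtype=float)
    np.divide(np.clip(decay, 0.0, None), steady, out=values, where=valid)
    return DOCIImage(
        channel=stack.channel,
        values=values,
        valid_mask=valid,
        threshold_used=thr,
    )


def compute_all_channels(
    stacks: Sequence,
    timing: PulseTiming | None = None,
    min_steady: float | None = None,
) -> list[DOCIImage]:
    """Compute DOCI maps for every channel stack, independently per channel.

    Input order is preserved; channels must be unique.  There is no
    cross-channel normalization.
    """
    channels = [s.channel for s in stacks]
    if len(set(channels)) != len(channels):
        dupes = sorted({c for c in channels if channels.count(c) > 1})
        raise ValueError(f"duplicate channels in input: {dupes}")
    if len(channels) == 0:
        warnings.warn("no stacks supplied; returning empty list", stacklevel=2)
    return [compute_doci(s, timing=timing, min_steady=min_steady) for s in stacks]
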