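"""Perineural-invasion detection along nerve axes.

Invaded nerve segments show lower relative lifetimes (lower DOCI values)
than healthy nerve, so a nerve is interrogated by extracting the DOCI
profile along its axis, calibrating a decision threshold on control nerves
(mean minus k standard deviations), and calling invasion when a persistent
run of axial positions falls below the threshold.  The run-length rule
suppresses isolated noise dips; the first position of the first qualifying
run localizes the healthy-to-invaded transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DOCIImage
from .phantom import NerveBand
from .roi import one_sample_t

__all__ = [
    "NerveProfile",
    "PNICall",
    "extract_profile",
    "calibrate_threshold",
    "call_pni",
    "evaluate_detection",
    "PNIDetector",
    "PNIDetectionResults",
]


@dataclass(frozen=True)
class NerveProfile:
    """Mean DOCI across the band width at each axial position of a nerve."""

    positions: np.ndarray
    values: np.ndarray
    channel: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")


@dataclass(frozen=True)
class PNICall:
    """Classification of one nerve: control or PNI, with the evidence used."""

    label: str  # "control" | "pni"
    score: float  # mean DOCI over the whole band
    threshold: float
    transition_index: int | None  # absent for control calls


def extract_profile(doci: DOCIImage, band: NerveBand) -> NerveProfile:
    """Axial DOCI profile of a nerve band: mean over the band width.

    Positions whose entire cross-section is masked are dropped; a fully
    masked band is an error.
    """
    mask = band.mask(doci.values.shape)
    vals = np.where(doci.valid_mask & mask, doci.values, np.nan)
    if band.axis == "h":
        section = vals[band.offset : band.offset + band.width, band.start : band.stop]
        axis0 = 0
    else:
        section = vals[band.start : band.stop, band.offset : band.offset + band.width]
        axis0 = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cross-sections
        prof = np.nanmean(section, axis=axis0)
    positions = np.arange(band.start, band.stop)
    keep = np.isfinite(prof)
    if not keep.any():
        raise ValueError("nerve band is fully masked; no profile available")
    return NerveProfile(positions=positions[keep], values=prof[keep], channel=doci.channel)


def calibrate_threshold(
    control_profiles: Sequence[NerveProfile], k: float = 3.0
) -> float:
    """Decision threshold from pooled control-nerve values: mean - k*sd.

    Values below the threshold indicate invasion (invaded nerve has lower
    relative lifetime).  Zero control variance with k > 0 degenerates to
    the control mean, with a warning.
    """
    if len(control_profiles) < 1:
        raise ValueError("need at least 1 control profile to calibrate")
    pooled = np.concatenate([p.values for p in control_profiles])
    if pooled.size < 2:
        raise ValueError("need at least 2 pooled control values to calibrate")
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    if sd == 0 and k > 0:
        warnings.warn(
            "control profiles have zero variance; threshold degenerates to the mean",
            stacklevel=2,
        )
        return mean
    return mean - k * sd


def call_pni(
    profile: NerveProfile, threshold: float, min_run: int = 5
) -> PNICall:
    """Classify one nerve by run-length persistence below the threshold.

    The call is PNI iff at least ``min_run`` consecutive axial positions lie
    strictly below ``threshold``; the transition index is the first position
    of the first qualifying run.  The score (band-wide mean DOCI) is always
    reported.
    """
    if profile.values.size == 0:
        raise ValueError("empty profile")
    below = profile.values < threshold
    run = 0
    start = None
    for i, b in enumerate(below):
        if b:
            run += 1
            if run == 1:
                start = i
            if run >= min_run:
                return PNICall(
                    label="pni",
                    score=float(profile.values.mean()),
                    threshold=float(threshold),
                    transition_index=int(profile.positions[start]),
                )
        else:
            run = 0
            start = None
    return PNICall(
        label="control",
        score=float(profile.values.mean()),
        threshold=float(threshold),
        transition_index=None,
    )


def evaluate_detection(
    predicted: Sequence[str], truth: Sequence[str]
) -> dict[str, float | None]:
    """Confusion-matrix metrics of PNI calls against ground truth.

    Labels are "pni" (positive) and "control" (negative).  Sensitivity or
    specificity is None when its class is absent from the truth.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth label lists differ in length")
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    for lab in np.concatenate([pred, true]):
        if lab not in ("pni", "control"):
            raise ValueError(f"unknown label {lab!r}")
    pos = true == "pni"
    neg = ~pos
    acc = float((pred == true).mean()) if true.size else None
    sens = float((pred[pos] == "pni").mean()) if pos.any() else None
    spec = float((pred[neg] == "control").mean()) if neg.any() else None
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


class PNIDetector:
    """Model for threshold-based PNI detection over a set of nerves.

    Holds the extracted profiles, which are control (used for threshold
    calibration) and, optionally, ground-truth labels.  ``fit()`` calibrates
    the threshold on the controls, calls every nerve, and returns a
    :class:`PNIDetectionResults` with per-nerve calls, confusion metrics and
    a one-sample t-test of control-normalized PNI scores against 1.
    """

    def __init__(
        self,
        profiles: Sequence[NerveProfile],
        is_control: Sequence[bool],
        truth: Sequence[str] | None = None,
        k: float = 3.0,
        min_run: int = 5,
    ) -> None:
        if len(profiles) != len(is_control):
            raise ValueError("profiles and is_control differ in length")
        if truth is not None and len(truth) != len(profiles):
            raise ValueError("truth labels differ in length from profiles")
        self.profiles = list(profiles)
        self.is_control = list(bool(c) for c in is_control)
        self.truth = list(truth) if truth is not None else None
        self.k = float(k)
        self.min_run = int(min_run)

    def fit(self) -> "PNIDetectionResults":
        controls = [p for p, c in zip(self.profiles, self.is_control) if c]
        threshold = calibrate_threshold(controls, k=self.k)
        calls = [call_pni(p, threshold, min_run=self.min_run) for p in self.profiles]

        metrics = None
        if self.truth is not None:
            metrics = evaluate_detection([c.label for c in calls], self.truth)

        # Fig-4B-style test: PNI-nerve scores normalized by the control-score
        # mean, tested against 1.
        ctrl_scores = np.array(
            [c.score for c, isc in zip(calls, self.is_control) if isc]
        )
        test_scores = np.array(
            [c.score for c, isc in zip(calls, self.is_control) if not isc]
        )
        score_test = None
        if ctrl_scores.size and test_scores.size and ctrl_scores.mean() > 0:
            t, df, p = one_sample_t(test_scores / ctrl_scores.mean(), null_value=1.0)
            score_test = {"t": t, "df": df, "p": p}

        rows = []
        for i, (prof, call) in enumerate(zip(self.profiles, calls)):
            rows.append(
                {
                    "nerve_id": i,
                    "channel": prof.channel,
                    "score": call.score,
                    "threshold": call.threshold,
                    "label": call.label,
                    "transition_index": (
                        -1 if call.transition_index is None else call.transition_index
                    ),
                    "is_control": self.is_control[i],
                    "truth": self.truth[i] if self.truth is not None else "",
                }
            )
        return PNIDetectionResults(
            calls=pd.DataFrame(rows),
            threshold=float(threshold),
            metrics=metrics,
            score_test=score_test,
            k=self.k,
            min_run=self.min_run,
        )


@dataclass
class PNIDetectionResults:
    """Per-nerve calls, calibrated threshold and detection metrics."""

    calls: pd.DataFrame
    threshold: float
    metrics: dict[str, float | None] | None
    score_test: dict[str, float | None] | None
    k: float
    min_run: int

    def summary(self) -> str:
        lines = [
            f"PNI detection (threshold {self.threshold:.5g}, "
            f"k={self.k:g}, min_run={self.min_run})",
            "",
            self.calls.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.metrics is not None:
            m = {
                key: ("n/a" if v is None else f"{v:.3f}")
                for key, v in self.metrics.items()
            }
            lines += ["", f"accuracy={m['accuracy']} sensitivity={m['sensitivity']} "
                          f"specificity={m['specificity']}"]
        if self.score_test is not None and self.score_test["p"] is not None:
            lines += [
                f"PNI vs control scores: t={self.score_test['t']:.3f}, "
                f"df={self.score_test['df']}, p={self.score_test['p']:.3g}"
            ]
        return "\n".join(lines)
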