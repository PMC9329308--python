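"""Run configuration: every tunable default, overridable from one YAML file.

A config round-trips through ``save_config``/``load_config`` at the value
level; saving records the fully resolved defaults explicitly.  Unknown keys
are rejected by name so typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decay import PulseTiming
from .phantom import DEFAULT_CHANNELS, DEFAULT_LIFETIMES, NoiseModel, TISSUE_NAMES

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """All analysis and simulation parameters for one run."""

    channels: tuple[float, ...] = DEFAULT_CHANNELS
    timing: PulseTiming = field(default_factory=PulseTiming)
    noise: NoiseModel = field(default_factory=NoiseModel)
    lifetimes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIFETIMES)
    )
    brightness: dict[str, float] = field(default_factory=dict)
    reference_tissue: str = "tumor"
    k: float = 3.0  # control-threshold multiplier (mean - k*sd)
    min_run: int = 5  # consecutive below-threshold positions for a PNI call
    min_steady: float | None = None  # None -> derived from read noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_tissue not in TISSUE_NAMES:
            raise ValueError(
                f"reference_tissue: unknown tissue {self.reference_tissue!r}"
            )
        for name in list(self.lifetimes) + list(self.brightness):
            if name not in TISSUE_NAMES:
                raise ValueError(f"lifetimes/brightness: unknown tissue {name!r}")
        for name, tau in self.lifetimes.items():
            if not tau >= 0:
                raise ValueError(f"lifetimes.{name}: must be >= 0, got {tau}")
        if self.min_run < 1:
            raise ValueError("min_run: must be >= 1")
        if self.min_steady is not None and self.min_steady < 0:
            raise ValueError("min_steady: must be >= 0 or null")


_TIMING_KEYS = {"pulse_on", "pulse_off", "steady_gate", "decay_gate", "sample_dt"}
_NOISE_KEYS = {"photon_scale", "read_sigma"}
_TOP_KEYS = {
    "channels",
    "timing",
    "noise",
    "lifetimes",
    "brightness",
    "reference_tissue",
    "k",
    "min_run",
    "min_steady",
    "seed",
}


def _reject_unknown(given: dict, allowed: set[str], where: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; absent keys take defaults, unknown keys raise."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")

    kwargs: dict = {}
    if "timing" in raw:
        t = dict(raw["timing"])
        _reject_unknown(t, _TIMING_KEYS, "timing")
        if "steady_gate" in t:
            t["steady_gate"] = tuple(float(v) for v in t["steady_gate"])
        if "decay_gate" in t:
            t["decay_gate"] = tuple(float(v) for v in t["decay_gate"])
        kwargs["timing"] = PulseTiming(**t)  # validates gate/pulse ordering
    if "noise" in raw:
        n = dict(raw["noise"])
        _reject_unknown(n, _NOISE_KEYS, "noise")
        kwargs["noise"] = NoiseModel(**n)
    if "channels" in raw:
        kwargs["channels"] = tuple(float(c) for c in raw["channels"])
    for key in ("lifetimes", "brightness"):
        if key in raw:
            kwargs[key] = {str(k): float(v) for k, v in dict(raw[key]).items()}
    for key in ("reference_tissue", "k", "min_run", "min_steady", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config (defaults made explicit) as YAML."""
    data = {
        "channels": [float(c) for c in config.channels],
        "timing": {
            "pulse_on": config.timing.pulse_on,
            "pulse_off": config.timing.pulse_off,
            "steady_gate": list(config.timing.steady_gate),
            "decay_gate": list(config.timing.decay_gate),
            "sample_dt": config.timing.sample_dt,
        },
        "noise": {
            "photon_scale": config.noise.photon_scale,
            "read_sigma": config.noise.read_sigma,
        },
        "lifetimes": dict(config.lifetimes),
        "brightness": dict(config.brightness),
        "reference_tissue": config.reference_tissue,
        "k": config.k,
        "min_run": config.min_run,
        "min_steady": config.min_steady,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
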