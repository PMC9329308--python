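"""Synthetic surgical-scene generator for DOCI analysis.

Composes labeled 2-D scenes (tumor surrounded by healthy tissues, or
parallel nerve bands with a perineural-invasion segment) and renders one
noisy time-resolved stack per spectral channel.  Each tissue class carries a
multi-exponential decay per channel; detected counts follow a standard CMOS
camera model — Poisson shot noise on the scaled noiseless intensity plus
additive Gaussian read noise, clipped at zero.

Default tissue lifetimes are synthetic: the murine autofluorescence decay
parameters behind the original measurements are not published, so defaults
only preserve the qualitative structure the analysis relies on — tumor
distinct from every healthy class, and invaded nerve with a strictly lower
amplitude-weighted lifetime than healthy nerve in every channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .decay import (
    DecayComponent,
    PulseTiming,
    amplitude_weighted_lifetime,
    trace,
)

__all__ = [
    "TISSUE_NAMES",
    "DEFAULT_CHANNELS",
    "DEFAULT_LIFETIMES",
    "TissueClass",
    "Rectangle",
    "Ellipse",
    "NerveBand",
    "NoiseModel",
    "PhantomSpec",
    "TimeResolvedStack",
    "render_label_map",
    "render_stacks",
    "default_tissues",
    "default_scene",
]

TISSUE_NAMES = frozenset(
    {"tumor", "muscle", "adipose", "dat", "nerve", "pni_nerve", "background"}
)

#: Emission band-pass channel centers (nm) under 365 nm excitation.
DEFAULT_CHANNELS: tuple[float, ...] = (405, 415, 434, 465, 494, 520, 542, 572, 605)

#: Default monoexponential lifetimes (ns).  Synthetic values; the only
#: orderings treated as load-bearing are pni_nerve < nerve and tumor
#: separated from every healthy class.
DEFAULT_LIFETIMES: dict[str, float] = {
    "tumor": 1.5,
    "pni_nerve": 1.8,
    "muscle": 2.5,
    "nerve": 4.0,
    "dat": 5.0,
    "adipose": 6.0,
}


@dataclass(frozen=True)
class TissueClass:
    """Optical description of one tissue class.

    ``components_by_channel`` maps channel wavelength (nm) to the decay
    mixture emitted into that band; ``brightness`` scales the plateau photon
    rate per pixel.  Background is the only class allowed brightness 0 (and
    may omit components entirely).
    """

    name: str
    components_by_channel: Mapping[float, tuple[DecayComponent, ...]]
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in TISSUE_NAMES:
            raise ValueError(f"unknown tissue name {self.name!r}")
        if self.name == "background":
            if self.brightness < 0:
                raise ValueError("background brightness must be >= 0")
            return
        if not (self.brightness > 0):
            raise ValueError(f"{self.name}: brightness must be > 0")
        for ch, comps in self.components_by_channel.items():
            if len(comps) == 0 or not any(c.amplitude > 0 for c in comps):
                raise ValueError(
                    f"{self.name}: channel {ch} needs >= 1 component with amplitude > 0"
                )

    def components(self, channel: float) -> tuple[DecayComponent, ...]:
        try:
            return tuple(self.components_by_channel[channel])
        except KeyError:
            raise KeyError(
                f"tissue {self.name!r} has no decay parameters for channel {channel}"
            ) from None


# ---------------------------------------------------------------------------
# Scene geometry.  0-based pixel indices, row-major, origin top-left.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned rectangle: rows [row0, row0+height), cols [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        _check_bounds(self.row0, self.row0 + self.height, shape[0], "rectangle rows")
        _check_bounds(self.col0, self.col0 + self.width, shape[1], "rectangle cols")
        m = np.zeros(shape, dtype=bool)
        m[self.row0 : self.row0 + self.height, self.col0 : self.col0 + self.width] = True
        return m


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse: pixels with ((r-row)/r_row)^2 + ((c-col)/r_col)^2 <= 1."""

    row: float
    col: float
    radius_row: float
    radius_col: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.radius_row <= 0 or self.radius_col <= 0:
            raise ValueError("ellipse radii must be positive")
        _check_bounds(
            int(np.floor(self.row - self.radius_row)),
            int(np.ceil(self.row + self.radius_row)) + 1,
            shape[0],
            "ellipse rows",
        )
        _check_bounds(
            int(np.floor(self.col - self.radius_col)),
            int(np.ceil(self.col + self.radius_col)) + 1,
            shape[1],
            "ellipse cols",
        )
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        return ((rr - self.row) / self.radius_row) ** 2 + (
            (cc - self.col) / self.radius_col
        ) ** 2 <= 1.0


@dataclass(frozen=True)
class NerveBand:
    """Axis-aligned nerve band with an optional healthy-to-invaded transition.

    For ``axis='h'`` the band occupies rows ``[offset, offset+width)`` and
    runs along columns ``[start, stop)``; the axial coordinate is the column
    index.  For ``axis='v'`` rows and columns swap roles.  When
    ``transition`` is set, axial positions >= transition take the
    ``pni_nerve`` label instead of the band's own label.
    """

    offset: int
    width: int
    start: int
    stop: int
    transition: int | None = None
    axis: str = "h"

    def __post_init__(self) -> None:
        if self.axis not in ("h", "v"):
            raise ValueError("axis must be 'h' or 'v'")
        if self.transition is not None and not (self.start <= self.transition < self.stop):
            raise ValueError(
                f"transition {self.transition} outside band extent "
                f"[{self.start}, {self.stop})"
            )

    def _bounds(self, shape: tuple[int, int]) -> None:
        along = shape[1] if self.axis == "h" else shape[0]
        across = shape[0] if self.axis == "h" else shape[1]
        _check_bounds(self.offset, self.offset + self.width, across, "nerve band width")
        _check_bounds(self.start, self.stop, along, "nerve band extent")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        self._bounds(shape)
        m = np.zeros(shape, dtype=bool)
        if self.axis == "h":
            m[self.offset : self.offset + self.width, self.start : self.stop] = True
        else:
            m[self.start : self.stop, self.offset : self.offset + self.width] = True
        return m

    def segment_masks(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """(healthy segment, invaded segment) masks; invaded empty if no transition."""
        m = self.mask(shape)
        if self.transition is None:
            return m, np.zeros(shape, dtype=bool)
        axial = np.arange(shape[1] if self.axis == "h" else shape[0])
        past = axial >= self.transition
        pni = m.copy()
        if self.axis == "h":
            pni[:, ~past] = False
        else:
            pni[~past, :] = False
        return m & ~pni, pni


def _check_bounds(lo: int, hi: int, extent: int, what: str) -> None:
    if lo < 0 or hi > extent or hi <= lo:
        raise ValueError(f"{what}: [{lo}, {hi}) outside frame extent {extent}")


Geometry = Rectangle | Ellipse | NerveBand


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: Poisson(photon_scale * intensity) + N(0, read_sigma).

    ``photon_scale`` is the photon count corresponding to unit noiseless
    intensity; ``None`` disables shot noise entirely (noiseless rendering).
    ``read_sigma`` is the Gaussian read-noise standard deviation in counts.
    """

    photon_scale: float | None = 1e4
    read_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.photon_scale is not None and not (self.photon_scale > 0):
            raise ValueError("photon_scale must be positive or None")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description: geometry, channels, noise and RNG seed."""

    shape: tuple[int, int]
    regions: tuple[tuple[str, Geometry], ...]
    channels: tuple[float, ...] = DEFAULT_CHANNELS
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != len(set(self.channels)):
            raise ValueError("channels must be unique")
        for name, _ in self.regions:
            if name not in TISSUE_NAMES:
                raise ValueError(f"region label {name!r} is not a tissue name")


@dataclass
class TimeResolvedStack:
    """One channel's detected counts: frames (time, row, col) on a time grid."""

    channel: float
    time_grid: np.ndarray
    frames: np.ndarray
    timing: PulseTiming

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.frames.shape[0] != self.time_grid.size:
            raise ValueError("number of frames must match time grid length")
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("frames must be non-negative")


def render_label_map(spec: PhantomSpec) -> tuple[np.ndarray, dict[int, str]]:
    """Rasterize the scene into an integer label map plus a legend.

    Deterministic: later regions overwrite earlier ones; unassigned pixels
    are background (label 0).  A nerve band with a transition contributes
    its own label up to the transition and ``pni_nerve`` beyond it.
    """
    labels = np.zeros(spec.shape, dtype=np.int32)
    legend: dict[int, str] = {0: "background"}
    ids: dict[str, int] = {"background": 0}

    def _id(name: str) -> int:
        if name not in ids:
            ids[name] = max(legend) + 1
            legend[ids[name]] = name
        return ids[name]

    for name, geom in spec.regions:
        if isinstance(geom, NerveBand) and geom.transition is not None:
            healthy, invaded = geom.segment_masks(spec.shape)
            labels[healthy] = _id(name)
            labels[invaded] = _id("pni_nerve")
        else:
            labels[geom.mask(spec.shape)] = _id(name)
    return labels, legend


def _validate_tissues(
    tissues: Mapping[str, TissueClass],
    legend: Mapping[int, str],
    channels: Sequence[float],
) -> None:
    for name in legend.values():
        if name not in tissues:
            raise ValueError(f"no TissueClass supplied for label {name!r}")
        tc = tissues[name]
        if name == "background":
            continue
        for ch in channels:
            tc.components(ch)  # raises naming tissue and channel
    if "nerve" in tissues and "pni_nerve" in tissues:
        for ch in channels:
            try:
                awl_n = amplitude_weighted_lifetime(tissues["nerve"].components(ch))
                awl_p = amplitude_weighted_lifetime(tissues["pni_nerve"].components(ch))
            except KeyError:
                continue
            if not awl_p < awl_n:
                raise ValueError(
                    f"pni_nerve mean lifetime must be below nerve at channel {ch} "
                    f"({awl_p} ns vs {awl_n} ns)"
                )


def render_stacks(
    spec: PhantomSpec,
    tissues: Mapping[str, TissueClass],
    timing: PulseTiming | None = None,
) -> list[TimeResolvedStack]:
    """Render one noisy time-resolved stack per channel.

    Every pixel of a tissue shares the same noiseless trace (class decay
    times brightness); noise is drawn independently per pixel and per frame.
    Channel stacks use independent substreams spawned from the spec seed, so
    output is bit-reproducible for a given spec.
    """
    timing = timing or PulseTiming()
    labels, legend = render_label_map(spec)
    _validate_tissues(tissues, legend, spec.channels)
    grid = timing.time_grid()
    n_t = grid.size
    n_pix = labels.size
    flat = labels.ravel()
    pixel_idx = {lid: np.flatnonzero(flat == lid) for lid in legend}

    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.channels))
    stacks: list[TimeResolvedStack] = []
    for ch, stream in zip(spec.channels, streams):
        rng = np.random.default_rng(stream)
        counts = np.zeros((n_t, n_pix), dtype=np.float32)
        for lid in sorted(legend):
            name = legend[lid]
            idx = pixel_idx[lid]
            if idx.size == 0:
                continue
            tc = tissues[name]
            if name == "background" or tc.brightness == 0:
                continue  # zero noiseless signal; read noise added below
            base = tc.brightness * trace(tc.components(ch), timing, grid)
            if spec.noise.photon_scale is None:
                counts[:, idx] = base[:, None].astype(np.float32)
            else:
                lam = spec.noise.photon_scale * base
                block = np.empty((n_t, idx.size), dtype=np.float32)
                for ti in range(n_t):
                    if lam[ti] <= 0:
                        block[ti] = 0.0
                    else:
                        block[ti] = rng.poisson(lam[ti], idx.size)
                counts[:, idx] = block
        if spec.noise.read_sigma > 0:
            counts += np.float32(spec.noise.read_sigma) * rng.standard_normal(
                counts.shape, dtype=np.float32
            )
            np.clip(counts, 0.0, None, out=counts)
        stacks.append(
            TimeResolvedStack(
                channel=ch,
                time_grid=grid,
                frames=counts.reshape(n_t, *spec.shape),
                timing=timing,
            )
        )
    return stacks


def default_tissues(
    channels: Sequence[float] = DEFAULT_CHANNELS,
    lifetimes: Mapping[str, float] | None = None,
    brightness: Mapping[str, float] | None = None,
) -> dict[str, TissueClass]:
    """Monoexponential tissue table at the default lifetimes.

    Amplitudes are channel-uniform by default; per-channel spectra can be
    introduced by overriding the returned classes.
    """
    lifetimes = dict(DEFAULT_LIFETIMES if lifetimes is None else lifetimes)
    brightness = dict(brightness or {})
    out: dict[str, TissueClass] = {
        "background": TissueClass("background", {}, brightness=0.0)
    }
    for name, tau in lifetimes.items():
        comps = {
            float(ch): (DecayComponent(amplitude=1.0, lifetime=float(tau)),)
            for ch in channels
        }
        out[name] = TissueClass(name, comps, brightness=brightness.get(name, 1.0))
    return out


# Margin-scene layout: one row of disjoint square patches per tissue, each
# patch one ROI instance (>= 200 px), mirroring independent specimens.
_MARGIN_TISSUES = ("tumor", "muscle", "adipose", "dat")


def default_scene(
    kind: str,
    seed: int = 0,
    *,
    noise: NoiseModel | None = None,
    channels: Sequence[float] = DEFAULT_CHANNELS,
    n_instances: int = 15,
    instance_size: int = 15,
    gap: int = 3,
    band_width: int = 8,
    band_length: int = 64,
    transition: int = 32,
) -> tuple[PhantomSpec, dict[str, TissueClass]]:
    """Build a default study scene and its tissue table.

    ``kind='margin'`` lays out ``n_instances`` disjoint patches for each of
    tumor, muscle, adipose and DAT (each patch one ROI instance of
    ``instance_size**2`` pixels).  ``kind='pni'`` lays out two parallel
    nerve bands: a control band of uniform healthy nerve and a test band
    that switches to invaded nerve at the configured ``transition`` column.
    """
    noise = noise if noise is not None else NoiseModel()
    channels = tuple(float(c) for c in channels)
    if kind == "margin":
        step = instance_size + gap
        shape = (gap + len(_MARGIN_TISSUES) * step, gap + n_instances * step)
        regions: list[tuple[str, Geometry]] = []
        for r, name in enumerate(_MARGIN_TISSUES):
            for i in range(n_instances):
                regions.append(
                    (
                        name,
                        Rectangle(
                            row0=gap + r * step,
                            col0=gap + i * step,
                            height=instance_size,
                            width=instance_size,
                        ),
                    )
                )
        spec = PhantomSpec(
            shape=shape,
            regions=tuple(regions),
            channels=channels,
            noise=noise,
            seed=seed,
        )
        return spec, default_tissues(channels)
    if kind == "pni":
        shape = (48, band_length)
        control = NerveBand(offset=8, width=band_width, start=0, stop=band_length)
        test = NerveBand(
            offset=30,
            width=band_width,
            start=0,
            stop=band_length,
            transition=transition,
        )
        spec = PhantomSpec(
            shape=shape,
            regions=(("nerve", control), ("nerve", test)),
            channels=channels,
            noise=noise,
            seed=seed,
        )
        return spec, default_tissues(channels)
    raise ValueError(f"unknown scene kind {kind!r} (expected 'margin' or 'pni')")
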