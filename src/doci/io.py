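"""File-format layer: TIFF stacks, label maps, DOCI maps and JSON sidecars.

Raw time-resolved stacks are written as one multi-page TIFF per channel
(pages = time frames, 16-bit unsigned counts) with a JSON sidecar carrying
the time grid, pulse/gate timing, channel list, seed, legend, noise
parameters and any nerve-band geometry.  DOCI maps are written as 32-bit
float TIFFs with 8-bit validity masks.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .core import DOCIImage
from .decay import PulseTiming
from .phantom import NerveBand, NoiseModel, PhantomSpec, TimeResolvedStack

__all__ = [
    "write_scene",
    "read_scene",
    "write_doci",
    "read_doci",
    "write_label_map",
    "read_label_map",
]

SIDECAR = "scene.json"
DOCI_META = "doci.json"
LABELS = "labels.tif"


def _chname(channel: float) -> str:
    return f"{channel:g}"


def write_label_map(path: str | Path, label_map: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(label_map, dtype=np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_scene(
    outdir: str | Path,
    stacks: Sequence[TimeResolvedStack],
    label_map: np.ndarray,
    legend: Mapping[int, str],
    spec: PhantomSpec,
) -> None:
    """Write channel stacks, the label map and the JSON sidecar to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stack in stacks:
        counts = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max)
        tifffile.imwrite(
            out / f"stack_{_chname(stack.channel)}nm.tif",
            counts.astype(np.uint16),
        )
    write_label_map(out / LABELS, label_map)

    timing = stacks[0].timing if stacks else PulseTiming()
    bands = [
        {"label": name, **asdict(geom)}
        for name, geom in spec.regions
        if isinstance(geom, NerveBand)
    ]
    sidecar = {
        "channels": [float(s.channel) for s in stacks],
        "time_grid": [float(t) for t in (stacks[0].time_grid if stacks else [])],
        "timing": {
            "pulse_on": timing.pulse_on,
            "pulse_off": timing.pulse_off,
            "steady_gate": list(timing.steady_gate),
            "decay_gate": list(timing.decay_gate),
            "sample_dt": timing.sample_dt,
        },
        "noise": {
            "photon_scale": spec.noise.photon_scale,
            "read_sigma": spec.noise.read_sigma,
        },
        "seed": spec.seed,
        "shape": list(spec.shape),
        "legend": {str(k): v for k, v in legend.items()},
        "bands": bands,
    }
    (out / SIDECAR).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_scene(indir: str | Path):
    """Read a scene directory back into stacks, label map, legend and metadata.

    Returns ``(stacks, label_map, legend, meta)`` where ``meta`` holds the
    parsed timing, noise model and any nerve bands.
    """
    indir = Path(indir)
    sidecar_path = indir / SIDECAR
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no {SIDECAR} in {indir}")
    side = json.loads(sidecar_path.read_text())
    t = side["timing"]
    timing = PulseTiming(
        pulse_on=t["pulse_on"],
        pulse_off=t["pulse_off"],
        steady_gate=tuple(t["steady_gate"]),
        decay_gate=tuple(t["decay_gate"]),
        sample_dt=t["sample_dt"],
    )
    grid = np.asarray(side["time_grid"], dtype=float)
    stacks = []
    for ch in side["channels"]:
        frames = tifffile.imread(indir / f"stack_{_chname(ch)}nm.tif").astype(
            np.float32
        )
        stacks.append(
            TimeResolvedStack(channel=float(ch), time_grid=grid, frames=frames,
                              timing=timing)
        )
    label_map = read_label_map(indir / LABELS)
    legend = {int(k): v for k, v in side["legend"].items()}
    bands = [
        (b["label"], NerveBand(**{k: v for k, v in b.items() if k != "label"}))
        for b in side.get("bands", [])
    ]
    meta = {
        "timing": timing,
        "noise": NoiseModel(**side["noise"]),
        "seed": side["seed"],
        "bands": bands,
    }
    return stacks, label_map, legend, meta


def write_doci(outdir: str | Path, images: Sequence[DOCIImage]) -> None:
    """Write DOCI maps (32-bit float) and masks (8-bit) plus a metadata JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for img in images:
        name = _chname(img.channel)
        tifffile.imwrite(out / f"doci_{name}nm.tif", img.values.astype(np.float32))
        tifffile.imwrite(
            out / f"mask_{name}nm.tif", img.valid_mask.astype(np.uint8)
        )
    meta = {
        "channels": [float(i.channel) for i in images],
        "thresholds": {_chname(i.channel): i.threshold_used for i in images},
    }
    (out / DOCI_META).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_doci(indir: str | Path) -> list[DOCIImage]:
    indir = Path(indir)
    meta = json.loads((indir / DOCI_META).read_text())
    images = []
    for ch in meta["channels"]:
        name = _chname(ch)
        values = tifffile.imread(indir / f"doci_{name}nm.tif").astype(float)
        mask = tifffile.imread(indir / f"mask_{name}nm.tif").astype(bool)
        images.append(
            DOCIImage(
                channel=float(ch),
                values=values,
                valid_mask=mask,
                threshold_used=meta["thresholds"][name],
            )
        )
    return images
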