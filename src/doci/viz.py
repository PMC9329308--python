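"""Pseudo-color rendering of DOCI maps — a pure view layer.

Two policies: ``continuous`` maps one channel's DOCI values through a
colormap over a fixed range, and ``tissue_classified`` assigns each pixel
the color of the configured tissue whose expected DOCI value is nearest
(tumor green, muscle blue, adipose red by default).  Masked pixels render
black in both modes.  Rendering never alters analysis outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import matplotlib
import numpy as np

from .core import DOCIImage

__all__ = ["ColorPolicy", "DEFAULT_CLASS_COLORS", "render_pseudocolor"]

DEFAULT_CLASS_COLORS: dict[str, tuple[int, int, int]] = {
    "tumor": (0, 200, 0),
    "muscle": (40, 80, 220),
    "adipose": (220, 50, 50),
    "dat": (235, 150, 40),
    "nerve": (240, 220, 60),
    "pni_nerve": (170, 60, 200),
}


@dataclass(frozen=True)
class ColorPolicy:
    """How DOCI values become colors.

    ``continuous`` uses ``colormap`` over ``colormap_range=(lo, hi)``;
    ``tissue_classified`` uses ``class_colors``.
    """

    mode: str = "continuous"
    class_colors: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COLORS)
    )
    colormap: str = "viridis"
    colormap_range: tuple[float, float] = (0.0, 0.15)

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "tissue_classified"):
            raise ValueError(f"unknown mode {self.mode!r}")
        lo, hi = self.colormap_range
        if not lo < hi:
            raise ValueError("colormap_range must satisfy lo < hi")
        seen: dict[tuple[int, int, int], str] = {}
        for name, rgb in self.class_colors.items():
            rgb = tuple(int(v) for v in rgb)
            if rgb in seen:
                raise ValueError(
                    f"classes {seen[rgb]!r} and {name!r} share color {rgb}"
                )
            seen[rgb] = name


def render_pseudocolor(
    doci: DOCIImage,
    policy: ColorPolicy,
    class_doci: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Render one DOCI map to an 8-bit RGB image.

    For ``tissue_classified`` mode, ``class_doci`` maps tissue names to
    their expected DOCI values at this channel; each valid pixel takes the
    color of the nearest class.  Every class in ``class_doci`` must have a
    color in the policy.
    """
    h, w = doci.values.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    valid = doci.valid_mask

    if policy.mode == "continuous":
        lo, hi = policy.colormap_range
        frac = np.clip((doci.values - lo) / (hi - lo), 0.0, 1.0)
        cmap = matplotlib.colormaps[policy.colormap]
        colored = (cmap(frac)[..., :3] * 255).round().astype(np.uint8)
        rgb[valid] = colored[valid]
        return rgb

    if class_doci is None or not class_doci:
        raise ValueError("tissue_classified mode needs per-class DOCI values")
    names = list(class_doci)
    missing = [n for n in names if n not in policy.class_colors]
    if missing:
        raise ValueError(f"no color configured for tissue(s): {missing}")
    centers = np.array([class_doci[n] for n in names], dtype=float)
    colors = np.array([policy.class_colors[n] for n in names], dtype=np.uint8)
    nearest = np.abs(doci.values[..., None] - centers).argmin(axis=-1)
    rgb[valid] = colors[nearest[valid]]
    return rgb
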