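"""ROI statistics: tumor-normalized relative lifetimes and significance maps.

The sampling unit is one ROI *instance* — a connected region of one tissue
label, standing in for one specimen — never a pixel; per-pixel testing would
grossly inflate significance.  Per channel, each tissue's instance means are
normalized against the reference tissue (tumor by default) and tested
against 1 with a one-sample t-test, reproducing the Manhattan-plot view of
per-channel p-values with significance at p < 0.05.

Normalization pairs each instance with the reference instance of the same
scene position (per-specimen normalization) whenever the instance counts
match; this keeps the reference's estimation noise out of the test
statistic, so the t-test stays calibrated.  Grand-mean normalization is
available as a fallback and an explicit option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .core import DOCIImage

__all__ = [
    "ROISet",
    "roi_means",
    "normalize_to_reference",
    "one_sample_t",
    "significance_sweep",
    "TissueContrast",
    "TissueContrastResults",
]


@dataclass(frozen=True)
class ROISet:
    """Tissue label map plus legend and the reference tissue for normalization."""

    label_map: np.ndarray
    legend: Mapping[int, str]
    reference_tissue: str = "tumor"

    def __post_init__(self) -> None:
        if self.reference_tissue not in self.legend.values():
            raise ValueError(
                f"reference tissue {self.reference_tissue!r} absent from legend"
            )

    def tissue_ids(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for lid, name in self.legend.items():
            if name != "background":
                out.setdefault(name, []).append(lid)
        return out


def roi_means(doci: DOCIImage, rois: ROISet) -> dict[str, list[float]]:
    """Per-tissue list of per-instance mean DOCI values.

    An instance is one 4-connected region of a tissue label.  Masked pixels
    are excluded from the mean; an instance with no valid pixel is dropped
    with a warning.
    """
    out: dict[str, list[float]] = {}
    valid = doci.valid_mask
    for name, ids in rois.tissue_ids().items():
        region = np.isin(rois.label_map, ids)
        comp, n_comp = ndimage.label(region)
        means: list[float] = []
        for i in range(1, n_comp + 1):
            m = (comp == i) & valid
            if not m.any():
                warnings.warn(
                    f"ROI instance {i} of {name!r} has no valid pixels; dropped",
                    stacklevel=2,
                )
                continue
            means.append(float(doci.values[m].mean()))
        out[name] = means
    return out


def normalize_to_reference(
    means_by_tissue: Mapping[str, Sequence[float]],
    reference_tissue: str = "tumor",
    paired: bool = False,
) -> dict[str, np.ndarray]:
    """Normalize each tissue's instance means against the reference tissue.

    ``paired=False`` divides every sample by the reference's grand mean at
    this channel, so the reference normalizes to mean exactly 1.
    ``paired=True`` divides instance *i* of each tissue by reference
    instance *i* (per-specimen normalization); it requires matching
    instance counts and falls back to grand-mean normalization with a
    warning when they differ.
    """
    if reference_tissue not in means_by_tissue:
        raise ValueError(f"reference tissue {reference_tissue!r} not in table")
    ref = np.asarray(means_by_tissue[reference_tissue], dtype=float)
    if ref.size == 0 or not np.all(ref > 0):
        raise ValueError("reference tissue has no positive instance means")

    out: dict[str, np.ndarray] = {}
    for name, vals in means_by_tissue.items():
        v = np.asarray(vals, dtype=float)
        if paired:
            if v.size == ref.size:
                out[name] = v / ref
                continue
            warnings.warn(
                f"{name!r}: {v.size} instances vs {ref.size} reference instances; "
                "using grand-mean normalization",
                stacklevel=2,
            )
        out[name] = v / ref.mean()
    return out


def one_sample_t(
    samples: Sequence[float], null_value: float = 1.0
) -> tuple[float, int, float | None]:
    """Two-sided one-sample t-test of the mean against ``null_value``.

    Returns ``(t, df, p)``; ``p`` is None (reported absent) when n < 2 or
    the sample variance is zero, so noiseless degenerate inputs stay
    runnable rather than raising.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    df = max(n - 1, 0)
    if n < 2:
        return float("nan"), df, None
    sd = x.std(ddof=1)
    if sd == 0:
        return float("nan"), df, None
    t = (x.mean() - null_value) / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


class TissueContrast:
    """Model for tissue-vs-reference relative-lifetime contrast.

    Built from per-channel DOCI images and an ROI set; ``fit()`` runs the
    full sweep — instance means, reference normalization and per-tissue,
    per-channel one-sample t-tests — and returns a
    :class:`TissueContrastResults`.
    """

    def __init__(
        self,
        doci_images: Sequence[DOCIImage],
        rois: ROISet,
        paired: bool = True,
    ) -> None:
        channels = [img.channel for img in doci_images]
        if len(set(channels)) != len(channels):
            raise ValueError("duplicate channels among DOCI images")
        if not channels:
            raise ValueError("need at least one DOCI image")
        self.doci_images = list(doci_images)
        self.rois = rois
        self.paired = paired

    @classmethod
    def from_label_map(
        cls,
        doci_images: Sequence[DOCIImage],
        label_map: np.ndarray,
        legend: Mapping[int, str],
        reference_tissue: str = "tumor",
        paired: bool = True,
    ) -> "TissueContrast":
        return cls(doci_images, ROISet(label_map, legend, reference_tissue), paired)

    def fit(self) -> "TissueContrastResults":
        ref = self.rois.reference_tissue
        rows = []
        raw_by_channel: dict[float, dict[str, list[float]]] = {}
        for img in self.doci_images:
            means = roi_means(img, self.rois)
            if len(means.get(ref, [])) == 0:
                raise ValueError(
                    f"reference tissue {ref!r} has no valid ROI instance at "
                    f"channel {img.channel}"
                )
            raw_by_channel[img.channel] = means
            norm = normalize_to_reference(means, ref, paired=self.paired)
            for tissue, vals in norm.items():
                raw = np.asarray(means[tissue], dtype=float)
                if tissue == ref:
                    t = np.nan
                    df = max(raw.size - 1, 0)
                    p = None
                else:
                    t, df, p = one_sample_t(vals, null_value=1.0)
                rows.append(
                    {
                        "tissue": tissue,
                        "channel_nm": img.channel,
                        "n": raw.size,
                        "mean_doci": raw.mean() if raw.size else np.nan,
                        "normalized_mean": float(np.mean(vals)) if vals.size else np.nan,
                        "t": t,
                        "df": df,
                        "p": np.nan if p is None else p,
                    }
                )
        table = pd.DataFrame(rows)
        # BH-corrected q-values are informational; the significance flag uses
        # raw per-channel p-values against 0.05.
        tested = table["p"].notna()
        table["q"] = np.nan
        if tested.any():
            table.loc[tested, "q"] = multipletests(
                table.loc[tested, "p"].to_numpy(), method="fdr_bh"
            )[1]
        return TissueContrastResults(
            table=table,
            reference_tissue=ref,
            raw_means=raw_by_channel,
            alpha=0.05,
        )


@dataclass
class TissueContrastResults:
    """Fitted tissue-contrast sweep: the stats table plus derived views."""

    table: pd.DataFrame
    reference_tissue: str
    raw_means: dict[float, dict[str, list[float]]]
    alpha: float = 0.05

    @property
    def channels(self) -> list[float]:
        return sorted(self.table["channel_nm"].unique())

    def contrast_scores(self) -> pd.Series:
        """Per-channel contrast: mean pairwise |difference| of normalized means.

        Used to rank channels by tissue-discrimination strength (the band
        with the greatest contrast is the natural calling channel).
        """
        scores = {}
        for ch, grp in self.table.groupby("channel_nm"):
            m = grp["normalized_mean"].to_numpy(dtype=float)
            if m.size < 2:
                scores[ch] = 0.0
                continue
            diffs = np.abs(m[:, None] - m[None, :])
            scores[ch] = float(diffs[np.triu_indices(m.size, k=1)].mean())
        return pd.Series(scores).sort_index()

    @property
    def best_channel(self) -> float:
        return float(self.contrast_scores().idxmax())

    def manhattan_data(self) -> pd.DataFrame:
        """-log10 p per tissue per channel, with the alpha threshold line."""
        d = self.table[self.table["tissue"] != self.reference_tissue].copy()
        d = d[d["p"].notna()]
        d["neg_log10_p"] = -np.log10(d["p"].clip(lower=np.finfo(float).tiny))
        d["threshold"] = -np.log10(self.alpha)
        d["significant"] = d["p"] < self.alpha
        return d[
            ["tissue", "channel_nm", "p", "neg_log10_p", "threshold", "significant"]
        ].reset_index(drop=True)

    def plot_manhattan(self, ax=None):
        """Manhattan plot of -log10 p across channels, one series per tissue."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        d = self.manhattan_data()
        for tissue, grp in d.groupby("tissue"):
            ax.plot(grp["channel_nm"], grp["neg_log10_p"], "o-", label=tissue)
        ax.axhline(-np.log10(self.alpha), color="gray", ls="--", lw=1)
        ax.set_xlabel("channel (nm)")
        ax.set_ylabel(r"$-\log_{10} p$")
        ax.legend(fontsize=8)
        return ax

    def summary(self) -> str:
        lines = [
            "Tissue contrast vs reference "
            f"'{self.reference_tissue}' ({len(self.channels)} channels)",
            "",
            self.table.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
            "",
            "Per-channel contrast scores:",
            self.contrast_scores().to_string(float_format=lambda v: f"{v:.4g}"),
            f"Best channel: {self.best_channel:g} nm",
        ]
        return "\n".join(lines)


def significance_sweep(
    doci_images: Sequence[DOCIImage],
    rois: ROISet,
    paired: bool = True,
) -> TissueContrastResults:
    """Functional entry point for the full tissue-contrast sweep."""
    return TissueContrast(doci_images, rois, paired=paired).fit()
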