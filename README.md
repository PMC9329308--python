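# doci — dynamic optical contrast imaging analysis

`doci` implements the analysis pipeline behind dynamic optical contrast
imaging (DOCI), a label-free intraoperative imaging method for head and neck
cancer surgery.  Tissue autofluorescence (NADH, FAD, collagen) is excited
with a square 365 nm pulse and resolved into 9 emission band-pass channels
(405–605 nm); malignant tissue has altered fluorophore composition and hence
altered fluorescence decay, so a per-pixel *relative lifetime* map separates
tumor from muscle, adipose tissue, dermal adipose tissue (DAT) and nerve —
and flags nerve segments harboring perineural invasion (PNI), which show
lower relative lifetimes than healthy nerve.

The package is aimed at readers who want to study, extend or stress-test
this class of time-gated lifetime-contrast analysis.  Because the original
in vivo murine image data are not publicly available, the pipeline ships
with a physics-based synthetic phantom generator that emulates the study
designs (tumor-margin scenes with 15 specimens per tissue; paired
control/invaded sciatic-nerve scenes) and is itself a tested, first-class
component.

## The statistic

For a pixel whose emission is a multi-exponential decay
`I(t) = Σᵢ aᵢ(1 − e^{−(t−t_on)/τᵢ})` during the pulse, the DOCI value is the
ratio of two gated integrals of the detected time course,

```
D = ∫_decay I(t) dt  /  ∫_steady I(t) dt ,
```

with the steady-state gate `[50, 100) ns` late in the 100 ns pulse and the
decay gate `[100, 200) ns` after turn-off.  No per-pixel curve fitting is
involved.  In the long-gate limit `D → (Σ aᵢτᵢ / Σ aᵢ) / W_ss`: the
amplitude-weighted mean lifetime divided by the steady-gate width, which is
why D reads as a relative lifetime.  Intensity cancels in the ratio, so the
map is insensitive to illumination and concentration.

Downstream statistics follow the original study design: per tissue and per
channel, ROI-instance means (one connected region = one specimen) are
normalized against the tumor value and tested against 1 with a two-sided
one-sample t-test; significance is read per channel at p < 0.05 in a
Manhattan-plot layout.  PNI calling extracts the DOCI profile along a nerve
axis, calibrates a threshold on control nerves (mean − 3 sd) and calls
invasion when ≥ 5 consecutive positions fall below it; the first such
position localizes the healthy→invaded transition.

## Worked example

```python
from doci import (PulseTiming, ROISet, compute_all_channels,
                  default_min_steady, default_scene, render_label_map,
                  render_stacks, significance_sweep)

timing = PulseTiming()
spec, tissues = default_scene("margin", seed=7, channels=(465.0,), n_instances=5)
stacks = render_stacks(spec, tissues, timing)
images = compute_all_channels(stacks, min_steady=default_min_steady(2.0, timing))
labels, legend = render_label_map(spec)
result = significance_sweep(images, ROISet(labels, legend, "tumor"))
print(result.summary())
```

prints

```
Tissue contrast vs reference 'tumor' (1 channels)

 tissue  channel_nm  n  mean_doci  normalized_mean    t  df         p         q
  tumor         465  5    0.03042                1  NaN   4       NaN       NaN
 muscle         465  5    0.05029            1.654 2233   4 2.413e-13 2.413e-13
adipose         465  5     0.1202             3.95 3306   4 5.025e-14 7.537e-14
    dat         465  5     0.1002            3.293 5082   4 8.997e-15 2.699e-14

Per-channel contrast scores:
465.0   1.748
Best channel: 465 nm
```

Each row is one tissue at the 465 nm channel: `mean_doci` is the mean
relative-lifetime value over its 5 ROI instances, `normalized_mean` the
tumor-normalized value (muscle ≈ 1.65× tumor, adipose ≈ 3.9×, tracking the
configured lifetime ratios), and `p` the one-sample t-test of the normalized
instance values against 1 — every healthy tissue separates from tumor far
below the 0.05 threshold.  The contrast score (mean pairwise separation of
normalized means) ranks channels for downstream calling.

The same pipeline detects perineural invasion:

```python
from doci.experiments import pni_batch
print(pni_batch(list(range(1, 7))).summary())
```

classifies 6 control and 6 invaded simulated nerves — with the threshold
calibrated only on the controls — at `accuracy=1.000`, localizes every
transition at the configured column 32, and separates invaded from control
scores at p = 4.2e-19.

A command-line pipeline wraps the same functions:

```
doci simulate --scene pni --seed 1 --out scene/
doci compute  --in scene/ --out maps/
doci pni      --doci maps/ --labels scene/labels.tif --out calls/
doci render   --doci maps/ --out view.tif --mode continuous
```

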