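# Methods

## Signal model

Each pixel's autofluorescence is modelled as a mixture of exponential decays
under square-pulse excitation.  A component with amplitude `a` and lifetime
`τ` (ns) rises as `a(1 − e^{−(t−t_on)/τ})` while the pulse is on and decays
as its attained plateau times `e^{−(t−t_off)/τ}` afterwards.  `τ = 0` is an
admitted degenerate case (tracks the pulse, no tail), which makes the
zero-DOCI limit testable.  Time is continuous in nanoseconds; integration
gates are half-open `[a, b)` so adjacent gates partition the axis.

The DOCI value is the ratio of the trapezoidal integral of the detected
counts over the decay gate to that over the steady-state gate.  The
implementation closes the final trapezoid at a grid sample lying exactly on
the gate's right edge, so adjacent gates tile the time axis without double
counting and a constant signal over a 50 ns gate integrates to exactly 50.
`doci_closed_form` evaluates the exact gated integrals of the model
(including finite-pulse plateau corrections), and is the oracle the gated
integrator is tested against.

### Timing defaults

| parameter | default | rationale |
|---|---|---|
| pulse | `[0, 100) ns` | ≥ 16 lifetimes of the slowest default tissue: plateau error < 1e−7 |
| steady gate | `[50, 100) ns` | late-pulse plateau, width W_ss = 50 ns |
| decay gate | `[100, 200) ns` | captures > 99.99% of the tail for ns-scale fluorophores |
| sample_dt | 0.5 ns | 401 frames per stack; see "Numerical choices" |

The original instrument's gate durations are not published; these are
declared package defaults, all overridable through `RunConfig`/YAML.

## Synthetic phantoms

The generator composes labeled 2-D scenes (0-based pixel indices, row-major,
origin top-left) from rectangles, ellipses and axis-aligned nerve bands, and
renders one time-resolved stack per emission channel (9 bands, 405–605 nm).
Detected counts follow a standard CMOS model: `Poisson(photon_scale ×
noiseless intensity) + N(0, read_sigma)`, clipped at zero; defaults
`photon_scale = 1e4`, `read_sigma = 2` counts.  Channels use independent RNG
substreams spawned from the scene seed, so rendering is bit-reproducible.
Poisson draws are grouped by (tissue, frame) — all pixels of a tissue share
one rate per frame — which is distributionally identical to per-pixel draws
and much faster.

Default tissue lifetimes (ns, monoexponential, channel-uniform): tumor 1.5,
invaded nerve 1.8, muscle 2.5, nerve 4.0, DAT 5.0, adipose 6.0, brightness
1.0 everywhere.  These are synthetic: the murine autofluorescence decay
parameters behind the original measurements are not published, so the
generator claims only the qualitative structure the analysis relies on —
tumor distinct from every healthy class, and invaded nerve strictly below
healthy nerve in amplitude-weighted mean lifetime at every channel (the
latter is enforced as a validation invariant).  Channel-dependent spectra
can be configured per tissue; with the channel-uniform defaults, all 9
channels carry equal contrast, so which channel "wins" the contrast ranking
is configuration-driven rather than a reproduction of any particular band.

Two default scenes mirror the study designs.  The *margin* scene lays out
15 disjoint 15×15 px patches per tissue (tumor, muscle, adipose, DAT); each
patch is one ROI instance, mirroring one specimen of a 15-tumor study.  The
*PNI* scene holds two parallel 8 px-wide nerve bands: a control band of
uniform healthy nerve and a test band switching to invaded nerve at column
32 of 64, mirroring the paired PBS/tumor-injected sciatic-nerve design.

What the phantoms do **not** emulate: optical blur, spectral bleed-through,
3-D structure, motion, spatial heterogeneity within a tissue, and the true
(unknown) decay parameters of real tissue.  Passing tests therefore
establish the correctness and statistical calibration of the *pipeline*,
not quantitative performance on real surgical images.

## Masking and ROI statistics

Pixels whose steady-state integral falls below `min_steady` are masked
invalid (value 0 by convention); the default threshold is 5× the read-noise
scale of the steady integral, `5·σ_read·√(W_ss·dt)`.  Low signal is a mask
state, never an error.

The statistical sampling unit is one ROI instance (a 4-connected region of
one tissue label), never a pixel.  Per channel, instance means are
normalized against the tumor reference and tested against 1 with a
two-sided one-sample t-test; p-values are reported raw per channel
(significance at 0.05, Manhattan-plot layout), with Benjamini–Hochberg
q-values emitted as an informational column only.

Normalization pairs instance *i* of each tissue with reference instance *i*
(per-specimen normalization) whenever instance counts match.  This choice is
load-bearing: dividing by the reference's *grand mean* injects the
reference's estimation noise into every test statistic, inflating |t| by
≈ √(1 + n/m) under the null — with equal instance counts the measured
type-I rate was ~0.14 at α = 0.05 instead of 0.05.  Paired normalization
keeps the null ratio distribution centred on 1 (up to a negligible
second-order CV² bias) and measures calibrated (0.04–0.05 over 1000
replicates).  Grand-mean normalization remains available (`paired=False`)
and is the automatic fallback when instance counts differ.

Degenerate samples (n < 2 or zero variance, e.g. noiseless scenes) report
an absent p-value rather than raising.

## PNI detection

A nerve is interrogated through its axial DOCI profile (mean across the
band width per axial position, masked pixels excluded).  The decision
threshold is calibrated on control-nerve values as `mean − k·sd` (default
k = 3); a nerve is called invaded when ≥ `min_run` consecutive positions
(default 5) lie strictly below threshold, and the first position of the
first qualifying run is the reported transition.  The run-length rule
suppresses isolated noise dips; the per-nerve score is the mean over the
whole band, matching how an intact nerve would be interrogated.  This
quantitative rule is a declared surrogate — the original readout was visual
contrast — and k, `min_run` and the calling channel (default 465 nm) are
configurable.  Raising k can only move calls from "invaded" toward
"control" (tested as a property).

## Numerical choices

- Trapezoidal integration on the stored grid keeps results grid-density
  invariant and comparable to the analytic oracle.  At the default
  `dt = 0.5 ns` the trapezoid overestimates an exponential tail integral by
  `≈ dt²/(12τ²)` (+0.92% at τ = 1.5 ns, +0.23% at dt = 0.25 ns); oracle
  tests that demand ≤ 0.5% agreement with the closed form therefore sample
  at `dt ≤ 0.25 ns`.  The bias is common-mode across tissues at fixed dt
  and does not affect orderings or the normalized statistics' calibration.
- Negative decay integrals (possible under read noise) are clipped to 0, so
  valid DOCI values are non-negative.
- Masked pixels carry value 0 + mask false rather than NaN; all downstream
  consumers honour the mask.
- Ties in nearest-class pseudo-color assignment resolve to the first class
  in the configured order (argmin).

## Experiment scales

The packaged experiment runners use: 20 seeds × the 15-instance margin
scene for the significance re-creation; 10 batches × 6 scenes (6 control +
6 invaded nerves) for the PNI accuracy re-creation; 1000 replicates of a
reduced two-tissue scene (8 instances of 8×8 px, one channel) for type-I
calibration; and 100 scenes at photon scale 1e3 (threshold calibrated on 5
separate control scenes) for transition recovery.  These sizes give
binomial uncertainties comfortably inside the tolerances they are checked
against.

## Known limitations

- No instrument-response deconvolution, photobleaching kinetics or
  frequency-domain estimation; DOCI is deliberately a non-fitting method.
- Nerve bands are axis-aligned; curved-nerve centerline tracing is out of
  scope, as is estimating invasion depth or the minimum detectable lesion.
- The multi-channel color composition of the original display is not
  specified; classified rendering assigns each pixel the nearest configured
  class in DOCI space at a single calling channel.
- With channel-uniform default spectra, per-channel results are
  statistically independent replicas; cross-channel spectral structure must
  be configured explicitly to study channel selection.
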