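"""Reproducible study-scale experiments on the default synthetic scenes.

These runners re-create the two headline analyses end to end — the
tissue-vs-tumor significance sweep on the margin scene and the
control-vs-invaded nerve classification — plus the calibration experiments
(type-I error of the sweep, transition-point recovery) used to validate the
pipeline.  Every function is deterministic given its seed.
"""

from __future__ import annotations

from .core import compute_doci, compute_all_channels, default_min_steady
from .decay import PulseTiming
from .phantom import (
    NoiseModel,
    PhantomSpec,
    Rectangle,
    default_scene,
    default_tissues,
    render_label_map,
    render_stacks,
)
from .pni import PNIDetector, extract_profile
from .roi import ROISet, significance_sweep

__all__ = [
    "margin_max_p",
    "pni_batch",
    "calibrate_transition_threshold",
    "transition_trial",
    "type1_replicate",
]

#: Calling channel for the nerve analyses (the band reported to give the
#: greatest tissue contrast).
CALLING_CHANNEL = 465.0


def margin_max_p(
    seed: int,
    photon_scale: float = 1e4,
    n_instances: int = 15,
    timing: PulseTiming | None = None,
) -> float:
    """Worst (largest) tissue-vs-tumor p over all tissues and all 9 channels.

    Renders the default margin scene (tumor, muscle, adipose, DAT;
    ``n_instances`` ROI instances per tissue), computes DOCI images for
    every channel and runs the tumor-normalized significance sweep.
    """
    timing = timing or PulseTiming()
    noise = NoiseModel(photon_scale=photon_scale, read_sigma=2.0)
    spec, tissues = default_scene(
        "margin", seed=seed, noise=noise, n_instances=n_instances
    )
    stacks = render_stacks(spec, tissues, timing)
    min_steady = default_min_steady(noise.read_sigma, timing)
    images = compute_all_channels(stacks, min_steady=min_steady)
    labels, legend = render_label_map(spec)
    results = significance_sweep(images, ROISet(labels, legend, "tumor"))
    tested = results.table[results.table["p"].notna()]
    return float(tested["p"].max())


def pni_batch(
    seeds: list[int],
    photon_scale: float = 1e4,
    k: float = 3.0,
    min_run: int = 5,
    timing: PulseTiming | None = None,
):
    """Classify one batch of nerves: one control + one invaded per seed.

    Each seed renders the default PNI scene at the calling channel; the
    scene's uniform band is a control nerve and its transition band an
    invaded nerve.  The threshold is calibrated on the batch's control
    profiles (mean - k*sd) and every nerve is called with the run-length
    rule.  Returns the fitted :class:`~doci.pni.PNIDetectionResults`.
    """
    timing = timing or PulseTiming()
    noise = NoiseModel(photon_scale=photon_scale, read_sigma=2.0)
    profiles, is_control, truth = [], [], []
    for seed in seeds:
        spec, tissues = default_scene(
            "pni", seed=seed, noise=noise, channels=(CALLING_CHANNEL,)
        )
        stack = render_stacks(spec, tissues, timing)[0]
        img = compute_doci(
            stack, min_steady=default_min_steady(noise.read_sigma, timing)
        )
        for _, band in spec.regions:
            profiles.append(extract_profile(img, band))
            is_control.append(band.transition is None)
            truth.append("control" if band.transition is None else "pni")
    return PNIDetector(profiles, is_control, truth, k=k, min_run=min_run).fit()


def _pni_scene_image(seed, photon_scale, timing):
    noise = NoiseModel(photon_scale=photon_scale, read_sigma=2.0)
    spec, tissues = default_scene(
        "pni", seed=seed, noise=noise, channels=(CALLING_CHANNEL,)
    )
    stack = render_stacks(spec, tissues, timing)[0]
    img = compute_doci(
        stack, min_steady=default_min_steady(noise.read_sigma, timing)
    )
    return spec, img


def calibrate_transition_threshold(
    seeds: list[int],
    photon_scale: float = 1e3,
    k: float = 3.0,
    timing: PulseTiming | None = None,
) -> float:
    """Threshold from the control bands of several calibration scenes."""
    from .pni import calibrate_threshold

    timing = timing or PulseTiming()
    controls = []
    for seed in seeds:
        spec, img = _pni_scene_image(seed, photon_scale, timing)
        control = next(g for _, g in spec.regions if g.transition is None)
        controls.append(extract_profile(img, control))
    return calibrate_threshold(controls, k=k)


def transition_trial(
    seed: int,
    threshold: float,
    photon_scale: float = 1e3,
    min_run: int = 5,
    timing: PulseTiming | None = None,
) -> tuple[int | None, int]:
    """(called transition index, true transition column) for one test scene."""
    from .pni import call_pni

    timing = timing or PulseTiming()
    spec, img = _pni_scene_image(seed, photon_scale, timing)
    band = next(g for _, g in spec.regions if g.transition is not None)
    call = call_pni(extract_profile(img, band), threshold, min_run=min_run)
    return call.transition_index, band.transition


def type1_replicate(
    seed: int,
    photon_scale: float = 1e4,
    n_instances: int = 8,
    instance_size: int = 8,
    timing: PulseTiming | None = None,
) -> float:
    """Null p-value: a tissue configured identically to the reference.

    Renders a single-channel scene holding ``n_instances`` patches each of
    "tumor" and "muscle" given the *same* decay parameters, and returns the
    muscle-vs-tumor p-value from the sweep.  Under the null this should be
    uniform on (0, 1).
    """
    timing = timing or PulseTiming()
    gap = 2
    step = instance_size + gap
    regions = []
    for r, name in enumerate(("tumor", "muscle")):
        for i in range(n_instances):
            regions.append(
                (name, Rectangle(gap + r * step, gap + i * step,
                                 instance_size, instance_size))
            )
    noise = NoiseModel(photon_scale=photon_scale, read_sigma=2.0)
    spec = PhantomSpec(
        shape=(gap + 2 * step, gap + n_instances * step),
        regions=tuple(regions),
        channels=(CALLING_CHANNEL,),
        noise=noise,
        seed=seed,
    )
    tissues = default_tissues((CALLING_CHANNEL,), {"tumor": 2.5, "muscle": 2.5})
    stack = render_stacks(spec, tissues, timing)[0]
    img = compute_doci(
        stack, min_steady=default_min_steady(noise.read_sigma, timing)
    )
    labels, legend = render_label_map(spec)
    results = significance_sweep([img], ROISet(labels, legend, "tumor"))
    row = results.table[results.table["tissue"] == "muscle"]
    return float(row["p"].iloc[0])
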