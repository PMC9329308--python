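import pytest

from doci import (
    NoiseModel,
    PulseTiming,
    compute_doci,
    default_scene,
    render_label_map,
    render_stacks,
)

NOISELESS = NoiseModel(photon_scale=None, read_sigma=0.0)


@pytest.fixture(scope="session")
def timing() -> PulseTiming:
    return PulseTiming()


@pytest.fixture(scope="session")
def fine_timing() -> PulseTiming:
    """Finer sampling for tests that compare against the analytic closed form."""
    return PulseTiming(sample_dt=0.25)


@pytest.fixture(scope="session")
def noiseless_margin(fine_timing):
    """Noiseless default margin scene (3 instances per tissue, single channel)."""
    spec, tissues = default_scene(
        "margin", seed=0, noise=NOISELESS, channels=(465.0,), n_instances=3
    )
    stacks = render_stacks(spec, tissues, fine_timing)
    labels, legend = render_label_map(spec)
    image = compute_doci(stacks[0], fine_timing)
    return spec, tissues, labels, legend, image
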