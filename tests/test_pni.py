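"""Nerve profiles, threshold calibration, PNI calls and detection metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from doci import (
    DOCIImage,
    NerveBand,
    NerveProfile,
    NoiseModel,
    PNIDetector,
    calibrate_threshold,
    call_pni,
    compute_doci,
    default_scene,
    evaluate_detection,
    extract_profile,
    render_stacks,
)


def image_from(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else mask
    return DOCIImage(channel=465.0, values=values, valid_mask=mask,
                     threshold_used=0.0)


def profile(values, start=0):
    values = np.asarray(values, dtype=float)
    return NerveProfile(np.arange(start, start + values.size), values, 465.0)


class TestExtractProfile:
    def test_uniform_image_gives_constant_profile(self):
        band = NerveBand(offset=2, width=4, start=0, stop=10)
        prof = extract_profile(image_from(np.full((8, 10), 2.5)), band)
        assert prof.values == pytest.approx(np.full(10, 2.5))
        assert list(prof.positions) == list(range(10))

    def test_width_one_band_equals_pixel_row(self):
        vals = np.arange(40.0).reshape(4, 10)
        band = NerveBand(offset=1, width=1, start=0, stop=10)
        prof = extract_profile(image_from(vals), band)
        assert prof.values == pytest.approx(vals[1])

    def test_step_image_steps_at_the_label_change(self):
        vals = np.full((8, 64), 4.0)
        vals[:, 32:] = 2.0
        band = NerveBand(offset=0, width=8, start=0, stop=64)
        prof = extract_profile(image_from(vals), band)
        assert (prof.values[:32] == 4.0).all()
        assert (prof.values[32:] == 2.0).all()

    def test_masked_positions_dropped(self):
        mask = np.ones((8, 10), dtype=bool)
        mask[:, 3] = False
        band = NerveBand(offset=0, width=8, start=0, stop=10)
        prof = extract_profile(image_from(np.ones((8, 10)), mask), band)
        assert 3 not in prof.positions
        assert prof.positions.size == 9

    def test_fully_masked_band_rejected(self):
        band = NerveBand(offset=0, width=2, start=0, stop=10)
        img = image_from(np.ones((4, 10)), np.zeros((4, 10), dtype=bool))
        with pytest.raises(ValueError, match="masked"):
            extract_profile(img, band)

    def test_vertical_band(self):
        vals = np.arange(40.0).reshape(10, 4)
        band = NerveBand(offset=1, width=2, start=0, stop=10, axis="v")
        prof = extract_profile(image_from(vals), band)
        assert prof.values == pytest.approx(vals[:, 1:3].mean(axis=1))


class TestThreshold:
    def test_mean_minus_k_sd(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(4.0, 0.1, size=500)
        profs = [profile(vals[:250]), profile(vals[250:])]
        pooled = vals
        expected = pooled.mean() - 3 * pooled.std(ddof=1)
        assert calibrate_threshold(profs, k=3) == pytest.approx(expected)
        assert calibrate_threshold(profs, k=3) == pytest.approx(3.7, abs=0.05)

    def test_k_zero_gives_control_mean(self):
        profs = [profile([4.0, 4.2]), profile([3.8, 4.0])]
        assert calibrate_threshold(profs, k=0) == pytest.approx(4.0)

    def test_zero_variance_degenerates_with_warning(self):
        profs = [profile([4.0, 4.0]), profile([4.0, 4.0])]
        with pytest.warns(UserWarning, match="zero variance"):
            assert calibrate_threshold(profs, k=3) == pytest.approx(4.0)

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([profile([4.0])], k=3)


class TestCallPni:
    def test_profile_above_threshold_is_control(self):
        call = call_pni(profile(np.full(50, 4.0)), threshold=3.7)
        assert call.label == "control"
        assert call.transition_index is None
        assert call.score == pytest.approx(4.0)

    def test_step_profile_called_pni_at_the_step(self):
        vals = np.full(64, 4.0)
        vals[32:] = 2.0
        call = call_pni(profile(vals), threshold=3.7)
        assert call.label == "pni"
        assert call.transition_index == 32
        # brute-force check: first position of >=5 consecutive below threshold
        below = vals < 3.7
        runs = [
            i for i in range(len(vals) - 4) if all(below[i : i + 5])
        ]
        assert call.transition_index == min(runs)

    def test_isolated_dip_below_min_run_is_control(self):
        vals = np.full(50, 4.0)
        vals[20] = 1.0
        assert call_pni(profile(vals), threshold=3.7).label == "control"

    def test_transition_index_uses_absolute_positions(self):
        vals = np.full(40, 4.0)
        vals[10:] = 2.0
        call = call_pni(profile(vals, start=100), threshold=3.7)
        assert call.transition_index == 110

    @given(
        k1=st.floats(0.0, 3.0),
        dk=st.floats(0.0, 3.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_raising_k_never_creates_a_pni_call(self, k1, dk, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(4.0, 0.3, size=40)
        mean, sd = 4.0, 0.3
        lo = call_pni(profile(vals), mean - k1 * sd)
        hi = call_pni(profile(vals), mean - (k1 + dk) * sd)
        if lo.label == "control":
            assert hi.label == "control"


class TestEvaluateDetection:
    def test_all_correct(self):
        pred = ["control"] * 6 + ["pni"] * 6
        m = evaluate_detection(pred, pred)
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_inverted_calls(self):
        truth = ["control"] * 6 + ["pni"] * 6
        pred = ["pni"] * 6 + ["control"] * 6
        m = evaluate_detection(pred, truth)
        assert m["accuracy"] == 0.0
        assert m["sensitivity"] == 0.0

    def test_confusion_arithmetic(self):
        truth = ["control"] * 6 + ["pni"] * 6
        pred = ["control"] * 6 + ["pni"] * 5 + ["control"]
        m = evaluate_detection(pred, truth)
        assert m["accuracy"] == pytest.approx(11 / 12)
        assert m["sensitivity"] == pytest.approx(5 / 6)
        assert m["specificity"] == pytest.approx(1.0)

    def test_absent_class_reports_none(self):
        m = evaluate_detection(["control", "control"], ["control", "control"])
        assert m["sensitivity"] is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_detection(["pni"], ["pni", "control"])


class TestDetectorOnPhantoms:
    def test_noiseless_transition_recovered_exactly(self, timing):
        spec, tissues = default_scene(
            "pni", seed=0, channels=(465.0,),
            noise=NoiseModel(photon_scale=None, read_sigma=0.0),
        )
        img = compute_doci(render_stacks(spec, tissues, timing)[0])
        control = next(g for _, g in spec.regions if g.transition is None)
        test = next(g for _, g in spec.regions if g.transition is not None)
        profiles = [extract_profile(img, control), extract_profile(img, test)]
        with pytest.warns(UserWarning, match="zero variance"):
            res = PNIDetector(
                profiles + [profiles[0]],
                is_control=[True, False, True],
                truth=["control", "pni", "control"],
            ).fit()
        call = res.calls[res.calls["truth"] == "pni"].iloc[0]
        assert call["label"] == "pni"
        assert call["transition_index"] == test.transition
        assert res.metrics["accuracy"] == 1.0

    def test_detector_separates_control_and_pni_at_default_noise(self, timing):
        profiles, is_control, truth = [], [], []
        for seed in range(1, 5):
            spec, tissues = default_scene("pni", seed=seed, channels=(465.0,))
            img = compute_doci(render_stacks(spec, tissues, timing)[0])
            for _, band in spec.regions:
                profiles.append(extract_profile(img, band))
                is_control.append(band.transition is None)
                truth.append("control" if band.transition is None else "pni")
        res = PNIDetector(profiles, is_control, truth).fit()
        assert res.metrics["accuracy"] == 1.0
        assert res.score_test["p"] < 0.05
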