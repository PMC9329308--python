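"""Synthetic scene generation: geometry, noise model, parameter recovery."""

import numpy as np
import pytest

from doci import (
    Ellipse,
    NerveBand,
    NoiseModel,
    PhantomSpec,
    Rectangle,
    amplitude_weighted_lifetime,
    compute_doci,
    default_scene,
    default_tissues,
    doci_closed_form,
    render_label_map,
    render_stacks,
)


class TestLabelMap:
    def test_full_frame_rectangle_labels_everything(self):
        spec = PhantomSpec(
            shape=(16, 16),
            regions=(("muscle", Rectangle(0, 0, 16, 16)),),
            channels=(465.0,),
        )
        labels, legend = render_label_map(spec)
        assert (labels == 1).all()
        assert legend == {0: "background", 1: "muscle"}

    def test_ellipse_area_matches_pointwise_oracle(self):
        ell = Ellipse(row=32.0, col=32.0, radius_row=8.0, radius_col=8.0)
        spec = PhantomSpec(
            shape=(64, 64),
            regions=(("muscle", Rectangle(0, 0, 64, 64)), ("tumor", ell)),
            channels=(465.0,),
        )
        labels, legend = render_label_map(spec)
        tumor_id = next(k for k, v in legend.items() if v == "tumor")
        # brute-force point-in-ellipse test, pixel by pixel
        expected = np.zeros((64, 64), dtype=bool)
        for r in range(64):
            for c in range(64):
                expected[r, c] = ((r - 32) / 8) ** 2 + ((c - 32) / 8) ** 2 <= 1
        assert np.array_equal(labels == tumor_id, expected)

    def test_nerve_band_transition_splits_labels(self):
        band = NerveBand(offset=10, width=8, start=0, stop=64, transition=32)
        spec = PhantomSpec(shape=(32, 64), regions=(("nerve", band),),
                          channels=(465.0,))
        labels, legend = render_label_map(spec)
        ids = {v: k for k, v in legend.items()}
        assert (labels[10:18, :32] == ids["nerve"]).all()
        assert (labels[10:18, 32:] == ids["pni_nerve"]).all()
        assert (labels[:10] == 0).all()

    def test_later_regions_overwrite_earlier(self):
        spec = PhantomSpec(
            shape=(8, 8),
            regions=(
                ("muscle", Rectangle(0, 0, 8, 8)),
                ("tumor", Rectangle(2, 2, 4, 4)),
            ),
            channels=(465.0,),
        )
        labels, legend = render_label_map(spec)
        ids = {v: k for k, v in legend.items()}
        assert (labels[2:6, 2:6] == ids["tumor"]).all()
        assert labels[0, 0] == ids["muscle"]

    def test_out_of_bounds_region_rejected(self):
        spec = PhantomSpec(
            shape=(8, 8), regions=(("muscle", Rectangle(0, 0, 9, 8)),),
            channels=(465.0,),
        )
        with pytest.raises(ValueError, match="outside"):
            render_label_map(spec)

    def test_transition_outside_band_rejected(self):
        with pytest.raises(ValueError, match="transition"):
            NerveBand(offset=0, width=4, start=10, stop=50, transition=60)


class TestRenderStacks:
    def test_same_seed_bit_identical(self, timing):
        spec, tissues = default_scene("pni", seed=11, channels=(465.0,))
        a = render_stacks(spec, tissues, timing)
        b = render_stacks(spec, tissues, timing)
        assert all(np.array_equal(x.frames, y.frames) for x, y in zip(a, b))

    def test_different_seed_differs(self, timing):
        spec1, tissues = default_scene("pni", seed=11, channels=(465.0,))
        spec2, _ = default_scene("pni", seed=12, channels=(465.0,))
        a = render_stacks(spec1, tissues, timing)
        b = render_stacks(spec2, tissues, timing)
        assert not np.array_equal(a[0].frames, b[0].frames)

    def test_background_frames_are_zero_without_read_noise(self, timing):
        spec, tissues = default_scene(
            "pni", seed=0, noise=NoiseModel(photon_scale=100.0, read_sigma=0.0),
            channels=(465.0,),
        )
        labels, _ = render_label_map(spec)
        frames = render_stacks(spec, tissues, timing)[0].frames
        assert (frames[:, labels == 0] == 0).all()

    def test_high_photon_limit_recovers_closed_form(self, fine_timing):
        spec = PhantomSpec(
            shape=(4, 4),
            regions=(("nerve", Rectangle(0, 0, 4, 4)),),
            channels=(465.0,),
            noise=NoiseModel(photon_scale=1e6, read_sigma=0.0),
            seed=5,
        )
        tissues = default_tissues((465.0,))
        stack = render_stacks(spec, tissues, fine_timing)[0]
        img = compute_doci(stack)
        expected = doci_closed_form(tissues["nerve"].components(465.0), fine_timing)
        assert img.values == pytest.approx(np.full((4, 4), expected), rel=5e-3)

    def test_missing_channel_parameters_error_names_tissue_and_channel(self, timing):
        spec, _ = default_scene("pni", seed=0, channels=(465.0, 494.0))
        tissues = default_tissues((465.0,))  # 494 missing
        with pytest.raises(KeyError, match="nerve.*494"):
            render_stacks(spec, tissues, timing)

    def test_pni_ordering_invariant_enforced(self, timing):
        spec, _ = default_scene("pni", seed=0, channels=(465.0,))
        bad = default_tissues((465.0,), {"nerve": 2.0, "pni_nerve": 3.0,
                                         "tumor": 1.5})
        with pytest.raises(ValueError, match="pni_nerve"):
            render_stacks(spec, bad, timing)


class TestDefaultScenes:
    def test_margin_scene_has_all_tissues_with_enough_pixels(self):
        spec, _ = default_scene("margin", seed=0)
        labels, legend = render_label_map(spec)
        for name in ("tumor", "muscle", "adipose", "dat"):
            lid = next(k for k, v in legend.items() if v == name)
            assert (labels == lid).sum() >= 200 * 15

    def test_pni_scene_control_band_has_no_invaded_pixels(self):
        spec, _ = default_scene("pni", seed=0)
        labels, legend = render_label_map(spec)
        control = next(g for _, g in spec.regions if g.transition is None)
        pni_id = next(k for k, v in legend.items() if v == "pni_nerve")
        assert (labels[control.mask(spec.shape)] != pni_id).all()
        assert (labels == pni_id).sum() > 0  # but the test band has some

    def test_default_lifetime_ordering(self):
        tissues = default_tissues()
        for ch in (405.0, 465.0, 605.0):
            awl = {
                n: amplitude_weighted_lifetime(tc.components(ch))
                for n, tc in tissues.items() if n != "background"
            }
            assert awl["pni_nerve"] < awl["nerve"]
            assert all(
                awl["tumor"] != awl[n] for n in awl if n != "tumor"
            )

    def test_unknown_scene_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            default_scene("flank")


class TestNoiseBehaviour:
    def test_pixel_doci_scatter_shrinks_with_photon_scale(self, timing):
        sds = []
        for scale in (1e2, 1e3, 1e4):
            spec = PhantomSpec(
                shape=(16, 16),
                regions=(("muscle", Rectangle(0, 0, 16, 16)),),
                channels=(465.0,),
                noise=NoiseModel(photon_scale=scale, read_sigma=0.0),
                seed=3,
            )
            stack = render_stacks(spec, default_tissues((465.0,)), timing)[0]
            img = compute_doci(stack)
            sds.append(img.values[img.valid_mask].std())
        assert sds[0] > sds[1] > sds[2]

    def test_roi_means_recover_lifetime_rank_order(self, timing):
        for seed in range(3):
            spec, tissues = default_scene("margin", seed=seed, channels=(465.0,),
                                          n_instances=3)
            stack = render_stacks(spec, tissues, timing)[0]
            img = compute_doci(stack)
            labels, legend = render_label_map(spec)
            means = {
                name: img.values[labels == lid].mean()
                for lid, name in legend.items() if name != "background"
            }
            by_doci = sorted(means, key=means.get)
            by_tau = sorted(
                means, key=lambda n: tissues[n].components(465.0)[0].lifetime
            )
            assert by_doci == by_tau
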