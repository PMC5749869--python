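from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from actionrep.gabor import Template, TemplateBank, build_conv1_bank
from actionrep.stcnn import (FixedTemplateModel, PoolGroups, build_scale_pyramid,
                             conv3d, even_partition_sizes, make_pool_groups,
                             max_pool, random_even_groups, sample_templates)


def brute_force_conv3d(x, w):
    """Triple-loop valid cross-correlation oracle (single template)."""
    if x.ndim == 3:
        x = x[None]
    if w.ndim == 3:
        w = w[None]
    C, H, W, T = x.shape
    _, h, wd, t = w.shape
    out = np.zeros((H - h + 1, W - wd + 1, T - t + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            for k in range(out.shape[2]):
                out[i, j, k] = np.sum(x[:, i:i + h, j:j + wd, k:k + t] * w)
    return out


class TestConv3d:
    def test_matches_bruteforce_on_small_inputs(self):
        """Randomized oracle suite over all template/input shapes <= 8^3."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            C = int(rng.integers(1, 4))
            H, W, T = rng.integers(2, 9, size=3)
            h = int(rng.integers(1, H + 1))
            w = int(rng.integers(1, W + 1))
            t = int(rng.integers(1, T + 1))
            x = rng.standard_normal((C, H, W, T))
            tpl = rng.standard_normal((C, h, w, t))
            out = conv3d(x, tpl[None], normalize=False)
            assert np.abs(out[0] - brute_force_conv3d(x, tpl)).max() < 1e-10

    def test_normalized_response_is_maximal_at_aligned_position(self):
        rng = np.random.default_rng(0)
        tpl = rng.standard_normal((4, 4, 3))
        tpl -= tpl.mean()
        tpl /= np.linalg.norm(tpl)
        x = np.zeros((9, 9, 7))
        x[2:6, 3:7, 1:4] = tpl
        out = conv3d(x, tpl[None], normalize=True)[0]
        assert out.max() == pytest.approx(1.0, abs=1e-10)
        assert np.unravel_index(out.argmax(), out.shape) == (2, 3, 1)
        assert out.max() >= out.flat[0]  # Cauchy-Schwarz bound

    def test_zero_input_gives_zero_responses(self):
        tpl = np.ones((3, 3, 2))
        out = conv3d(np.zeros((6, 6, 4)), tpl[None], normalize=True)
        assert np.all(out == 0)

    def test_oversized_template_rejected_with_dimensions(self):
        with pytest.raises(ValueError, match=r"9x9x2.*4x4x4"):
            conv3d(np.zeros((4, 4, 4)), np.ones((9, 9, 2))[None])

    def test_stride_subsamples_output(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 8, 8))
        tpl = rng.standard_normal((3, 3, 3))
        full = conv3d(x, tpl[None], normalize=False)[0]
        strided = conv3d(x, tpl[None], stride=(2, 2, 2), normalize=False)[0]
        assert np.allclose(strided, full[::2, ::2, ::2], atol=1e-12)

    def test_wrap_boundary_output_matches_input_extent(self):
        x = np.random.default_rng(2).standard_normal((6, 5, 4))
        out = conv3d(x, np.ones((3, 3, 2))[None], boundary="wrap", normalize=False)
        assert out.shape == (1, 6, 5, 4)


class TestScalePyramid:
    def test_factor_one_returns_identical_tensor(self):
        x = np.random.default_rng(0).random((16, 12, 5))
        assert build_scale_pyramid(x, [1.0])[0] is x

    def test_quarter_scale_of_paper_geometry(self):
        x = np.zeros((128, 76, 3))
        small = build_scale_pyramid(x, [0.25])[0]
        assert small.shape == (32, 19, 3)

    def test_frame_count_preserved_at_all_factors(self):
        x = np.random.default_rng(0).random((32, 24, 7))
        for s in build_scale_pyramid(x, [1.0, 0.5, 0.25]):
            assert s.shape[2] == 7

    def test_rescale_below_one_pixel_rejected(self):
        with pytest.raises(ValueError, match="below 1 px"):
            build_scale_pyramid(np.zeros((8, 8, 2)), [0.05])


class TestMaxPool:
    def test_full_extent_region_gives_global_max(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 6, 5, 3))
        out = max_pool(x, (6, 5, 3))
        assert out.shape == (4, 1, 1, 1)
        assert np.allclose(out[:, 0, 0, 0], x.max(axis=(1, 2, 3)))

    def test_single_spike_appears_in_exactly_the_covering_windows(self):
        x = np.zeros((1, 6, 6, 4))
        x[0, 3, 2, 1] = 5.0
        out = max_pool(x, (2, 2, 2), (1, 1, 1))[0]
        expected = np.zeros_like(out)
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                for k in range(out.shape[2]):
                    if i <= 3 < i + 2 and j <= 2 < j + 2 and k <= 1 < k + 2:
                        expected[i, j, k] = 5.0
        assert np.array_equal(out, expected)

    def test_unit_region_is_identity(self):
        x = np.random.default_rng(4).standard_normal((2, 5, 5, 3))
        assert np.array_equal(max_pool(x, (1, 1, 1), (1, 1, 1)), x)

    def test_region_larger_than_input_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            max_pool(np.zeros((1, 3, 3, 3)), (4, 4, 1))

    def test_channel_groups_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            PoolGroups([[0, 1], [1, 2, 3]], "unstructured", 4)


class TestSampleTemplates:
    def test_same_seed_reproduces_the_bank(self, small_pool1):
        a = sample_templates(small_pool1, [(3, 3, 3)], 10, seed=5)
        b = sample_templates(small_pool1, [(3, 3, 3)], 10, seed=5)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.weights, tb.weights)
            assert ta.meta == tb.meta

    def test_count_and_complete_provenance(self, small_pool1):
        bank = sample_templates(small_pool1, [(3, 3, 3), (3, 3, 4)], 15, seed=1)
        assert len(bank) == 15
        for tpl in bank:
            assert {"actor", "action", "viewpoint", "size_class",
                    "scale_channel", "position"} <= tpl.meta.keys()
            assert np.linalg.norm(tpl.weights) == pytest.approx(1.0)

    def test_single_source_clip_stamps_its_labels_everywhere(self, small_pool1):
        bank = sample_templates(small_pool1[:1], [(3, 3, 3)], 6, seed=2)
        key = small_pool1[0][0]
        for tpl in bank:
            assert (tpl.meta["actor"], tpl.meta["action"], tpl.meta["viewpoint"]) == key[:3]

    def test_oversized_request_rejected(self, small_pool1):
        with pytest.raises(ValueError, match="exceeds"):
            sample_templates(small_pool1, [(50, 50, 50)], 2, seed=0)


def _provenance_bank(pairs, sizes, viewpoints=(0.0, 90.0)):
    """Bank with one template per (actor/action pair, size, viewpoint)."""
    bank = TemplateBank()
    rng = np.random.default_rng(0)
    for actor, action in pairs:
        for size in sizes:
            for vp in viewpoints:
                w = rng.standard_normal((2,) + size)
                w -= w.mean()
                w /= np.linalg.norm(w)
                bank.templates.append(Template(w, meta={
                    "actor": actor, "action": action, "viewpoint": vp,
                    "size_class": size, "scale_channel": 0, "position": (0, 0, 0),
                }))
    return bank


class TestPoolGroups:
    def test_structured_six_units_per_pair_with_three_sizes_two_scales(self):
        bank = _provenance_bank([(0, 0)], [(3, 3, 2), (4, 4, 2), (5, 5, 2)])
        groups = make_pool_groups(bank, "structured", n_scale_channels=2)
        assert len(groups) == 6  # 3 size classes x 2 scale channels

    def test_even_partition_512_into_60_gives_sizes_8_and_9(self):
        sizes = even_partition_sizes(512, 60)
        assert set(sizes) == {8, 9}
        assert max(sizes) == 9 and sum(sizes) == 512
        groups = random_even_groups(512, 60, seed=0)
        assert groups.size_multiset() == Counter({9: 32, 8: 28})

    def test_unstructured_is_seeded_and_matches_structured_multiset(self):
        bank = _provenance_bank([(0, 0), (0, 1), (1, 0)], [(3, 3, 2)])
        s = make_pool_groups(bank, "structured", n_scale_channels=1)
        u1 = make_pool_groups(bank, "unstructured", seed=9, n_scale_channels=1)
        u2 = make_pool_groups(bank, "unstructured", seed=9, n_scale_channels=1)
        assert u1.groups == u2.groups
        assert u1.size_multiset() == s.size_multiset()

    def test_structured_requires_provenance(self):
        bank = build_conv1_bank(speeds=(2.0,), size_classes=((7, 3),))
        with pytest.raises(ValueError, match="provenance"):
            make_pool_groups(bank, "structured")

    def test_per_channel_pools_scales_within_one_template(self):
        bank = _provenance_bank([(0, 0)], [(3, 3, 2)])
        groups = make_pool_groups(bank, "per-channel", n_scale_channels=2)
        assert len(groups) == len(bank)
        assert all(len(g) == 2 for g in groups.groups)


class TestSignatureInvariances:
    def _wrap_model(self, rng):
        """Periodic-padding harness: wrap convolutions, no Pool1 subsampling."""
        conv1 = build_conv1_bank(orientations=(0, 90), speeds=(2.0,),
                                 size_classes=((5, 3),))
        clip = rng.random((14, 12, 6))
        base = FixedTemplateModel(
            conv1_bank=conv1, conv2_bank=conv1, pool_groups=None,
            pyramid_factors=(1.0,), scale_pairs=((0, 0),),
            pool1_region=(1, 1, 1), pool1_stride=(1, 1, 1),
            boundary="wrap",
        )
        pool1 = [(("a", "x", 0.0, 0), base.pool1_responses(clip))]
        conv2 = sample_templates(pool1, [(3, 3, 2)], 6, seed=3)
        groups = make_pool_groups(conv2, "per-channel", n_scale_channels=1)
        return replace(base, conv2_bank=conv2, pool_groups=groups), clip

    def test_global_pooling_gives_exact_translation_invariance(self):
        """Circular spatial shifts leave the signature exactly unchanged."""
        model, clip = self._wrap_model(np.random.default_rng(6))
        ref = model.extract(clip)
        for shift in ((3, 0), (0, 4), (5, 2)):
            shifted = np.roll(clip, shift, axis=(0, 1))
            assert np.array_equal(model.extract(shifted), ref)

    def test_structured_pooling_is_viewpoint_invariant_on_template_stimuli(self):
        """A stimulus equal to a sampled template at either viewpoint drives
        the same structured unit to its maximal (unit) response, while other
        actions' units respond less."""
        bank = _provenance_bank([(0, 0), (0, 1)], [(3, 3, 2)])
        groups = make_pool_groups(bank, "structured", n_scale_channels=1)
        unit_of = {key[:2]: gi for gi, key in enumerate(groups.keys)}
        for tpl in bank:
            stim = tpl.weights  # a Pool1-space stimulus identical to the template
            resp = np.array([
                conv3d(stim, [bank[i] for i in g], normalize=True).max()
                for g in groups.groups
            ])
            own = unit_of[(tpl.meta["actor"], tpl.meta["action"])]
            assert resp[own] == pytest.approx(1.0, abs=1e-9)
            other = [r for gi, r in enumerate(resp) if gi != own]
            assert resp[own] >= max(other) - 1e-9

    def test_end_to_end_signature_is_deterministic(self, small_index,
                                                   small_base_model, small_conv2_bank):
        groups = make_pool_groups(small_conv2_bank, "structured", n_scale_channels=1)
        model = replace(small_base_model, conv2_bank=small_conv2_bank,
                        pool_groups=groups)
        clip = small_index.get_clip(small_index.records[0]).pixels
        assert np.array_equal(model.extract(clip), model.extract(clip))
        assert model.extract(clip).shape == (len(groups),)

    def test_all_zero_video_yields_all_zero_signature(self, small_base_model,
                                                      small_conv2_bank):
        groups = make_pool_groups(small_conv2_bank, "per-channel", n_scale_channels=1)
        model = replace(small_base_model, conv2_bank=small_conv2_bank,
                        pool_groups=groups)
        sig = model.extract(np.zeros((32, 24, 10)))
        assert np.all(sig == 0)
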