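"""Synthetic stimulus generation: controls, scrambles, transforms, viewpoint."""

import numpy as np
import pytest

from convsel.stimuli import (
    StimulusSet,
    StimulusSpec,
    generate_exemplar,
    generate_stimulus_set,
    generate_transform_sweep,
    generate_viewpoint_set,
    local_texture_scramble,
    patch_scramble,
    phase_scramble,
    registered_classes,
    transform_object,
)


class TestExemplars:
    def test_deterministic(self):
        a = generate_exemplar("face", 3, 4, image_size=96)
        b = generate_exemplar("face", 3, 4, image_size=96)
        np.testing.assert_array_equal(a, b)

    def test_identities_differ(self):
        a = generate_exemplar("face", 1, 0, image_size=96)
        b = generate_exemplar("face", 2, 0, image_size=96)
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert r < 1.0

    def test_unknown_class_lists_registered(self):
        with pytest.raises(ValueError, match="face"):
            generate_exemplar("spaceship", 0, 0)
        assert "scrambled_face" in registered_classes()

    def test_face_pairwise_correlation_small_and_reproducible(self):
        def mean_corr(seed):
            spec = StimulusSpec(
                classes=("face",), n_per_class=50, image_size=64, seed=seed
            )
            X = generate_stimulus_set(spec).images.reshape(50, -1)
            X = X - X.mean(axis=1, keepdims=True)
            X = X / np.linalg.norm(X, axis=1, keepdims=True)
            c = X @ X.T
            return c[np.triu_indices(50, 1)].mean()

        m1, m2 = mean_corr(11), mean_corr(12)
        # composed face stimuli share coarse layout only: small positive mean
        assert 0.0 < m1 < 0.6
        assert m1 == pytest.approx(m2, abs=0.1)

    def test_bbox_area_matched_across_classes(self):
        fracs = {}
        for cls in ("face", "scrambled_face", "hand", "horn", "flower", "chair"):
            vals = []
            for i in range(8):
                lay = generate_exemplar(cls, 10 + i, i, image_size=96)
                ys, xs = np.nonzero(lay > 0)
                h = ys.max() - ys.min() + 1
                w = xs.max() - xs.min() + 1
                vals.append(h * w)
            fracs[cls] = np.mean(vals)
        spread = (max(fracs.values()) - min(fracs.values())) / np.mean(list(fracs.values()))
        assert spread < 0.05


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        out = phase_scramble(img, seed=1, clip=False)
        a0 = np.abs(np.fft.fft2(img))
        a1 = np.abs(np.fft.fft2(out))
        np.testing.assert_allclose(a1, a0, rtol=1e-6, atol=1e-9)

    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 0.3)
        out = phase_scramble(img, seed=0, clip=False)
        np.testing.assert_allclose(out, img, atol=1e-10)

    def test_white_noise_autocorrelation_preserved(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64))
        out = phase_scramble(img, seed=3, clip=False)

        def autocorr(x):
            f = np.fft.fft2(x - x.mean())
            return np.fft.ifft2(f * np.conj(f)).real

        # spectra match => autocorrelation matches (DC removed up to mean shift)
        np.testing.assert_allclose(autocorr(out), autocorr(img), atol=1.0)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            phase_scramble(np.zeros((8, 10)), 0)


class TestPatchScramble:
    def test_histogram_preserved(self):
        img = np.random.default_rng(1).random((36, 36)).astype(np.float32)
        out = patch_scramble(img, 6, seed=2)
        np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_seed_reproducible(self):
        img = np.random.default_rng(1).random((36, 36)).astype(np.float32)
        np.testing.assert_array_equal(
            patch_scramble(img, 6, seed=5), patch_scramble(img, 6, seed=5)
        )

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            patch_scramble(np.zeros((8, 8)), 1, 0)


class TestLocalTextureScramble:
    def test_full_window_equals_phase_scramble(self):
        img = np.random.default_rng(0).random((32, 32))
        np.testing.assert_array_equal(
            local_texture_scramble(img, 32, seed=4), phase_scramble(img, 4)
        )

    def test_local_mean_preserved(self):
        # mid-range image: clipping inactive, window DC is preserved
        img = 0.5 + 0.1 * np.random.default_rng(1).standard_normal((64, 64))
        out = local_texture_scramble(img, 16, seed=0)
        for r in range(0, 64, 16):
            for c in range(0, 64, 16):
                m0 = img[r : r + 16, c : c + 16].mean()
                m1 = out[r : r + 16, c : c + 16].mean()
                assert abs(m1 - m0) / m0 < 0.05

    def test_seed_reproducible(self):
        img = np.random.default_rng(2).random((48, 48))
        np.testing.assert_array_equal(
            local_texture_scramble(img, 16, seed=9), local_texture_scramble(img, 16, seed=9)
        )

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            local_texture_scramble(np.zeros((32, 32)), 4, 0)


class TestTransformObject:
    @pytest.fixture()
    def layer(self):
        return generate_exemplar("face", 0, 0, image_size=96, object_fraction=0.4)

    def test_identity(self, layer):
        np.testing.assert_array_equal(transform_object(layer), layer)

    def test_full_rotation_roundtrip(self, layer):
        out = transform_object(layer, rotation_deg=360.0)
        np.testing.assert_allclose(out, layer, atol=0.02)

    def test_offset_inverse_composition(self, layer):
        out = transform_object(transform_object(layer, offset_px=(10, 0)), offset_px=(-10, 0))
        np.testing.assert_allclose(out, layer, atol=0.02)

    def test_area_scales_quadratically(self, layer):
        a0 = (layer > 0.04).sum()
        a1 = (transform_object(layer, scale=1.3) > 0.04).sum()
        assert a1 / a0 == pytest.approx(1.3**2, rel=0.05)

    def test_clipping_detected(self, layer):
        with pytest.raises(ValueError, match="clipped"):
            transform_object(layer, offset_px=(60, 0))


class TestViewpointSet:
    def test_default_counts_and_balance(self):
        vp = generate_viewpoint_set(n_identities=10, seed=0, image_size=64)
        assert len(vp) == 50
        labels, counts = np.unique(vp.class_labels, return_counts=True)
        assert len(labels) == 5 and np.all(counts == 10)

    def test_mirror_pairs_pixel_exact(self):
        vp = generate_viewpoint_set(n_identities=2, seed=1, image_size=64)
        lab = np.asarray(vp.class_labels)
        ident = vp.transform_meta["identity"].to_numpy()
        for k in range(2):
            neg = vp.images[(lab == "yaw-45") & (ident == k)][0]
            pos = vp.images[(lab == "yaw+45") & (ident == k)][0]
            np.testing.assert_array_equal(neg, pos[:, ::-1])
            frontal = vp.images[(lab == "yaw+0") & (ident == k)][0]
            np.testing.assert_array_equal(frontal, frontal[:, ::-1])

    def test_asymmetric_yaws_rejected(self):
        with pytest.raises(ValueError):
            generate_viewpoint_set(yaws=(-90, 0, 45), seed=0)


class TestFullSet:
    def test_partition_sizes_and_disjointness(self, small_stim):
        labels = np.asarray(small_stim.class_labels)
        tags = np.asarray(small_stim.partition_tags)
        for cls in np.unique(labels):
            m = labels == cls
            assert (tags[m] == "selection").sum() == 10
            assert (tags[m] == "train").sum() == 2
            assert (tags[m] == "test").sum() == 1
        ids = small_stim.stimulus_ids
        assert len(set(ids)) == len(ids)

    def test_luminance_contrast_within_2pct(self, small_stim):
        labels = np.asarray(small_stim.class_labels)
        for cls in np.unique(labels):
            imgs = small_stim.images[labels == cls]
            assert imgs.mean() == pytest.approx(0.5, rel=0.02)
            assert imgs.std(axis=(1, 2)).mean() == pytest.approx(0.18, rel=0.02)

    def test_seed_reproducible(self):
        spec = StimulusSpec(n_per_class=13, image_size=64, seed=5)
        a = generate_stimulus_set(spec)
        np.testing.assert_array_equal(a.images, generate_stimulus_set(spec).images)

    def test_too_small_set_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(n_per_class=5)

    def test_png_manifest_roundtrip(self, tmp_path, small_stim):
        sub = small_stim.partition("train")
        sub.save_dir(tmp_path / "stim")
        back = StimulusSet.load_dir(tmp_path / "stim")
        assert back.class_labels == sub.class_labels
        assert back.partition_tags == sub.partition_tags
        # 8-bit quantization on disk
        np.testing.assert_allclose(back.images, sub.images, atol=1 / 255 + 1e-6)


def test_transform_sweep_paired_and_labeled():
    sweeps = generate_transform_sweep(
        "rotation", [0.0, 180.0], classes=("face", "chair"), n_per_class=3,
        image_size=64, object_fraction=0.35, seed=2,
    )
    assert set(sweeps) == {0.0, 180.0}
    a, b = sweeps[0.0], sweeps[180.0]
    assert a.class_labels == b.class_labels
    assert list(a.transform_meta["identity"]) == list(b.transform_meta["identity"])
    assert (b.transform_meta["rotation"] == 180.0).all()
    with pytest.raises(ValueError):
        generate_transform_sweep("rotation", [], seed=0)
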