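"""Synthetic-data generator: determinism, label statistics, scale affinity,
noise injection, and patch cropping."""

import numpy as np
import pytest
from scipy import ndimage

from scalestack.denoise import psnr
from scalestack.metrics import auc
from scalestack.preprocess import build_scale_pyramid
from scalestack.records import ImageRecord
from scalestack.synth import (DatasetSpec, FindingSpec, NoiseSpec,
                              complementary_scale_spec, crop_patches,
                              generate_dataset, inject_noise)


def _spec(n=50, prevalence=0.5, seed=7, resolution=64, kind="texture"):
    return DatasetSpec(
        n_images=n,
        findings=[FindingSpec("f", prevalence, resolution, kind=kind)],
        resolution=resolution,
        seed=seed,
    )


class TestGenerateDataset:
    def test_label_frequency_matches_prevalence(self):
        """Label frequency within 3 binomial sd of the requested prevalence."""
        n = 1000
        recs = generate_dataset(_spec(n=n, prevalence=0.5, seed=7))
        freq = np.mean([r.labels[0] for r in recs])
        sd = np.sqrt(0.5 * 0.5 / n)
        assert abs(freq - 0.5) < 3 * sd

    def test_bit_identical_under_equal_spec_and_seed(self):
        a = generate_dataset(_spec(n=12, seed=3))
        b = generate_dataset(_spec(n=12, seed=3))
        for ra, rb in zip(a, b):
            assert ra.image_id == rb.image_id
            assert np.array_equal(ra.pixels, rb.pixels)
            assert np.array_equal(ra.labels, rb.labels)

    def test_pixels_in_8bit_range(self):
        for rec in generate_dataset(_spec(n=5, seed=1)):
            assert rec.pixels.dtype == np.uint8

    def test_audit_equals_label_table(self):
        recs, audit = generate_dataset(_spec(n=30, seed=5), return_audit=True)
        for rec in recs:
            assert audit.loc[rec.image_id, "f"] == rec.labels[0]

    def test_fine_texture_destroyed_by_8x_downsampling(self):
        """After 8x downsampling, no pixel-statistic detector separates the
        fine-texture finding from background (permutation test)."""
        recs = generate_dataset(_spec(n=1000, prevalence=0.5, seed=2))
        labels = np.array([r.labels[0] for r in recs])
        small = np.stack(
            [build_scale_pyramid(r, [8]).levels[8].astype(float) for r in recs]
        )
        flat = small.reshape(len(recs), -1)
        rng = np.random.default_rng(0)
        for stat in (flat.std(axis=1), flat.mean(axis=1),
                     np.abs(np.diff(flat, axis=1)).mean(axis=1)):
            observed = auc(labels, stat)
            perms = np.array([
                auc(rng.permutation(labels), stat) for _ in range(200)
            ])
            p = np.mean(np.abs(perms - 0.5) >= abs(observed - 0.5))
            assert p > 0.01, f"detector separated destroyed-scale texture (AUC {observed:.3f})"

    def test_coarse_blob_survives_all_scales(self):
        spec = _spec(n=300, seed=4, kind="blob", resolution=128)
        spec.findings[0].affinity_scale = 16
        spec.findings[0].amplitude = (16.0, 34.0)
        recs = generate_dataset(spec)
        labels = np.array([r.labels[0] for r in recs])
        for res in (16, 64, 128):
            imgs = np.stack(
                [build_scale_pyramid(r, [res]).levels[res].astype(float) for r in recs]
            )
            stat = np.array([
                (ndimage.gaussian_filter(im, res / 16) -
                 ndimage.gaussian_filter(im, res / 6)).max() for im in imgs
            ])
            assert auc(labels, stat) > 0.65, f"blob invisible at {res}"

    @pytest.mark.parametrize("bad", [
        dict(n_images=0), dict(resolution=8), dict(prevalence=1.5),
    ])
    def test_invalid_spec_rejected(self, bad):
        spec = _spec()
        if "prevalence" in bad:
            spec.findings[0].prevalence = bad["prevalence"]
        else:
            for k, v in bad.items():
                setattr(spec, k, v)
        with pytest.raises(ValueError):
            generate_dataset(spec)


class TestInjectNoise:
    def test_zero_noise_is_identity(self, flat_image):
        out = inject_noise(flat_image, NoiseSpec(), seed=0)
        assert np.array_equal(out.pixels, flat_image.pixels)

    def test_periodic_term_creates_conjugate_peaks(self, flat_image):
        noisy = inject_noise(
            flat_image, NoiseSpec(periodic=[((8.0, 0.0), 40.0)]), seed=0
        )
        spectrum = np.abs(np.fft.fft2(noisy.pixels.astype(float)))
        spectrum[0, 0] = 0.0
        peaks = np.argwhere(spectrum > spectrum.max() * 0.5)
        assert {tuple(p) for p in peaks} == {(8, 0), (64 - 8, 0)}

    def test_any_noise_reduces_psnr(self, flat_image):
        noisy = inject_noise(flat_image, NoiseSpec(gaussian_sigma=10.0), seed=1)
        assert np.isfinite(psnr(flat_image, noisy))
        assert psnr(flat_image, noisy) < psnr(flat_image, flat_image)

    def test_psnr_monotone_in_gaussian_sigma(self, flat_image):
        values = [
            psnr(flat_image, inject_noise(flat_image, NoiseSpec(gaussian_sigma=s), seed=3))
            for s in (2.0, 6.0, 18.0)
        ]
        assert values[0] > values[1] > values[2]

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(impulse_fraction=1.5).validate()
        with pytest.raises(ValueError):
            NoiseSpec(periodic=[((1.0, 0.0), -2.0)]).validate()


class TestCropPatches:
    def test_degenerate_geometry_single_patch(self):
        rec = ImageRecord("a", np.zeros((113, 113), np.uint8))
        patches = crop_patches(rec, seed=0)
        assert len(patches) == 1
        assert patches[0].pixels.shape == (113, 113)

    def test_cap_limits_emitted_patches(self):
        rec = ImageRecord("a", np.zeros((226, 226), np.uint8))
        patches = crop_patches(rec, n_proposals=10, cap_fraction=0.7, seed=1)
        assert len(patches) <= 7

    def test_bounds_always_inside_source(self):
        rec = ImageRecord("a", np.arange(150 * 150, dtype=np.uint8).reshape(150, 150))
        for seed in range(1000):
            for p in crop_patches(rec, patch=113, seed=seed):
                assert p.pixels.shape == (113, 113)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="smaller than patch"):
            crop_patches(ImageRecord("a", np.zeros((100, 100), np.uint8)))


def test_complementary_spec_has_one_finding_per_scale():
    spec = complementary_scale_spec(10, 0, (32, 64, 128, 256))
    assert [f.affinity_scale for f in spec.findings] == [32, 64, 128, 256]
    assert spec.findings[0].kind == "blob"
    # every finding carries independent components at complementary scales
    for f in spec.findings:
        assert f.extras, f.name
        for motif in f.extras:
            if motif.kind == "texture":
                assert motif.scale != f.affinity_scale
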