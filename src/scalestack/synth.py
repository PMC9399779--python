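"""Synthetic multi-label images with scale-specific discriminative signal.

Real chest-radiograph corpora are restricted, so the pipeline is exercised on
generated images in which each finding's signal is *constructed* to live at a
known pyramid level ("scale affinity"):

* **texture** findings paint an oriented sinusoidal patch whose spatial
  frequency lies above the Nyquist limit of the next-coarser pyramid level —
  anti-aliased downsampling below the affinity scale removes it entirely,
  while scales at and above the affinity retain it (with signal-to-noise
  ratio highest at the affinity scale, because downsampling also averages
  the white pixel noise);
* **blob** findings paint a large low-contrast Gaussian blob (diameter at
  least a quarter of the image) that is buried in per-pixel noise at native
  resolution and becomes prominent at coarse scales.

Images also carry a smooth random background field and white pixel noise, so
that no finding is trivially separable. A finding may optionally carry a
weak *secondary* component at a complementary scale, which is what gives a
multi-scale ensemble genuine headroom over the best single-scale model.

A separate :func:`inject_noise` step adds quasi-periodic, Gaussian and
impulse contamination for the denoising front-end, and :func:`crop_patches`
emits random fixed-size crops with a cap on the fraction of proposals kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import transform

from .records import ImageRecord

__all__ = [
    "FindingSpec",
    "NoiseSpec",
    "DatasetSpec",
    "generate_dataset",
    "inject_noise",
    "crop_patches",
    "complementary_scale_spec",
    "save_dataset",
    "load_dataset",
]


@dataclass
class Motif:
    """One painted component: kind, contrast range, and (for textures) the
    pyramid level whose band it occupies."""

    kind: str  # "texture" | "blob" | "smallblob" | "largeblob"
    amplitude: tuple[float, float]
    scale: int | None = None
    orientation: float | None = None


@dataclass
class FindingSpec:
    """One synthetic finding and where its signal lives.

    ``affinity_scale`` is the coarsest pyramid level (pixels per side) at
    which the primary motif survives resampling. ``amplitude`` is the
    per-image uniform range of motif contrast in intensity levels;
    randomizing it makes some positives genuinely hard, so single-scale
    classifiers stay off the AUC ceiling. Additional components painted
    whenever the finding is positive can be given either through the
    ``secondary_*`` convenience fields (one extra motif, contrast coupled to
    or independent of the primary) or as an explicit ``extras`` list of
    :class:`Motif`; components at complementary scales with independent
    contrast draws are what give the finding multiple decorrelated views
    (used by the complementary-scale benchmark).
    """

    name: str
    prevalence: float
    affinity_scale: int
    kind: str = "texture"  # "texture" | "blob"
    amplitude: tuple[float, float] = (10.0, 22.0)
    orientation: float | None = None  # degrees; None draws per image
    secondary: str | None = None  # "blob" | "smallblob" | "texture"
    secondary_scale: int | None = None  # texture secondaries need a scale
    secondary_gain: float = 0.5
    secondary_amplitude: tuple[float, float] | None = None  # independent draw
    secondary_orientation: float | None = None
    extras: list[Motif] = field(default_factory=list)  # further components


@dataclass
class NoiseSpec:
    """Contamination model: quasi-periodic + Gaussian + impulse ("sparse") noise."""

    periodic: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    gaussian_sigma: float = 0.0
    impulse_fraction: float = 0.0

    def validate(self) -> None:
        for (fu, fv), amp in self.periodic:
            if amp < 0:
                raise ValueError("periodic amplitudes must be >= 0")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if not 0.0 <= self.impulse_fraction <= 1.0:
            raise ValueError("impulse_fraction must be in [0, 1]")


@dataclass
class DatasetSpec:
    n_images: int
    findings: list[FindingSpec]
    resolution: int = 256
    noise: NoiseSpec | None = None
    seed: int = 0
    background_level: float = 120.0
    background_sigma: float = 20.0  # white pixel noise, intensity levels
    field_amplitude: float = 12.0  # smooth random background field
    mid_noise_sigma: float = 6.0  # band-limited (mid-frequency) clutter

    def validate(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.resolution < 16:
            raise ValueError("resolution must be >= 16")
        for f in self.findings:
            if not 0.0 <= f.prevalence <= 1.0:
                raise ValueError(f"prevalence of {f.name!r} must be in [0, 1]")
            if f.kind not in ("texture", "blob"):
                raise ValueError(f"unknown motif kind {f.kind!r}")
        if self.noise is not None:
            self.noise.validate()


def _texture_frequency(affinity_scale: int, resolution: int) -> float:
    """Cycles per native pixel for a texture tied to ``affinity_scale``.

    The band (Nyquist of the next-coarser level, Nyquist of the affinity
    level) maps to (s/4, s/2) cycles per image; 0.375*s sits mid-band.
    """
    return 0.375 * affinity_scale / resolution


def _paint_texture(
    canvas: np.ndarray,
    rng: np.random.Generator,
    freq: float,
    amplitude: float,
    orientation: float | None = None,
) -> None:
    n = canvas.shape[0]
    cy, cx = rng.uniform(0.25 * n, 0.75 * n, size=2)
    sigma = 0.15 * n
    theta = (np.deg2rad(orientation) if orientation is not None
             else rng.uniform(0.0, np.pi))
    phase = rng.uniform(0.0, 2 * np.pi)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    envelope = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    carrier = np.cos(2 * np.pi * freq * (np.cos(theta) * xx + np.sin(theta) * yy) + phase)
    canvas += amplitude * envelope * carrier


def _paint_blob(
    canvas: np.ndarray,
    rng: np.random.Generator,
    amplitude: float,
    sigma_range: tuple[float, float] = (0.065, 0.085),
) -> None:
    n = canvas.shape[0]
    cy, cx = rng.uniform(0.3 * n, 0.7 * n, size=2)
    # default range: 4*sigma diameter >= 25% of the image
    sigma = rng.uniform(*sigma_range) * n
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    canvas += amplitude * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))


def generate_dataset(
    spec: DatasetSpec, return_audit: bool = False
) -> list[ImageRecord] | tuple[list[ImageRecord], pd.DataFrame]:
    """Generate the dataset; a pure function of (spec, seed).

    A finding's label is 1 iff its motif was painted. With ``return_audit``
    the per-image painting bookkeeping is returned as a DataFrame so callers
    can verify label/motif self-consistency.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.resolution
    records: list[ImageRecord] = []
    audit_rows = []
    for i in range(spec.n_images):
        labels = (rng.random(len(spec.findings)) < np.array(
            [f.prevalence for f in spec.findings]
        )).astype(np.int8)
        # smooth background field: coarse random grid upsampled bicubically
        grid = rng.standard_normal((3, 3))
        fld = transform.resize(grid, (n, n), order=3, mode="reflect",
                               anti_aliasing=False)
        canvas = spec.background_level + spec.field_amplitude * fld
        canvas += spec.background_sigma * rng.standard_normal((n, n))
        if spec.mid_noise_sigma > 0:
            # difference-of-Gaussians clutter: gives the coarse frequency
            # bands a genuine noise floor (plain white noise averages away
            # under downsampling, leaving coarse levels unrealistically clean)
            from scipy.ndimage import gaussian_filter

            white = rng.standard_normal((n, n))
            band = (gaussian_filter(white, 0.0078 * n)
                    - gaussian_filter(white, 0.0234 * n))
            band /= max(band.std(), 1e-9)
            canvas += spec.mid_noise_sigma * band
        painted = {}
        for f, lab in zip(spec.findings, labels):
            painted[f.name] = int(lab)
            if not lab:
                continue
            amp = rng.uniform(*f.amplitude)
            if f.kind == "texture":
                _paint_texture(canvas, rng,
                               _texture_frequency(f.affinity_scale, n), amp,
                               f.orientation)
            else:
                _paint_blob(canvas, rng, amp)
            if f.secondary is not None:
                # an independently drawn contrast decorrelates the secondary
                # view's difficulty from the primary's
                amp2 = (rng.uniform(*f.secondary_amplitude)
                        if f.secondary_amplitude is not None
                        else f.secondary_gain * amp)
                if f.secondary == "blob":
                    _paint_blob(canvas, rng, amp2)
                elif f.secondary == "smallblob":
                    _paint_blob(canvas, rng, amp2, sigma_range=(0.025, 0.035))
                elif f.secondary == "texture":
                    _paint_texture(canvas, rng,
                                   _texture_frequency(f.secondary_scale, n),
                                   amp2, f.secondary_orientation)
            for motif in f.extras:
                amp3 = rng.uniform(*motif.amplitude)
                if motif.kind == "texture":
                    _paint_texture(canvas, rng,
                                   _texture_frequency(motif.scale, n),
                                   amp3, motif.orientation)
                elif motif.kind == "smallblob":
                    _paint_blob(canvas, rng, amp3, sigma_range=(0.025, 0.035))
                elif motif.kind == "largeblob":
                    _paint_blob(canvas, rng, amp3, sigma_range=(0.10, 0.13))
                else:
                    _paint_blob(canvas, rng, amp3)
        pixels = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
        rec = ImageRecord(image_id=f"img{i:05d}", pixels=pixels, labels=labels)
        if spec.noise is not None:
            noisy = inject_noise(rec, spec.noise, seed=int(rng.integers(2**31)))
            rec = ImageRecord(rec.image_id, noisy.pixels, labels)
        records.append(rec)
        audit_rows.append({"image_id": rec.image_id, **painted})
    if return_audit:
        return records, pd.DataFrame(audit_rows).set_index("image_id")
    return records


def inject_noise(record: ImageRecord, noise: NoiseSpec, seed: int) -> ImageRecord:
    """Add periodic + Gaussian + impulse contamination; output clipped to [0, 255].

    Periodic terms are cosines with frequency pairs in cycles per image, so a
    term at (8, 0) puts two conjugate peaks at row-frequency bins +-8. The
    caller retains the clean record as the PSNR reference.
    """
    noise.validate()
    rng = np.random.default_rng(seed)
    h, w = record.pixels.shape
    out = record.pixels.astype(np.float64)
    if noise.periodic:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        for (fu, fv), amp in noise.periodic:
            out += amp * np.cos(2 * np.pi * (fu * yy / h + fv * xx / w))
    if noise.gaussian_sigma > 0:
        out += rng.normal(0.0, noise.gaussian_sigma, size=(h, w))
    if noise.impulse_fraction > 0:
        hits = rng.random((h, w)) < noise.impulse_fraction
        out[hits] = np.where(rng.random((h, w))[hits] < 0.5, 0.0, 255.0)
    pixels = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return ImageRecord(record.image_id, pixels, record.labels)


def crop_patches(
    record: ImageRecord,
    patch: int = 113,
    cap_fraction: float = 0.7,
    n_proposals: int = 10,
    seed: int = 0,
) -> list[ImageRecord]:
    """Random ``patch``-square crops, capped to a fraction of the proposals.

    ``n_proposals`` random top-left corners are drawn (with replacement),
    duplicates dropped, the survivors shuffled, and at most
    ``floor(cap_fraction * n_proposals)`` (never fewer than one when any
    candidate exists) are emitted. Labels are inherited from the source.
    """
    h, w = record.pixels.shape
    if h < patch or w < patch:
        raise ValueError(f"image {record.image_id} ({h}x{w}) smaller than patch {patch}")
    if not 0.0 <= cap_fraction <= 1.0:
        raise ValueError("cap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tops = rng.integers(0, h - patch + 1, size=n_proposals)
    lefts = rng.integers(0, w - patch + 1, size=n_proposals)
    uniq = list(dict.fromkeys(zip(tops.tolist(), lefts.tolist())))
    rng.shuffle(uniq)
    keep = min(len(uniq), max(1, int(np.floor(cap_fraction * n_proposals))))
    out = []
    for k, (r, c) in enumerate(uniq[:keep]):
        out.append(
            ImageRecord(
                image_id=f"{record.image_id}_p{k}",
                pixels=record.pixels[r : r + patch, c : c + patch].copy(),
                labels=record.labels.copy(),
            )
        )
    return out


def complementary_scale_spec(
    n_images: int = 2000, seed: int = 42, scales: tuple[int, ...] = (32, 64, 128, 256)
) -> DatasetSpec:
    """The benchmark dataset: four findings, one affinity scale each.

    Texture findings are naturally visible at every scale at or above their
    affinity (best signal-to-noise at the affinity itself); the finest
    texture, visible only at the top scale, carries a weak secondary blob so
    every finding has at least two informative scales.
    """
    s = sorted(scales)
    # Each finding carries a multi-scale signature: one component per
    # frequency band, with contrast peaked at the finding's affinity scale.
    # Design rules that make the scale structure physically true and the
    # ensemble's headroom real:
    # * contrast rises with affinity scale (coarse motifs gain
    #   signal-to-noise from noise-averaging downsampling; the finest
    #   texture competes with full-strength pixel noise), keeping every
    #   finding learnable but off the AUC ceiling;
    # * component contrasts are drawn independently per image, so the
    #   difficulty of a finding's views decorrelates across scales — the
    #   complementarity a stacked ensemble exploits; nested views of a
    #   single motif would instead have strongly correlated errors;
    # * several findings share each band at distinct contrast levels; the
    #   resulting attribution ambiguity acts as scale-specific label noise
    #   with independent errors across scales;
    # * motif orientations stay random per image, which keeps detection an
    #   energy (not template) task.
    if len(s) == 1:  # degenerate single-scale configuration
        findings = [FindingSpec(f"texture_{s[0]}", 0.5, s[0],
                                amplitude=(8.0, 20.0))]
        return DatasetSpec(n_images=n_images, findings=findings,
                           resolution=s[0], seed=seed)
    if len(s) != 4:
        # generic fallback (used by small smoke configurations): one finding
        # per scale, no secondary components
        findings = [FindingSpec("blob_coarse", 0.5, s[0], kind="blob",
                                amplitude=(13.0, 28.0))]
        findings += [FindingSpec(f"texture_{lvl}", 0.5, lvl,
                                 amplitude=(6.0, 16.0)) for lvl in s[1:]]
        return DatasetSpec(n_images=n_images, findings=findings,
                           resolution=max(scales), seed=seed)
    findings = [
        FindingSpec("blob_coarse", 0.5, s[0], kind="blob",
                    amplitude=(14.0, 28.0),
                    extras=[Motif("texture", (6.2, 13.5), scale=s[1])]),
        FindingSpec(f"texture_{s[1]}", 0.5, s[1],
                    amplitude=(6.0, 14.5),
                    extras=[Motif("texture", (13.0, 26.0), scale=s[3])]),
        FindingSpec(f"texture_{s[2]}", 0.5, s[2],
                    amplitude=(8.5, 19.0),
                    extras=[Motif("texture", (4.2, 9.5), scale=s[0])]),
        FindingSpec(f"texture_{s[3]}", 0.5, s[3],
                    amplitude=(11.0, 23.0),
                    # dimmer second blob population: only coarse models can
                    # see blobs at all (sub-noise at fine scales), and the
                    # brightness separation keeps the two blob findings
                    # distinguishable at the coarse scale
                    extras=[Motif("texture", (7.0, 15.0), scale=s[2]),
                            Motif("blob", (10.0, 19.0))]),
    ]
    return DatasetSpec(
        n_images=n_images, findings=findings, resolution=max(scales), seed=seed
    )


def save_dataset(
    records: list[ImageRecord],
    finding_names: list[str],
    out_dir: str | Path,
    image_format: str = "png",
    jpeg_quality: int = 96,
) -> Path:
    """Write images (PNG lossless or JPEG quality 96) and a labels CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = {"png": "png", "jpeg": "jpg"}[image_format]
    rows = []
    for rec in records:
        img = Image.fromarray(rec.pixels, mode="L")
        path = out / f"{rec.image_id}.{ext}"
        if image_format == "jpeg":
            img.save(path, quality=jpeg_quality)
        else:
            img.save(path)
        rows.append({"image_id": rec.image_id,
                     **dict(zip(finding_names, rec.labels.tolist()))})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    return out


def load_dataset(data_dir: str | Path) -> tuple[list[ImageRecord], list[str]]:
    """Read back a directory written by :func:`save_dataset`."""
    data = Path(data_dir)
    table = pd.read_csv(data / "labels.csv")
    finding_names = [c for c in table.columns if c != "image_id"]
    records = []
    for _, row in table.iterrows():
        stem = data / str(row["image_id"])
        path = next(p for p in (stem.with_suffix(".png"), stem.with_suffix(".jpg"))
                    if p.exists())
        pixels = np.asarray(Image.open(path).convert("L"))
        labels = np.array([row[c] for c in finding_names], dtype=np.int8)
        records.append(ImageRecord(str(row["image_id"]), pixels, labels))
    return records, finding_names
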