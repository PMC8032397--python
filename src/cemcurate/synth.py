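"""Seeded synthetic EM-like fixtures: patches, volumes, labeled sets, encoders.

The generators emulate the visual classes the curation pipeline must
distinguish — textured cytoplasm with dark-membraned elliptical
organelles, empty resin, zero-padding frames, low-contrast and
stitching-artifact frames — with analytic ground truth (region masks,
labels, planted duplicates). Every generator is a pure function of its
configuration and seed. No claim of biological realism is made; the
appearance model exists to give each pipeline stage a measurable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .info_filter import label_with_criteria
from .types import LabeledPatchSet, Patch, PatchRecord, SourceImage

UNINFORMATIVE_KINDS = ("resin", "low_contrast", "padding", "artifact")


@dataclass
class SynthConfig:
    """Knobs of the synthetic EM appearance model.

    Intensities follow the regular EM polarity: bright resin/cytoplasm,
    dark membranes. Organelles are ellipses with a dark ring profile and
    a darker textured interior.
    """

    patch_size: int = 224
    n_patches: int = 5000
    duplicate_fraction: float = 0.4
    uninformative_fraction: float = 0.3
    organelle_count: Tuple[int, int] = (3, 8)        # per patch, inclusive
    organelle_radius: Tuple[float, float] = (14.0, 42.0)  # semi-axis, px
    background_mean: float = 160.0
    background_amplitude: float = 25.0
    interior_mean: float = 70.0
    membrane_intensity: float = 20.0
    membrane_width: float = 3.0
    noise_sd: float = 6.0
    drift: float = 0.5            # per-slice warp in pixels (volumes)
    contrast_floor: float = 10.0
    seed: int = 42

    def __post_init__(self):
        for f in (self.duplicate_fraction, self.uninformative_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def _smooth_background(rng: np.random.Generator, shape, mean, amplitude,
                       cells: int = 14) -> np.ndarray:
    """Perlin-like smooth texture: low-res noise bilinearly upsampled."""
    coarse = rng.normal(0.0, 1.0, size=(cells, cells))
    zy = shape[0] / cells
    zx = shape[1] / cells
    smooth = ndimage.zoom(coarse, (zy, zx), order=3)[:shape[0], :shape[1]]
    if smooth.shape != tuple(shape):
        smooth = np.pad(smooth, ((0, shape[0] - smooth.shape[0]),
                                 (0, shape[1] - smooth.shape[1])),
                        mode="edge")
    return mean + amplitude * smooth / max(np.abs(smooth).max(), 1e-9)


def _ellipse_distance(shape, cy, cx, ry, rx, angle) -> np.ndarray:
    """Normalized elliptical radius field (1.0 on the ellipse boundary)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * x + sa * y) / rx
    v = (-sa * x + ca * y) / ry
    return np.sqrt(u**2 + v**2)


def make_informative_patch(cfg: SynthConfig, seed: int):
    """An informative patch: textured cytoplasm plus dark-ringed organelles.

    Returns (image uint8, masks dict) with boolean ``organelle`` and
    ``uniform`` masks; by construction the uniform area stays below 80%.
    """
    rng = np.random.default_rng(seed)
    s = cfg.patch_size
    img = _smooth_background(rng, (s, s), cfg.background_mean,
                             cfg.background_amplitude)
    organelle = np.zeros((s, s), dtype=bool)
    n_org = int(rng.integers(cfg.organelle_count[0], cfg.organelle_count[1] + 1))
    for _ in range(n_org):
        ry = rng.uniform(*cfg.organelle_radius)
        rx = rng.uniform(*cfg.organelle_radius)
        cy = rng.uniform(0.1 * s, 0.9 * s)
        cx = rng.uniform(0.1 * s, 0.9 * s)
        ang = rng.uniform(0, np.pi)
        d = _ellipse_distance((s, s), cy, cx, ry, rx, ang)
        inside = d < 1.0
        rim_frac = cfg.membrane_width / ((ry + rx) / 2.0)
        ring = (d >= 1.0 - rim_frac) & (d < 1.0)
        interior = d < 1.0 - rim_frac
        img[interior] = cfg.interior_mean + 10.0 * rng.standard_normal(
            int(interior.sum()))
        img[ring] = cfg.membrane_intensity
        organelle |= inside
    img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    masks = {"organelle": organelle,
             "uniform": np.zeros((s, s), dtype=bool)}
    return img, masks


def make_uninformative_patch(cfg: SynthConfig, seed: int, kind: str = "resin"):
    """An uninformative patch of the requested failure mode.

    resin: near-uniform bright frame. padding: zero border covering >=80%
    with a small informative corner. low_contrast: textured frame whose
    global contrast sits below the floor. artifact: blocky reconstruction
    seams on an otherwise flat frame.
    """
    if kind not in UNINFORMATIVE_KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    s = cfg.patch_size
    uniform = np.zeros((s, s), dtype=bool)
    artifact = False

    if kind == "resin":
        level = rng.uniform(150, 230)
        img = level + rng.normal(0.0, 1.5, size=(s, s))
        uniform[:] = True
    elif kind == "padding":
        img = np.zeros((s, s), dtype=float)
        # informative content confined to a corner block of < 20% area
        side = int(np.sqrt(0.18) * s)
        sub_cfg = SynthConfig(patch_size=side, seed=cfg.seed,
                              organelle_count=(1, 2),
                              organelle_radius=(8.0, 18.0))
        block, _ = make_informative_patch(sub_cfg, int(rng.integers(2**31)))
        img[:side, :side] = block
        uniform[:] = True
        uniform[:side, :side] = False
    elif kind == "low_contrast":
        base, _ = make_informative_patch(
            SynthConfig(patch_size=s, seed=cfg.seed, noise_sd=cfg.noise_sd),
            int(rng.integers(2**31)))
        center = rng.uniform(100, 160)
        span = 0.6 * cfg.contrast_floor  # target std well under the floor
        b = base.astype(float)
        scale = span / max(b.std(), 1e-9)
        img = center + (b - b.mean()) * scale
    else:  # artifact: misregistered tile seams
        level = rng.uniform(120, 200)
        img = level + rng.normal(0.0, 1.5, size=(s, s))
        n_seams = int(rng.integers(2, 5))
        for _ in range(n_seams):
            pos = int(rng.integers(20, s - 20))
            horizontal = rng.random() < 0.5
            jump = rng.uniform(25, 60) * (1 if rng.random() < 0.5 else -1)
            if horizontal:
                img[pos:, :] += jump
                img[pos:pos + 2, :] = 10
            else:
                img[:, pos:] += jump
                img[:, pos:pos + 2] = 10
        uniform[:] = True
        artifact = True

    img = np.clip(img, 0, 255).astype(np.uint8)
    masks = {"organelle": np.zeros((s, s), dtype=bool), "uniform": uniform,
             "artifact": artifact, "kind": kind}
    return img, masks


def make_volume(cfg: SynthConfig, depth: int, seed: int,
                shape: Optional[Tuple[int, int]] = None,
                spacing_nm: Optional[Tuple[float, float, float]] = None,
                source_id: str = "synthvol") -> SourceImage:
    """A 3D stack whose adjacent slices are near-duplicates.

    The base slice is warped slice-to-slice by ``cfg.drift`` pixels of
    smooth displacement plus fresh speckle, mimicking the redundancy of
    consecutive sections in a high-resolution volume. ``drift = 0`` makes
    every slice byte-identical to the base.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    h, w = shape if shape is not None else (2 * cfg.patch_size,
                                            2 * cfg.patch_size)
    base_cfg = SynthConfig(patch_size=max(h, w), seed=cfg.seed,
                           organelle_count=(8, 16),
                           organelle_radius=cfg.organelle_radius,
                           noise_sd=cfg.noise_sd)
    base, _ = make_informative_patch(base_cfg, int(rng.integers(2**31)))
    base = base[:h, :w].astype(float)
    slices = [base.copy()]
    current = base
    for _ in range(depth - 1):
        if cfg.drift == 0:
            slices.append(base.copy())
            continue
        dy = rng.uniform(-cfg.drift, cfg.drift)
        dx = rng.uniform(-cfg.drift, cfg.drift)
        current = ndimage.shift(current, (dy, dx), order=1, mode="reflect")
        current = current + rng.normal(0.0, 1.0, size=current.shape)
        current = np.clip(current, 0, 255)
        slices.append(current.copy())
    vol = np.stack(slices).astype(np.uint8)
    return SourceImage(source_id=source_id, pixels=vol, spacing_nm=spacing_nm)


def make_filter_dataset(cfg: SynthConfig, n: int, seed: int) -> LabeledPatchSet:
    """A labeled informative/uninformative patch set with a 75/25 split.

    The uninformative share is exactly round(n * uninformative_fraction),
    cycled over the four failure modes; labels are the generator's ground
    truth (which matches the 80%-uniform-area / contrast / artifact
    criteria by construction).
    """
    if n < 40:
        raise ValueError("need n >= 40 for a meaningful split")
    rng = np.random.default_rng(seed)
    n_unin = int(round(n * cfg.uninformative_fraction))
    patches: List[Patch] = []
    labels = np.ones(n, dtype=int)
    masks = []
    for i in range(n):
        child = int(rng.integers(2**31))
        if i < n_unin:
            kind = UNINFORMATIVE_KINDS[i % len(UNINFORMATIVE_KINDS)]
            img, m = make_uninformative_patch(cfg, child, kind)
            labels[i] = 0
        else:
            img, m = make_informative_patch(cfg, child)
        rec = PatchRecord(patch_id=f"synth-{i}", source_id="synthetic")
        patches.append(Patch(image=img, record=rec))
        masks.append(m)
    perm = rng.permutation(n)
    n_train = int(round(0.75 * n))
    return LabeledPatchSet(patches=patches, labels=labels,
                           train_idx=perm[:n_train], test_idx=perm[n_train:],
                           masks=masks)


def make_corpus(cfg: SynthConfig, seed: int, n_sources: int = 10):
    """Stacked patch sources with planted duplicates and uninformative frames.

    ``cfg.n_patches`` patches are spread over ``n_sources`` anisotropic
    3D stacks of patch-sized slices (so standardization yields exactly
    one xy patch per slice). A ``duplicate_fraction`` share of slices are
    near-copies (sub-pixel shift + light noise) of earlier slices in the
    same stack; of the fresh slices, ``uninformative_fraction`` are
    uninformative frames.

    Returns (sources, truth) where truth maps patch ids (as emitted by
    ``standardize_source``) to {"duplicate_of": id or None, "label": 0/1}.
    """
    rng = np.random.default_rng(seed)
    s = cfg.patch_size
    per_source = [cfg.n_patches // n_sources] * n_sources
    for i in range(cfg.n_patches - sum(per_source)):
        per_source[i] += 1
    sources = []
    truth = {}
    kind_cycle = 0
    for si, depth in enumerate(per_source):
        source_id = f"stack{si:02d}"
        slices = []
        originals: List[int] = []  # indices of fresh slices
        for zi in range(depth):
            pid = f"{source_id}-xy-{zi}-0-0"
            if originals and rng.random() < cfg.duplicate_fraction:
                ref = int(originals[int(rng.integers(len(originals)))])
                # perturbation kept small enough that even near-flat frames
                # stay within the Hamming cutoff of their original
                img = slices[ref].astype(float)
                img = ndimage.shift(img, rng.uniform(-0.3, 0.3, 2),
                                    order=1, mode="reflect")
                img = np.clip(img + rng.normal(0, 0.3, img.shape), 0, 255)
                slices.append(img.astype(np.uint8))
                truth[pid] = {"duplicate_of": f"{source_id}-xy-{ref}-0-0",
                              "label": truth[f"{source_id}-xy-{ref}-0-0"]["label"]}
            else:
                child = int(rng.integers(2**31))
                if rng.random() < cfg.uninformative_fraction:
                    kind = UNINFORMATIVE_KINDS[kind_cycle % 4]
                    kind_cycle += 1
                    img, _ = make_uninformative_patch(cfg, child, kind)
                    label = 0
                else:
                    img, _ = make_informative_patch(cfg, child)
                    label = 1
                slices.append(img)
                originals.append(zi)
                truth[pid] = {"duplicate_of": None, "label": label}
        vol = np.stack(slices)
        sources.append(SourceImage(source_id=source_id, pixels=vol,
                                   spacing_nm=(50.0, 10.0, 10.0)))
    return sources, truth


# ---------------------------------------------------------------------------
# toy encoders


class _ToyEncoder:
    """Base: deterministic encoder with fixed pooled dimension."""

    def pooled(self, image):  # pragma: no cover - overridden
        raise NotImplementedError

    def feature_maps(self, image):
        image = np.asarray(image, dtype=float)
        h, w = image.shape
        return image[: h - h % 2, : w - w % 2].reshape(
            1, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


class GlobalMeanEncoder(_ToyEncoder):
    """D = 1: the global pixel mean. Exactly invariant to permutations."""

    def pooled(self, image):
        return np.array([np.asarray(image, dtype=float).mean()])


class CornerPixelEncoder(_ToyEncoder):
    """D = 1: the value of the top-left pixel. Maximally location-bound."""

    def pooled(self, image):
        return np.array([float(np.asarray(image)[0, 0])])


class RandomConvEncoder(_ToyEncoder):
    """A bank of seeded random 5x5 convolution kernels (stride-2 maps)."""

    def __init__(self, seed: int = 42, n_channels: int = 8):
        rng = np.random.default_rng(seed)
        self.kernels = rng.normal(0, 1, size=(n_channels, 5, 5))
        self.kernels -= self.kernels.mean(axis=(1, 2), keepdims=True)

    def feature_maps(self, image):
        image = np.asarray(image, dtype=float)
        maps = [np.abs(ndimage.convolve(image, k, mode="reflect"))[::2, ::2]
                for k in self.kernels]
        return np.stack(maps)

    def pooled(self, image):
        return self.feature_maps(image).mean(axis=(1, 2))


class PlantedFilterEncoder(RandomConvEncoder):
    """Random-conv bank whose channel ``planted_channel`` is an organelle
    detector: a Gaussian-smoothed indicator of dark pixels (organelle
    interiors and membranes are the dark structures in the appearance
    model)."""

    planted_channel = 0

    def __init__(self, seed: int = 42, n_channels: int = 8,
                 dark_threshold: float = 110.0, smooth_sigma: float = 2.0):
        super().__init__(seed=seed, n_channels=n_channels)
        self.dark_threshold = dark_threshold
        self.smooth_sigma = smooth_sigma

    def feature_maps(self, image):
        maps = super().feature_maps(image)
        image = np.asarray(image, dtype=float)
        detector = ndimage.gaussian_filter(
            (image < self.dark_threshold).astype(float), self.smooth_sigma)
        maps[self.planted_channel] = detector[::2, ::2]
        return maps


def make_toy_encoder(kind: str, seed: int = 42):
    """Instantiate a deterministic toy encoder satisfying the contract."""
    kinds = {
        "global_mean": lambda: GlobalMeanEncoder(),
        "corner_pixel": lambda: CornerPixelEncoder(),
        "random_conv": lambda: RandomConvEncoder(seed=seed),
        "planted_filter": lambda: PlantedFilterEncoder(seed=seed),
    }
    if kind not in kinds:
        raise ValueError(f"unknown encoder kind {kind!r}")
    return kinds[kind]()
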