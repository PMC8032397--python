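"""Standardization of heterogeneous 2D/3D EM data into 224x224 uint8 patches.

Pipeline per source: intensity normalization to 8-bit, optional polarity
inversion, size-budget downsampling (volumes), orthogonal-plane slicing
governed by voxel anisotropy, and non-overlapping 224-grid tiling with
edge-anchored remainder windows.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

from .types import (
    MIN_KEEP,
    PATCH_SIZE,
    Patch,
    PatchRecord,
    SlicePlan,
    SourceImage,
)

#: Relative z-spacing deviation below which a volume counts as isotropic.
ANISOTROPY_TOLERANCE = 0.20
#: Per-dataset size budget in bytes before downsampling kicks in.
MAX_SOURCE_BYTES = 5_000_000_000


def normalize_to_uint8(pixels: np.ndarray, *, source_id: str = "<array>",
                       clip_percentiles: Optional[Tuple[float, float]] = None
                       ) -> np.ndarray:
    """Affinely map an array's intensity range onto [0, 255] uint8.

    8-bit unsigned input passes through unchanged. Constant input maps to
    all zeros (degenerate range). Optionally clip to percentiles first.
    Non-finite values raise, naming the source.
    """
    pixels = np.asarray(pixels)
    if pixels.dtype == np.uint8 and clip_percentiles is None:
        return pixels
    arr = pixels.astype(np.float64)
    if not np.isfinite(arr).all():
        raise ValueError(f"source {source_id!r}: non-finite pixel values")
    if clip_percentiles is not None:
        lo, hi = np.percentile(arr, clip_percentiles)
        arr = np.clip(arr, lo, hi)
    vmin, vmax = arr.min(), arr.max()
    if vmax == vmin:
        return np.zeros_like(arr, dtype=np.uint8)
    # floor of 255*(v-min)/(max-min); upper bound attained only at v=max
    out = np.floor(255.0 * (arr - vmin) / (vmax - vmin))
    return np.clip(out, 0, 255).astype(np.uint8)


def plan_planes(spacing_nm: Optional[Sequence[float]]) -> SlicePlan:
    """Decide which orthogonal planes to slice from a volume.

    All three planes (xy, xz, yz) are sliced when spacing metadata is
    present and the z spacing deviates from the mean lateral spacing by
    strictly less than 20%; otherwise only xy. Missing spacing is treated
    conservatively as anisotropic.
    """
    if spacing_nm is None:
        return SlicePlan(planes=("xy",))
    z, y, x = (float(s) for s in spacing_nm)
    if z <= 0 or y <= 0 or x <= 0:
        raise ValueError(f"spacing must be positive, got {(z, y, x)}")
    lateral = (x + y) / 2.0
    deviation = abs(z - lateral) / lateral
    if deviation < ANISOTROPY_TOLERANCE:
        return SlicePlan(planes=("xy", "xz", "yz"))
    return SlicePlan(planes=("xy",))


def downsample_to_budget(volume: np.ndarray, max_bytes: int = MAX_SOURCE_BYTES
                         ) -> Tuple[np.ndarray, Tuple[int, int, int]]:
    """Stride-subsample a volume until it fits a byte budget.

    The smallest uniform integer stride f (applied to all three axes)
    whose result is no larger than ``max_bytes`` is used; f = 1 leaves
    the volume untouched. Returns the (possibly) reduced volume and the
    per-axis factors.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("downsample_to_budget expects a 3D volume")
    if max_bytes < 1:
        raise ValueError("max_bytes must be >= 1")
    f = 1
    while True:
        sub = volume[::f, ::f, ::f]
        if sub.nbytes <= max_bytes:
            return sub, (f, f, f)
        f += 1


def slice_volume(volume: np.ndarray, plan: SlicePlan
                 ) -> Iterator[Tuple[str, int, np.ndarray]]:
    """Yield every 2D cross-section of the planes in ``plan``, in axis order.

    Volume axes are (z, y, x): xy sections iterate over z, xz over y,
    yz over x.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("slice_volume expects a 3D volume")
    d, h, w = volume.shape
    if "xy" in plan.planes:
        for i in range(d):
            yield "xy", i, volume[i, :, :]
    if "xz" in plan.planes:
        for i in range(h):
            yield "xz", i, volume[:, i, :]
    if "yz" in plan.planes:
        for i in range(w):
            yield "yz", i, volume[:, :, i]


def _axis_offsets(dim: int, size: int, min_keep: int):
    """Offsets of non-overlapping windows along one axis.

    Full grid windows first; a remainder strip of width >= ``min_keep``
    adds one edge-anchored full window. Returns (offsets, flags, pad)
    where flags mark edge-anchored windows and pad signals the whole
    axis is shorter than ``size`` but still keepable.
    """
    if dim < min_keep:
        return [], [], False
    if dim < size:
        return [0], [False], True
    n_full = dim // size
    offsets = [i * size for i in range(n_full)]
    flags = [False] * n_full
    remainder = dim - n_full * size
    if remainder >= min_keep:
        offsets.append(dim - size)
        flags.append(True)
    return offsets, flags, False


def _reflect_pad_to(image: np.ndarray, size: int) -> np.ndarray:
    pad_y = max(size - image.shape[0], 0)
    pad_x = max(size - image.shape[1], 0)
    if pad_y == 0 and pad_x == 0:
        return image
    return np.pad(image, ((0, pad_y), (0, pad_x)), mode="reflect")


def tile_image(image: np.ndarray
               ) -> Iterator[Tuple[int, int, np.ndarray, dict]]:
    """Cut a 2D image into non-overlapping 224x224 crops.

    Full grid crops are emitted in row-major order. A remainder strip of
    width in [112, 224) along an axis yields edge-anchored full windows
    (offset dim-224, flagged ``edge_anchored``). Strips narrower than 112
    are discarded. Images shorter than 224 but at least 112 on an axis
    are reflect-padded to 224 on that axis and flagged ``padded``; images
    narrower than 112 on any axis produce nothing.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("tile_image expects a 2D image")
    h, w = image.shape
    ys, yflags, ypad = _axis_offsets(h, PATCH_SIZE, MIN_KEEP)
    xs, xflags, xpad = _axis_offsets(w, PATCH_SIZE, MIN_KEEP)
    if not ys or not xs:
        return
    padded = ypad or xpad
    src = _reflect_pad_to(image, PATCH_SIZE) if padded else image
    for y0, yf in zip(ys, yflags):
        for x0, xf in zip(xs, xflags):
            crop = src[y0:y0 + PATCH_SIZE, x0:x0 + PATCH_SIZE]
            yield y0, x0, crop, {"edge_anchored": yf or xf, "padded": padded}


def sample_random_patches(volume: np.ndarray, n: int = 1000,
                          seed: int = 42, source_id: str = "<volume>"
                          ) -> list:
    """Uniformly sample n 224x224 patches from a volume's xy planes.

    Slice indices and top-left offsets are drawn independently and
    uniformly; reproducible under a fixed seed.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("sample_random_patches expects a 3D volume")
    d, h, w = volume.shape
    if h < MIN_KEEP or w < MIN_KEEP:
        raise ValueError(
            f"volume xy extent {h}x{w} too small to sample {PATCH_SIZE} patches"
        )
    rng = np.random.default_rng(seed)
    patches = []
    for i in range(int(n)):
        z = int(rng.integers(0, d))
        plane = volume[z]
        if h < PATCH_SIZE or w < PATCH_SIZE:
            plane = _reflect_pad_to(plane, PATCH_SIZE)
            y0 = x0 = 0
            padded = True
        else:
            y0 = int(rng.integers(0, h - PATCH_SIZE + 1))
            x0 = int(rng.integers(0, w - PATCH_SIZE + 1))
            padded = False
        img = normalize_to_uint8(
            plane[y0:y0 + PATCH_SIZE, x0:x0 + PATCH_SIZE], source_id=source_id
        )
        rec = PatchRecord(
            patch_id=f"{source_id}-rand{i}", source_id=source_id,
            plane="xy", slice_index=z, y0=y0, x0=x0, padded=padded,
        )
        patches.append(Patch(image=img, record=rec))
    return patches


def standardize_source(src: SourceImage, *, max_bytes: int = MAX_SOURCE_BYTES,
                       unify_polarity: bool = False,
                       clip_percentiles: Optional[Tuple[float, float]] = None
                       ) -> Iterator[Patch]:
    """Standardize one source into provenance-tagged 224x224 uint8 patches.

    Volumes are normalized, budget-downsampled, sliced per the anisotropy
    rule, then each section is tiled; 2D images skip the volume steps.
    When ``unify_polarity`` is set, sources flagged inverted are negated
    after normalization.
    """
    pixels = normalize_to_uint8(src.pixels, source_id=src.source_id,
                                clip_percentiles=clip_percentiles)
    if unify_polarity and src.inverted:
        pixels = (255 - pixels.astype(np.int16)).astype(np.uint8)
    if pixels.ndim == 2:
        sections = [("xy", 0, pixels)]
    else:
        pixels, factors = downsample_to_budget(pixels, max_bytes)
        plan = plan_planes(src.spacing_nm)
        plan.downsample_factors = factors
        sections = slice_volume(pixels, plan)
    for plane, idx, section in sections:
        for y0, x0, crop, flags in tile_image(section):
            rec = PatchRecord(
                patch_id=f"{src.source_id}-{plane}-{idx}-{y0}-{x0}",
                source_id=src.source_id,
                plane=plane, slice_index=idx, y0=y0, x0=x0,
                edge_anchored=flags["edge_anchored"],
                padded=flags["padded"],
            )
            yield Patch(image=np.ascontiguousarray(crop), record=rec)
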