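"""Representation probes for image encoders.

Three analyses quantify what an encoder has learned, against a minimal
encoder contract (``pooled`` vectors and spatial ``feature_maps``):

* invariance — mean firing rates of selective neurons under parametric
  image distortions, with per-neuron firing thresholds calibrated on
  random-noise inputs;
* selectivity — Point-Biserial correlation of each feature map against a
  binary ground-truth mask, summarized by the mean of the top-k maps;
* occlusion — importance of image regions measured as the drop in
  pooled-vector dot-product similarity when a window is zeroed out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, Tuple, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .types import PATCH_SIZE

#: Identity level of each distortion family (level at which the image is unchanged).
IDENTITY_LEVELS = {
    "rotation": 0.0, "blur": 0.0, "noise": 0.0,
    "brightness": 1.0, "contrast": 1.0, "scale": 1.0,
}


@runtime_checkable
class Encoder(Protocol):
    """Contract every probed encoder must satisfy (deterministic)."""

    def pooled(self, image: np.ndarray) -> np.ndarray:
        """Globally pooled activation vector of fixed length D."""
        ...

    def feature_maps(self, image: np.ndarray) -> np.ndarray:
        """(C, h, w) stack of spatial feature maps at the declared stride."""
        ...


@dataclass
class InvarianceCurve:
    transform: str
    levels: np.ndarray
    mean_firing_rate: np.ndarray  # in [0, 1], one value per level
    n_selective: int


@dataclass
class SelectivityResult:
    r_pb: np.ndarray            # per-channel Point-Biserial coefficients
    top_channels: np.ndarray    # channel indices of the k most correlated maps
    heatmap: np.ndarray         # mean of top-k maps, rescaled to [0, 1]
    mask: np.ndarray            # heatmap >= threshold
    iou_vs_truth: float


@dataclass
class OcclusionResult:
    grid: np.ndarray            # per-window normalized importance, [0, 1]
    heatmap: np.ndarray         # grid upsampled to image size, [0, 1]
    window: int = 61
    stride: int = 30


def firing_thresholds(encoder: Encoder, n_noise: int = 1000,
                      seed: int = 42,
                      image_shape: Tuple[int, int] = (PATCH_SIZE, PATCH_SIZE)
                      ) -> np.ndarray:
    """Per-neuron 99th percentile of pooled responses to random noise.

    Noise images have pixels iid uniform on [0, 255]. Activations above
    this threshold count as the neuron "firing".
    """
    if n_noise < 100:
        raise ValueError("n_noise < 100 gives unstable 99th percentiles")
    rng = np.random.default_rng(seed)
    responses = np.stack([
        np.asarray(encoder.pooled(
            rng.integers(0, 256, size=image_shape).astype(np.uint8)))
        for _ in range(n_noise)
    ])
    return np.percentile(responses, 99, axis=0)


def select_Z(encoder: Encoder, images: Sequence[np.ndarray],
             thresholds: np.ndarray):
    """Near-maximal image sets Z and the selective-neuron mask.

    For each neuron, Z is the set of probe images whose response exceeds
    the neuron's 90th percentile over the probe set — operationally the
    top ceil(0.1 n) responses in descending order, index as tiebreak. A
    neuron is selective iff every image in its Z fires it strictly above
    its noise-calibrated threshold.
    """
    images = list(images)
    if not images:
        raise ValueError("probe image set is empty")
    resp = np.stack([np.asarray(encoder.pooled(im)) for im in images])  # (n, D)
    n, D = resp.shape
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (D,):
        raise ValueError(f"expected {D} thresholds, got {thresholds.shape}")
    k = int(np.ceil(0.1 * n))
    # stable argsort on negated responses: descending, index breaks ties
    order = np.argsort(-resp, axis=0, kind="stable")
    Z = order[:k, :].T  # (D, k) image indices per neuron
    z_resp = np.take_along_axis(resp, order[:k, :], axis=0).T
    selective = z_resp.min(axis=1) > thresholds
    return Z, selective


def apply_distortion(image: np.ndarray, transform: str, level: float,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Apply one parametric distortion; identity levels return the input.

    rotation: degrees about center, reflect padding. blur: Gaussian,
    sigma=level. noise: additive Gaussian sd=level (seeded rng), clipped.
    brightness: pixel*level, clipped. contrast: (pixel-mean)*level+mean,
    clipped. scale: center zoom by factor level, bilinear resample.
    """
    if transform not in IDENTITY_LEVELS:
        raise ValueError(f"unknown transform {transform!r}")
    image = np.asarray(image)
    if float(level) == IDENTITY_LEVELS[transform]:
        return image
    arr = image.astype(np.float64)

    if transform == "rotation":
        out = ndimage.rotate(arr, float(level), reshape=False,
                             mode="reflect", order=1)
    elif transform == "blur":
        out = ndimage.gaussian_filter(arr, sigma=float(level))
    elif transform == "noise":
        if rng is None:
            rng = np.random.default_rng(0)
        out = arr + rng.normal(0.0, float(level), size=arr.shape)
    elif transform == "brightness":
        out = arr * float(level)
    elif transform == "contrast":
        m = arr.mean()
        out = (arr - m) * float(level) + m
    elif transform == "scale":
        f = float(level)
        h, w = arr.shape
        zoomed = resize(arr, (max(1, round(h * f)), max(1, round(w * f))),
                        order=1, mode="reflect", anti_aliasing=f < 1,
                        preserve_range=True)
        zh, zw = zoomed.shape
        if zh >= h and zw >= w:  # zoom in: central crop
            y0, x0 = (zh - h) // 2, (zw - w) // 2
            out = zoomed[y0:y0 + h, x0:x0 + w]
        else:  # zoom out: reflect-pad back to size
            py, px = h - zh, w - zw
            out = np.pad(zoomed,
                         ((py // 2, py - py // 2), (px // 2, px - px // 2)),
                         mode="reflect")
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out


def mean_firing_rate_curve(encoder: Encoder, images: Sequence[np.ndarray],
                           transform: str, levels: Sequence[float],
                           thresholds: np.ndarray,
                           seed: int = 42) -> InvarianceCurve:
    """Mean firing rate of selective neurons across distortion strengths.

    Per level and selective neuron: the fraction of that neuron's
    near-maximal images Z whose distorted versions still fire it above
    its threshold, averaged over selective neurons.
    """
    images = list(images)
    Z, selective = select_Z(encoder, images, thresholds)
    if not selective.any():
        raise ValueError(
            "no selective neurons: every neuron has some near-maximal image "
            "responding below its noise threshold"
        )
    thresholds = np.asarray(thresholds, dtype=float)
    sel = np.flatnonzero(selective)
    rates = []
    for li, level in enumerate(levels):
        rng = np.random.default_rng(np.random.SeedSequence((seed, li)))
        resp = np.stack([
            np.asarray(encoder.pooled(
                apply_distortion(im, transform, level, rng=rng)))
            for im in images
        ])  # (n, D)
        per_neuron = [
            (resp[Z[d], d] > thresholds[d]).mean() for d in sel
        ]
        rates.append(float(np.mean(per_neuron)))
    return InvarianceCurve(transform=transform,
                           levels=np.asarray(levels, dtype=float),
                           mean_firing_rate=np.asarray(rates),
                           n_selective=int(selective.sum()))


def point_biserial(feature_map: np.ndarray, mask: np.ndarray) -> float:
    """Point-Biserial correlation of a continuous map with a binary mask.

    r_pb = ((M1 - M0) / s) * sqrt(n1 n0 / n^2) with s the population
    standard deviation of the map — identical to the Pearson correlation
    against the 0/1 mask. Degenerate inputs (single-class mask, constant
    map) raise rather than returning NaN.
    """
    x = np.asarray(feature_map, dtype=float).ravel()
    g = np.asarray(mask).astype(bool).ravel()
    if x.shape != g.shape:
        raise ValueError("map and mask shapes differ")
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("mask must contain both classes")
    s = x.std()
    if s == 0:
        raise ValueError("feature map has zero variance")
    n = x.size
    return float((x[g].mean() - x[~g].mean()) / s * np.sqrt(n1 * n0 / n**2))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; 1.0 if both empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def _rescale01(arr: np.ndarray) -> np.ndarray:
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr, dtype=float)
    return (arr - lo) / (hi - lo)


def selectivity_map(encoder: Encoder, image: np.ndarray,
                    truth_mask: np.ndarray, k: int = 32,
                    threshold: float = 0.3) -> SelectivityResult:
    """Rank feature maps by Point-Biserial correlation with a truth mask.

    Each map is bilinearly resized to the image size and correlated with
    the mask; the mean of the k most correlated maps, min-max rescaled to
    [0, 1], is thresholded into a binary segmentation and scored by IoU
    against the truth. Constant maps rank last.
    """
    maps = np.asarray(encoder.feature_maps(image))
    if maps.ndim != 3:
        raise ValueError("feature_maps must return a (C, h, w) stack")
    C = maps.shape[0]
    if k > C:
        raise ValueError(f"k={k} exceeds the {C} available maps")
    truth = np.asarray(truth_mask).astype(bool)
    target = truth.shape
    up = np.stack([
        resize(m.astype(float), target, order=1, mode="reflect",
               preserve_range=True)
        for m in maps
    ])
    r = np.full(C, -np.inf)
    for c in range(C):
        try:
            r[c] = point_biserial(up[c], truth)
        except ValueError:
            continue  # constant map: leave at -inf, never top-k
    if np.isinf(r).all():
        raise ValueError("all feature maps are constant")
    top = np.argsort(-r, kind="stable")[:k]
    heat = _rescale01(up[top].mean(axis=0))
    mask = heat >= threshold
    return SelectivityResult(r_pb=r, top_channels=top, heatmap=heat,
                             mask=mask, iou_vs_truth=iou(mask, truth))


def occlusion_map(encoder: Encoder, image: np.ndarray,
                  reference: np.ndarray, window: int = 61,
                  stride: int = 30, fill: float = 0) -> OcclusionResult:
    """Occlusion-sensitivity analysis of pooled-vector similarity.

    Windows of ``window`` pixels spaced every ``stride`` are zeroed out
    (filled) one at a time; importance of a window is the drop in
    dot-product similarity to the reference view, min-max normalized over
    the grid and bilinearly upsampled for overlay.
    """
    image = np.asarray(image)
    reference = np.asarray(reference)
    if image.shape != reference.shape:
        raise ValueError("image and reference shapes differ")
    h, w = image.shape
    if window > min(h, w):
        raise ValueError("occlusion window larger than the image")
    ref_vec = np.asarray(encoder.pooled(reference), dtype=float)
    s_full = float(np.dot(np.asarray(encoder.pooled(image), dtype=float),
                          ref_vec))
    ny = (h - window) // stride + 1
    nx = (w - window) // stride + 1
    grid = np.empty((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            occluded = image.copy()
            occluded[iy * stride:iy * stride + window,
                     ix * stride:ix * stride + window] = fill
            s_occ = float(np.dot(
                np.asarray(encoder.pooled(occluded), dtype=float), ref_vec))
            grid[iy, ix] = s_full - s_occ
    norm = _rescale01(grid)
    heat = resize(norm, image.shape, order=1, mode="reflect",
                  preserve_range=True)
    return OcclusionResult(grid=norm, heatmap=np.clip(heat, 0.0, 1.0),
                           window=window, stride=stride)
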