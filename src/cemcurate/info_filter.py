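"""Informative/uninformative patch classification.

Four image-level texture statistics (std of the local-binary-pattern map,
std of the local entropy map, median of the local geometric mean, mean of
the Canny edge map) feed a Random Forest; patches scoring below a
confidence threshold are culled. A patch is uninformative when 80% or
more of its area is uniform-intensity (resin, padding, homogeneous
interiors), when its global contrast is too low, or when it is dominated
by a reconstruction artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.feature import canny, local_binary_pattern
from sklearn.ensemble import RandomForestClassifier

from .types import LabeledPatchSet, Patch, PatchFeatures

#: Fraction of uniform-intensity area at or above which a patch is uninformative.
UNIFORM_AREA_CUTOFF = 0.80
DEFAULT_THRESHOLD = 0.5

DEFAULT_FEATURE_CONFIG = {
    "lbp_points": 8,
    "lbp_radius": 1,
    "lbp_method": "uniform",
    "entropy_window": 15,
    "entropy_bins": 16,
    "geomean_window": 5,
    "canny_sigma": 1.0,
    "canny_low": 0.1,
    "canny_high": 0.2,
}


def local_entropy(img8: np.ndarray, window: int = 15, bins: int = 16
                  ) -> np.ndarray:
    """Shannon entropy (bits) of the binned intensity histogram in a
    sliding square window, via per-bin integral images (reflect-padded).

    A constant image has zero entropy everywhere.
    """
    q = (np.asarray(img8, dtype=np.uint16) * bins // 256).astype(np.uint8)
    r = window // 2
    pad = np.pad(q, r, mode="reflect")
    h2, w2 = pad.shape
    ii = np.zeros((bins, h2 + 1, w2 + 1), dtype=np.int32)
    ii[:, 1:, 1:] = pad[None] == np.arange(bins, dtype=np.uint8)[:, None, None]
    ii.cumsum(axis=1, out=ii)
    ii.cumsum(axis=2, out=ii)
    counts = (ii[:, window:, window:] - ii[:, :-window, window:]
              - ii[:, window:, :-window] + ii[:, :-window, :-window])
    p = counts.astype(np.float32) / (window * window)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=0)


def extract_features(image: np.ndarray,
                     feature_config: Optional[dict] = None) -> PatchFeatures:
    """Compute the four texture statistics of a 224x224 uint8 patch.

    Deterministic; window sizes come from ``feature_config`` (defaults:
    LBP with 8 neighbors radius 1 uniform, 16-bin entropy in a 15x15
    window, geometric mean over a 5x5 window on intensities+1, Canny at
    sigma 1 with hysteresis at 0.1/0.2 of the intensity range).
    """
    cfg = dict(DEFAULT_FEATURE_CONFIG)
    if feature_config:
        cfg.update(feature_config)
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("extract_features expects a 2D image")
    img8 = image.astype(np.uint8)

    r = cfg["lbp_radius"]
    lbp = local_binary_pattern(img8, cfg["lbp_points"], r,
                               method=cfg["lbp_method"])
    lbp = lbp[r:-r, r:-r]  # border codes read past the image; drop them
    ent = local_entropy(img8, window=cfg["entropy_window"],
                        bins=cfg["entropy_bins"])
    # geometric mean filter on intensities+1 (avoids log 0), shifted back
    logs = np.log(img8.astype(np.float64) + 1.0)
    geomean = np.exp(uniform_filter(logs, size=cfg["geomean_window"])) - 1.0
    # Canny on the [0,1]-scaled image: hysteresis thresholds are fractions
    # of the full intensity range, so flat noise yields no edges.
    edges = canny(img8.astype(np.float64) / 255.0, sigma=cfg["canny_sigma"],
                  low_threshold=cfg["canny_low"],
                  high_threshold=cfg["canny_high"],
                  use_quantiles=False)

    return PatchFeatures(
        lbp_std=float(lbp.std()),
        entropy_std=float(ent.std()),
        geomean_median=float(np.median(geomean)),
        canny_mean=float(edges.mean()),
    )


@dataclass
class FilterModel:
    """Trained informativeness classifier with its decision threshold."""

    classifier: RandomForestClassifier
    threshold: float = DEFAULT_THRESHOLD
    feature_config: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_CONFIG))
    seed: int = 42

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def _features_matrix(patches: Sequence, feature_config: dict) -> np.ndarray:
    imgs = (p.image if isinstance(p, Patch) else np.asarray(p) for p in patches)
    return np.stack([extract_features(im, feature_config).as_vector()
                     for im in imgs])


def train_filter(train: LabeledPatchSet, seed: int = 42,
                 n_trees: int = 500,
                 feature_config: Optional[dict] = None) -> FilterModel:
    """Fit the Random Forest on the training split of a labeled patch set.

    Class-1 probability is the fraction of tree votes for the informative
    class. Both classes must be present; at least 20 examples required.
    """
    cfg = dict(DEFAULT_FEATURE_CONFIG)
    if feature_config:
        cfg.update(feature_config)
    idx = np.asarray(train.train_idx, dtype=int)
    if idx.size < 20:
        raise ValueError("need at least 20 training examples")
    y = train.labels[idx]
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = _features_matrix([train.patches[i] for i in idx], cfg)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                n_jobs=1)
    rf.fit(X, y)
    return FilterModel(classifier=rf, feature_config=cfg, seed=seed)


def predict_informative(patches: Sequence, model: FilterModel,
                        feature_config: Optional[dict] = None
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Score patches; informative iff probability >= model.threshold."""
    cfg = feature_config or model.feature_config
    if cfg != model.feature_config:
        raise ValueError("feature_config differs from the one frozen at training")
    X = _features_matrix(patches, model.feature_config)
    classes = list(model.classifier.classes_)
    proba = model.classifier.predict_proba(X)[:, classes.index(1)]
    return proba, proba >= model.threshold


def evaluate_auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Ties between a positive and a negative score earn half credit.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    from scipy.stats import rankdata
    ranks = rankdata(scores)  # midranks handle ties -> half credit
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def label_with_criteria(patch: np.ndarray,
                        uniform_mask: np.ndarray,
                        contrast_floor: float = 10.0,
                        artifact: bool = False) -> int:
    """Ground-truth informativeness label from known region masks.

    Uninformative (0) iff the uniform-intensity area covers >= 80% of the
    patch, the global intensity standard deviation falls below
    ``contrast_floor``, or the patch is flagged as an artifact /
    non-cellular object. Otherwise informative (1).
    """
    patch = np.asarray(patch)
    uniform_mask = np.asarray(uniform_mask, dtype=bool)
    if artifact:
        return 0
    if uniform_mask.mean() >= UNIFORM_AREA_CUTOFF:
        return 0
    if float(patch.std()) < contrast_floor:
        return 0
    return 1


@dataclass
class CallableFilter:
    """Plugin point for an external patch classifier.

    Wraps any callable mapping a 2D uint8 patch to an informative
    probability (e.g. a fine-tuned deep model) behind the same surface as
    :class:`FilterModel`, so ``filter_corpus`` can use either.
    """

    score_fn: Callable[[np.ndarray], float]
    threshold: float = DEFAULT_THRESHOLD

    def predict(self, patches: Sequence) -> Tuple[np.ndarray, np.ndarray]:
        imgs = (p.image if isinstance(p, Patch) else np.asarray(p)
                for p in patches)
        proba = np.array([float(self.score_fn(im)) for im in imgs])
        return proba, proba >= self.threshold


def filter_corpus(records: Iterable[dict],
                  image_loader: Callable[[dict], np.ndarray],
                  model: FilterModel):
    """Apply a trained filter to a manifest, retaining informative patches.

    Returns the retained records (each annotated with its probability)
    and a report with per-patch scores and the retained fraction.
    """
    records = list(records)
    failures = []
    images = []
    for rec in records:
        try:
            images.append(image_loader(rec))
        except Exception as exc:  # noqa: BLE001
            failures.append(f"{rec.get('patch_id')}: {exc}")
    if failures:
        raise IOError("unreadable patch images: " + "; ".join(failures))
    if not records:
        return [], {"n_input": 0, "n_kept": 0, "retained_fraction": 0.0,
                    "scores": {}}
    if isinstance(model, CallableFilter):
        proba, keep = model.predict(images)
    else:
        proba, keep = predict_informative(images, model)
    kept = []
    scores = {}
    for rec, p, k in zip(records, proba, keep):
        scores[rec["patch_id"]] = float(p)
        if k:
            rec = dict(rec)
            rec["probability"] = float(p)
            kept.append(rec)
    report = {
        "n_input": len(records),
        "n_kept": len(kept),
        "retained_fraction": len(kept) / len(records),
        "threshold": model.threshold,
        "scores": scores,
    }
    return kept, report
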