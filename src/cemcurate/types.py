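"""Core domain types shared across the curation pipeline.

The atomic unit throughout is the *patch*: a 224x224 8-bit unsigned
grayscale crop with full provenance back to its source image or volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

PATCH_SIZE = 224
#: Remainder strips (or whole images) narrower than this are discarded.
MIN_KEEP = 112

PLANES = ("xy", "xz", "yz")


@dataclass
class SourceImage:
    """A 2D image or 3D volume as ingested, before standardization.

    Parameters
    ----------
    source_id : str
        Unique identifier of the source dataset within a corpus.
    pixels : ndarray
        2D (H, W) or 3D (D, H, W) scalar array, any integer/float dtype.
    spacing_nm : tuple of float, optional
        Voxel spacing as (z, y, x) in nanometers. Only meaningful for
        volumes; ``None`` means unknown (treated as anisotropic).
    inverted : bool
        Whether intensities are inverted relative to the corpus polarity
        convention (dark membranes on light background).
    """

    source_id: str
    pixels: np.ndarray
    spacing_nm: Optional[tuple] = None
    inverted: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(
                f"source {self.source_id!r}: pixels must be 2D or 3D, "
                f"got {self.pixels.ndim}D"
            )
        if self.spacing_nm is not None:
            self.spacing_nm = tuple(float(s) for s in self.spacing_nm)
            if len(self.spacing_nm) != 3:
                raise ValueError("spacing_nm must be a (z, y, x) triple")
            if any(s <= 0 for s in self.spacing_nm):
                raise ValueError(
                    f"source {self.source_id!r}: spacing must be positive, "
                    f"got {self.spacing_nm}"
                )

    @property
    def kind(self) -> str:
        return "volume3d" if self.pixels.ndim == 3 else "image2d"


@dataclass
class SlicePlan:
    """Which orthogonal planes to slice and the downsampling applied."""

    planes: tuple = ("xy",)
    downsample_factors: tuple = (1, 1, 1)

    def __post_init__(self):
        self.planes = tuple(self.planes)
        if not self.planes:
            raise ValueError("plan must contain at least one plane")
        if "xy" not in self.planes:
            raise ValueError("xy plane is always sliced")
        for p in self.planes:
            if p not in PLANES:
                raise ValueError(f"unknown plane {p!r}")
        if any(int(f) < 1 for f in self.downsample_factors):
            raise ValueError("downsample factors must be >= 1")
        self.downsample_factors = tuple(int(f) for f in self.downsample_factors)


@dataclass
class PatchRecord:
    """Provenance of one patch: where in which source it was cut from."""

    patch_id: str
    source_id: str
    plane: str = "xy"
    slice_index: int = 0
    y0: int = 0
    x0: int = 0
    edge_anchored: bool = False
    padded: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PatchRecord":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class Patch:
    """A standardized 224x224 uint8 image plus its provenance record."""

    image: np.ndarray
    record: PatchRecord

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"patch {self.record.patch_id!r}: shape must be "
                f"{PATCH_SIZE}x{PATCH_SIZE}, got {self.image.shape}"
            )
        if self.image.dtype != np.uint8:
            raise ValueError(
                f"patch {self.record.patch_id!r}: dtype must be uint8, "
                f"got {self.image.dtype}"
            )


@dataclass
class PatchHash:
    """64-bit difference hash of one patch (hash_size**2 ordered bits)."""

    patch_id: str
    source_id: str
    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool).ravel()


@dataclass
class DuplicateGroup:
    """A connected component of near-duplicate patches from one source."""

    member_ids: frozenset
    exemplar_id: Optional[str] = None

    def __post_init__(self):
        self.member_ids = frozenset(self.member_ids)
        if not self.member_ids:
            raise ValueError("duplicate group cannot be empty")
        if self.exemplar_id is not None and self.exemplar_id not in self.member_ids:
            raise ValueError("exemplar must be a group member")


@dataclass
class PatchFeatures:
    """The four image-level texture statistics used by the quality filter.

    lbp_std
        Standard deviation of the local-binary-pattern code map.
    entropy_std
        Standard deviation of the local entropy map (bits).
    geomean_median
        Median of the locally geometric-mean-filtered image.
    canny_mean
        Mean of the binary Canny edge map (edge-pixel fraction in [0, 1]).
    """

    lbp_std: float
    entropy_std: float
    geomean_median: float
    canny_mean: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.lbp_std, self.entropy_std, self.geomean_median, self.canny_mean],
            dtype=float,
        )

    FEATURE_NAMES = ("lbp_std", "entropy_std", "geomean_median", "canny_mean")


@dataclass
class LabeledPatchSet:
    """Patches with binary informative labels and a train/test split."""

    patches: list  # of Patch
    labels: np.ndarray  # 1 = informative
    train_idx: np.ndarray
    test_idx: np.ndarray
    masks: list = field(default_factory=list)  # per-patch ground-truth masks

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train and test sets overlap")
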