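"""Near-duplicate removal via 64-bit difference hashes.

Each patch is hashed with dHash (signs of adjacent-pixel differences on
an area-averaged 9x8 reduction); patches of the same source dataset whose
hashes fall within a Hamming-distance cutoff are linked into groups
(single-linkage connected components), and one random exemplar per group
survives.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Callable, Dict, Iterable, List, Optional, Sequence

import numpy as np
from PIL import Image
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .types import DuplicateGroup, PatchHash

DEFAULT_HASH_SIZE = 8
#: Hamming distance below which two hashes are near-duplicates (strict).
DEFAULT_CUTOFF = 12


def dhash(image: np.ndarray, hash_size: int = DEFAULT_HASH_SIZE) -> np.ndarray:
    """Difference hash of a 2D grayscale image.

    The image is reduced with area averaging to (hash_size+1) columns by
    hash_size rows; bit (r, c) is 1 iff pixel (r, c) < pixel (r, c+1),
    serialized row-major. Returns a boolean vector of length hash_size**2.
    """
    if hash_size < 1:
        raise ValueError("hash_size must be >= 1")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("dhash expects a 2D image")
    pil = Image.fromarray(image.astype(np.float32), mode="F")
    small = np.asarray(
        pil.resize((hash_size + 1, hash_size), Image.Resampling.BOX),
        dtype=np.float64,
    )
    return (small[:, :-1] < small[:, 1:]).ravel()


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing bit positions between two equal-length bit vectors."""
    a = np.asarray(a, dtype=bool).ravel()
    b = np.asarray(b, dtype=bool).ravel()
    if a.shape != b.shape:
        raise ValueError(f"hash length mismatch: {a.size} vs {b.size}")
    return int(np.count_nonzero(a != b))


def _pairwise_hamming(bits: np.ndarray) -> np.ndarray:
    """Full Hamming distance matrix for an (n, nbits) boolean array."""
    b = bits.astype(np.uint8)
    # XOR popcount via dot products: d = a(1-b') + (1-a)b'
    ones = b @ (1 - b.T)
    return ones + ones.T


def group_near_duplicates(hashes: Sequence[PatchHash],
                          cutoff: int = DEFAULT_CUTOFF) -> List[DuplicateGroup]:
    """Partition one source's hashes into near-duplicate groups.

    Groups are the connected components of the graph with an edge between
    any two hashes at Hamming distance strictly below ``cutoff``
    (single-linkage: chains merge transitively). Singletons are groups
    of size one.
    """
    hashes = list(hashes)
    if not hashes:
        return []
    sources = {h.source_id for h in hashes}
    if len(sources) > 1:
        raise ValueError(
            f"group_near_duplicates compares within one source; got {sorted(sources)}"
        )
    bits = np.stack([h.bits for h in hashes])
    dist = _pairwise_hamming(bits)
    adj = coo_matrix(dist < cutoff)
    n_comp, labels = connected_components(adj, directed=False)
    members: Dict[int, set] = defaultdict(set)
    for h, lab in zip(hashes, labels):
        members[int(lab)].add(h.patch_id)
    return [DuplicateGroup(member_ids=members[c]) for c in range(n_comp)]


def select_exemplars(groups: Sequence[DuplicateGroup], seed: int = 42) -> set:
    """Keep one uniformly random member id per group, reproducibly.

    Groups are visited sorted by their smallest member id with a single
    seeded generator, so the result is independent of input order.
    """
    for g in groups:
        if not g.member_ids:
            raise ValueError("empty duplicate group")
    rng = np.random.default_rng(seed)
    kept = set()
    for g in sorted(groups, key=lambda g: min(g.member_ids)):
        ids = sorted(g.member_ids)
        choice = ids[int(rng.integers(0, len(ids)))]
        g.exemplar_id = choice
        kept.add(choice)
    return kept


def deduplicate_corpus(records: Iterable[dict],
                       image_loader: Callable[[dict], np.ndarray],
                       cutoff: int = DEFAULT_CUTOFF,
                       seed: int = 42,
                       hash_size: int = DEFAULT_HASH_SIZE):
    """Deduplicate a patch corpus, comparing hashes only within each source.

    Parameters
    ----------
    records : iterable of dict
        Manifest records; must carry ``patch_id`` and ``source_id``.
    image_loader : callable
        Maps a record to its 2D uint8 patch image.

    Returns
    -------
    kept_records : list of dict
    report : dict
        Group-size histogram, per-source group counts, and the overall
        reduction fraction (dropped / total).
    """
    records = list(records)
    by_source: Dict[str, List[dict]] = defaultdict(list)
    for rec in records:
        by_source[rec["source_id"]].append(rec)

    kept_ids = set()
    size_hist: Dict[int, int] = defaultdict(int)
    groups_per_source = {}
    failures = []
    for source_id in sorted(by_source):
        hashes = []
        for rec in by_source[source_id]:
            try:
                img = image_loader(rec)
            except Exception as exc:  # noqa: BLE001 - report offenders together
                failures.append(f"{rec.get('patch_id')}: {exc}")
                continue
            hashes.append(PatchHash(patch_id=rec["patch_id"],
                                    source_id=source_id,
                                    bits=dhash(img, hash_size)))
        if failures:
            continue
        groups = group_near_duplicates(hashes, cutoff)
        groups_per_source[source_id] = len(groups)
        for g in groups:
            size_hist[len(g.member_ids)] += 1
        kept_ids |= select_exemplars(groups, seed)
    if failures:
        raise IOError("unreadable patch images: " + "; ".join(failures))

    kept = [rec for rec in records if rec["patch_id"] in kept_ids]
    total = len(records)
    report = {
        "n_input": total,
        "n_kept": len(kept),
        "reduction_fraction": (total - len(kept)) / total if total else 0.0,
        "group_size_histogram": dict(sorted(size_hist.items())),
        "groups_per_source": groups_per_source,
        "cutoff": cutoff,
        "hash_size": hash_size,
    }
    return kept, report
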