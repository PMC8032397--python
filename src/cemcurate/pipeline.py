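"""End-to-end curation: standardize -> deduplicate -> filter.

One corpus seed fans out deterministically to per-stage seeds (via
``numpy.random.SeedSequence([seed, stage_index])``) so each stage is
independently reproducible. Stage reports mirror the corpus narrative:
raw patch count, deduplicated count, filtered count, and the reduction
fraction of each step.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional

import numpy as np

from . import io
from .config import CurateConfig
from .dedup import deduplicate_corpus
from .info_filter import FilterModel, filter_corpus, train_filter
from .ingest import standardize_source
from .synth import SynthConfig, make_filter_dataset

logger = logging.getLogger("cemcurate")

_STAGE_INDEX = {"standardize": 0, "dedup": 1, "filter": 2, "train": 3}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the corpus seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def default_filter_model(seed: int, n: int = 400) -> FilterModel:
    """Train the informativeness filter on a synthetic labeled set.

    Used when ``curate`` is not handed a pre-trained model; the labeled
    set stands in for a manually annotated subset of the corpus.
    """
    cfg = SynthConfig(uninformative_fraction=0.5, seed=seed)
    labeled = make_filter_dataset(cfg, n=n, seed=seed)
    return train_filter(labeled, seed=seed)


def curate(input_dir, output_dir, config: Optional[CurateConfig] = None,
           seed: Optional[int] = None,
           model: Optional[FilterModel] = None) -> dict:
    """Run the full curation pipeline over a directory of source files.

    Writes per-patch TIFFs plus stage manifests (raw / dedup / filtered)
    under ``output_dir`` and returns the stage report.
    """
    config = config or CurateConfig()
    seed = config.seed if seed is None else int(seed)
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    files = io.discover_sources(input_dir)
    if not files:
        raise FileNotFoundError(f"no readable source images in {input_dir}")

    patch_dir = output_dir / "patches"
    records: List[dict] = []
    for f in files:
        src = io.load_source(f)
        for patch in standardize_source(
                src, max_bytes=config.max_source_bytes,
                unify_polarity=config.unify_polarity,
                clip_percentiles=config.clip_percentiles):
            path = io.write_patch(patch, patch_dir)
            records.append(io.patch_to_record(patch, path, stage="raw"))
    io.write_manifest(records, output_dir / "manifest_raw.jsonl")
    logger.info("standardize: %d sources -> %d raw patches",
                len(files), len(records))

    kept, dedup_report = deduplicate_corpus(
        records, io.record_loader, cutoff=config.cutoff,
        seed=stage_seed(seed, "dedup"), hash_size=config.hash_size)
    for rec in kept:
        rec["stage"] = "dedup"
    io.write_manifest(kept, output_dir / "manifest_dedup.jsonl")
    logger.info("dedup: %d -> %d patches (reduction %.3f)",
                len(records), len(kept), dedup_report["reduction_fraction"])

    if model is None:
        model = default_filter_model(stage_seed(seed, "train"))
    model.threshold = config.threshold
    filtered, filter_report = filter_corpus(kept, io.record_loader, model)
    for rec in filtered:
        rec["stage"] = "filtered"
    io.write_manifest(filtered, output_dir / "manifest_filtered.jsonl")
    logger.info("filter: %d -> %d patches (retained %.3f)",
                len(kept), len(filtered), filter_report["retained_fraction"])

    return {
        "n_sources": len(files),
        "n_raw": len(records),
        "n_dedup": len(kept),
        "n_filtered": len(filtered),
        "dedup_reduction": dedup_report["reduction_fraction"],
        "filter_retained": filter_report["retained_fraction"],
        "dedup_report": {k: v for k, v in dedup_report.items()
                         if k != "groups_per_source"},
        "seed": seed,
    }
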