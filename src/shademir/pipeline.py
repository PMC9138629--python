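"""End-to-end orchestration: clean -> catalog -> DE -> scan -> degradome ->
integrate, on an in-memory bundle or on files, with a machine-readable
manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import degradome as deg
from . import expression as expr
from . import integrate as integ
from . import smallrna as sr
from . import targets as tgt
from .simulate import Bundle, derive_seed
from .targets import AllenParams, DEFAULT_PARAMS

logger = logging.getLogger(__name__)

__all__ = ["RunParams", "PipelineResult", "run_bundle", "run_files"]


@dataclass(frozen=True)
class RunParams:
    """All pipeline thresholds with their shortlist-paper defaults."""

    length_bounds: tuple[int, int] = (17, 25)
    min_quality: int = 30
    adapter: str | None = None
    max_mismatch: int = 2
    energy_threshold: float = -18.0
    fc_cutoff: float = 1.0
    p_cutoff: float = 0.9
    unique_min_count: float = 5.0
    pseudocount: float = 1.0
    target_cutoff: float = 0.25
    allen_threshold: float = 7.0
    refine_margin: float = 4.0
    min_tag_len: int = 16
    max_category: int = 4
    n_shuffles: int = 100
    seed: int = 0
    allen_params: AllenParams = DEFAULT_PARAMS


@dataclass
class PipelineResult:
    tags: list
    counts: pd.DataFrame
    calls: list
    target_records: list
    hits: list
    pairs: list
    shortlist: pd.DataFrame
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_bundle(bundle: Bundle, params: RunParams = RunParams()) -> PipelineResult:
    """Run the full analysis on an in-memory bundle."""
    t0 = time.perf_counter()
    stage_counts: dict[str, int] = {}

    tags = sr.collapse_libraries(
        bundle.reads,
        adapter=params.adapter,
        min_quality=params.min_quality,
        length_bounds=params.length_bounds,
    )
    stage_counts["tags"] = len(tags)
    logger.info("clean: %d unique tags (%.2fs)", len(tags), time.perf_counter() - t0)

    reference = [sr.MirnaRecord(mid, seq) for mid, seq in bundle.mirnas.items()]
    _assignments, counts = sr.match_known(tags, reference, params.max_mismatch)
    stage_counts["mirnas_detected"] = int((counts.sum(axis=1) > 0).sum())

    calls = expr.classify_mirna(
        counts,
        bundle.conditions,
        fc_cutoff=params.fc_cutoff,
        p_cutoff=params.p_cutoff,
        unique_min_count=params.unique_min_count,
        pseudocount=params.pseudocount,
    )
    call_by_id = {c.feature_id: c for c in calls}
    stage_counts["regulation_calls"] = len(calls)

    target_records = expr.classify_targets(bundle.target_table, params.target_cutoff)
    record_by_id = {r.transcript_id: r for r in target_records}
    stage_counts["target_records"] = len(target_records)

    profiles = deg.build_profiles(
        bundle.degradome_tags, bundle.transcripts, params.min_tag_len
    )
    stage_counts["degradome_positions"] = sum(
        len(p.tag5_counts) for p in profiles.values()
    )

    hits: list[deg.CleavageHit] = []
    for mid in sorted(bundle.mirnas):
        mseq = bundle.mirnas[mid]
        alignments = tgt.scan_targets(
            mseq,
            bundle.transcripts,
            params.allen_threshold,
            params.allen_params,
            mirna_id=mid,
            refine_margin=params.refine_margin,
        )
        for aln in alignments:
            hit = deg.coincidence_filter(aln, profiles[aln.transcript_id])
            if hit is None or hit.category > params.max_category:
                continue
            hit.p_value = deg.site_pvalue(
                hit,
                profiles[aln.transcript_id],
                mseq,
                bundle.transcripts[aln.transcript_id],
                n_shuffles=params.n_shuffles,
                seed=derive_seed(params.seed, mid, aln.transcript_id),
                params=params.allen_params,
                refine_margin=params.refine_margin,
            )
            hits.append(hit)
    stage_counts["cleavage_hits"] = len(hits)

    pairs: list[integ.RegulatoryPair] = []
    for hit in hits:
        call = call_by_id.get(hit.alignment.mirna_id)
        record = record_by_id.get(hit.transcript_id)
        if call is None or record is None:
            logger.info(
                "pair %s/%s skipped: missing %s",
                hit.alignment.mirna_id,
                hit.transcript_id,
                "regulation call" if call is None else "expression record",
            )
            continue
        pairs.append(integ.classify_pair(call, record, hit))
    stage_counts["pairs"] = len(pairs)

    shortlist = integ.build_shortlist(pairs)
    stage_counts["shortlist"] = len(shortlist)
    logger.info("pipeline done in %.2fs: %s", time.perf_counter() - t0, stage_counts)
    return PipelineResult(
        tags, counts, calls, target_records, hits, pairs, shortlist, stage_counts
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_files(
    bundle_dir: str | Path,
    outdir: str | Path,
    params: RunParams = RunParams(),
) -> PipelineResult:
    """Run on a bundle directory written by the simulator (or assembled by
    hand in the same layout) and write output tables plus a manifest."""
    from .simulate import load_bundle

    bundle_dir = Path(bundle_dir)
    if not (bundle_dir / "manifest.json").exists():
        raise FileNotFoundError(f"no manifest.json in {bundle_dir}")
    bundle = load_bundle(bundle_dir)
    result = run_bundle(bundle, params)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sr.tags_to_frame(result.tags).to_csv(out / "tags.tsv", sep="\t", index=False)
    result.counts.rename_axis("mirna").to_csv(out / "mirna_counts.tsv", sep="\t")
    expr.calls_to_frame(result.calls).to_csv(
        out / "mirna_regulation.tsv", sep="\t", index=False
    )
    integ.pairs_to_frame(result.pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)
    result.shortlist.to_csv(out / "shortlist.tsv", sep="\t", index=False)

    cfg = dataclasses.asdict(params)
    cfg["allen_params"] = dataclasses.asdict(params.allen_params)
    cfg_json = json.dumps(cfg, sort_keys=True)
    manifest = {
        "params": cfg,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "inputs": {
            p.name: _checksum(p) for p in sorted(bundle_dir.iterdir()) if p.is_file()
        },
        "stage_counts": result.stage_counts,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result
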