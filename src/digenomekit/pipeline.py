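"""Workflow orchestration: specificity and efficiency runs, config handling.

Two workflows mirror how a staggered-cutting nuclease is characterised:

* specificity — in-vitro digested WGS alignments are reduced to strand
  5'-end pileups, scored per position under the 1-5 nt overhang sweep,
  thresholded and merged into cleavage calls, annotated against the
  PAM-anchored candidate-site scan, and (optionally) cross-checked by
  amplicon indel quantification at each called site;
* efficiency — amplicon FASTQs are quantified into per-amplicon indel
  frequencies with the in-frame/out-of-frame split.

All thresholds live in one validated config namespace; nothing scientific
is hard-coded.  Reruns with the same config and inputs are byte-identical,
and every output is listed in a JSON manifest with its SHA-256 checksum.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import endpileup, digenome, sitescan, indelquant
from .endpileup import AlignmentFilter
from .digenome import ScoringParams
from .indelquant import AmpliconConfig
from .sitescan import GuideTarget

__all__ = [
    "PipelineConfig",
    "PipelineConfigError",
    "validate_config",
    "run_specificity",
    "run_efficiency",
]

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline config:\n" + "\n".join(errors))


@dataclass
class PipelineConfig:
    guide: GuideTarget
    genome_fasta: str | None
    digest_alignments: str | None  # SAM/BAM of the in-vitro digested WGS
    amplicons: dict[str, dict]  # id -> {"fastq": path, "config": AmpliconConfig}
    scoring: ScoringParams = field(default_factory=ScoringParams)
    alignment_filter: AlignmentFilter = field(default_factory=AlignmentFilter)
    max_mismatches: int = 4
    annotate_window: int = 25
    window_size: int = 100_000
    track_floor: float = 0.1
    outdir: str = "out"
    seed: int = 0


_DEFAULTS_NOTE = {
    "scoring.cutoff": 2.5,
    "scoring.overhang_min": 1,
    "scoring.overhang_max": 5,
    "max_mismatches": 4,
}


def validate_config(source) -> PipelineConfig:
    """Normalise a YAML path / dict into a :class:`PipelineConfig`.

    Fills defaults (cutoff 2.5, overhang sweep 1-5, max_mismatches 4),
    raising :class:`PipelineConfigError` with one message per offending key
    path.  Idempotent: validating an already-validated config is a no-op.
    """
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        raise TypeError("config must be a path, dict, or PipelineConfig")

    errors: list[str] = []

    gdata = data.get("guide")
    guide = None
    if gdata is None:
        errors.append("guide: missing")
    elif isinstance(gdata, GuideTarget):
        guide = gdata
    else:
        try:
            guide = GuideTarget(**gdata)
        except (TypeError, ValueError) as exc:
            errors.append(f"guide: {exc}")

    def _sub(key, cls, default):
        v = data.get(key)
        if v is None:
            return default
        if isinstance(v, cls):
            return v
        try:
            return cls(**v)
        except (TypeError, ValueError) as exc:
            errors.append(f"{key}: {exc}")
            return default

    scoring = _sub("scoring", ScoringParams, ScoringParams())
    filt = _sub("alignment_filter", AlignmentFilter, AlignmentFilter())

    amplicons: dict[str, dict] = {}
    for amp_id, spec in (data.get("amplicons") or {}).items():
        if isinstance(spec.get("config"), AmpliconConfig):
            cfg = spec["config"]
        else:
            try:
                cfg = AmpliconConfig(amplicon_id=amp_id, **(spec.get("config") or {}))
            except (TypeError, ValueError) as exc:
                errors.append(f"amplicons.{amp_id}.config: {exc}")
                continue
        fastq = spec.get("fastq")
        if fastq is None:
            errors.append(f"amplicons.{amp_id}.fastq: missing")
            continue
        amplicons[amp_id] = {"fastq": fastq, "config": cfg}

    mm = data.get("max_mismatches", 4)
    if not isinstance(mm, int) or mm < 0:
        errors.append("max_mismatches: must be a non-negative integer")

    genome = data.get("genome_fasta")
    digest = data.get("digest_alignments")
    for key, path in (("genome_fasta", genome), ("digest_alignments", digest)):
        if path is not None and not Path(str(path)).exists():
            errors.append(f"{key}: path {path!r} does not exist")
    for amp_id, spec in amplicons.items():
        if not Path(str(spec["fastq"])).exists():
            errors.append(f"amplicons.{amp_id}.fastq: path {spec['fastq']!r} does not exist")

    if errors:
        raise PipelineConfigError(errors)

    return PipelineConfig(
        guide=guide,
        genome_fasta=genome,
        digest_alignments=digest,
        amplicons=amplicons,
        scoring=scoring,
        alignment_filter=filt,
        max_mismatches=mm,
        annotate_window=int(data.get("annotate_window", 25)),
        window_size=int(data.get("window_size", 100_000)),
        track_floor=float(data.get("track_floor", 0.1)),
        outdir=str(data.get("outdir", "out")),
        seed=int(data.get("seed", 0)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, outputs: dict[str, Path]) -> Path:
    manifest = {
        name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
        for name, p in outputs.items()
    }
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return mpath


def run_specificity(config) -> dict[str, Path]:
    """Score -> call -> annotate -> (optionally) verify by amplicon.

    Writes BED (sites), bedGraph (score track), annotated call TSV, a
    per-site amplicon summary TSV when amplicon inputs are configured, and
    a checksum manifest.  Returns the named output paths.
    """
    cfg = validate_config(config)
    if cfg.digest_alignments is None:
        raise PipelineConfigError(["digest_alignments: required for run_specificity"])
    if cfg.genome_fasta is None:
        raise PipelineConfigError(["genome_fasta: required for run_specificity"])
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = cfg.scoring

    logger.info("stage endpileup+digenome: scanning %s", cfg.digest_alignments)
    track_path = outdir / "cleavage_score.bedgraph"
    calls = []
    first_tile = True
    try:
        tiles = endpileup.stream_pileups(
            cfg.digest_alignments,
            cfg.window_size,
            overlap=params.overhang_max,
            filt=cfg.alignment_filter,
        )
        tile_calls: dict = {}
        for tile in tiles:
            scores, _ = digenome.score_span(tile, params)
            # interior only for the track, so tile overlaps are written once
            interior = min(len(tile), cfg.window_size)
            digenome.export_track(
                tile.contig,
                tile.start,
                scores[:interior],
                track_path,
                floor=cfg.track_floor,
                append=not first_tile,
            )
            first_tile = False
            for c in digenome.scan_genome(tile, params):
                key = (c.contig, c.cut_position)
                prev = tile_calls.get(key)
                if prev is None or c.score > prev.score:
                    tile_calls[key] = c
        calls = digenome.merge_calls(
            [tile_calls[k] for k in sorted(tile_calls)], params.merge_distance
        )
    except Exception as exc:
        raise RuntimeError(f"stage digenome failed: {exc}") from exc
    logger.info("stage digenome: %d merged calls", len(calls))
    if first_tile:  # no tiles at all (empty input): still produce the track file
        import numpy as np

        digenome.export_track("NA", 0, np.empty(0), track_path)

    bed_path = outdir / "cleavage_sites.bed"
    digenome.export_sites(calls, bed_path)
    calls_tsv = outdir / "cleavage_calls.tsv"
    digenome.calls_to_frame(calls).to_csv(calls_tsv, sep="\t", index=False)

    try:
        hits = sitescan.find_candidate_sites(cfg.genome_fasta, cfg.guide, cfg.max_mismatches)
    except Exception as exc:
        raise RuntimeError(f"stage sitescan failed: {exc}") from exc
    logger.info("stage sitescan: %d candidate sites at k<=%d", len(hits), cfg.max_mismatches)
    hits_tsv = outdir / "candidate_sites.tsv"
    sitescan.write_hits(hits, hits_tsv)
    annotated = sitescan.annotate_calls(calls, hits, cfg.guide, window=cfg.annotate_window)
    annotated_tsv = outdir / "annotated_calls.tsv"
    annotated.to_csv(annotated_tsv, sep="\t", index=False)

    outputs = {
        "cleavage_sites_bed": bed_path,
        "cleavage_score_bedgraph": track_path,
        "cleavage_calls_tsv": calls_tsv,
        "candidate_sites_tsv": hits_tsv,
        "annotated_calls_tsv": annotated_tsv,
    }

    if cfg.amplicons:
        try:
            summary_tsv = outdir / "site_indel_summary.tsv"
            indelquant.batch_quantify(
                {k: v["fastq"] for k, v in cfg.amplicons.items()},
                {k: v["config"] for k, v in cfg.amplicons.items()},
                out_tsv=summary_tsv,
            )
        except Exception as exc:
            raise RuntimeError(f"stage indelquant failed: {exc}") from exc
        outputs["site_indel_summary_tsv"] = summary_tsv

    outputs["manifest"] = _write_manifest(outdir, outputs)
    return outputs


def run_efficiency(config) -> dict[str, Path]:
    """Per-amplicon indel quantification (editing-efficiency workflow)."""
    cfg = validate_config(config)
    if not cfg.amplicons:
        raise PipelineConfigError(["amplicons: at least one required for run_efficiency"])
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary_tsv = outdir / "amplicon_indel_summary.tsv"
    try:
        indelquant.batch_quantify(
            {k: v["fastq"] for k, v in cfg.amplicons.items()},
            {k: v["config"] for k, v in cfg.amplicons.items()},
            out_tsv=summary_tsv,
        )
    except Exception as exc:
        raise RuntimeError(f"stage indelquant failed: {exc}") from exc
    outputs = {"amplicon_indel_summary_tsv": summary_tsv}
    outputs["manifest"] = _write_manifest(outdir, outputs)
    return outputs
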