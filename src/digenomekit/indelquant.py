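"""Amplicon deep-seq indel quantification with reading-frame classification.

Each read is globally aligned to its amplicon reference (affine gaps; the
reference may overhang the read's ends without penalty, so truncated reads
still align).  Insertions/deletions whose footprint overlaps the padded
guide window count the read as an indel read; substitutions never do.  The
per-amplicon summary reports the indel frequency, the split of indel reads
into in-frame and out-of-frame by the net-length-change mod-3 rule, and a
ranked table of mutant patterns keyed by their left-normalised op lists.

A gap of length L is penalised gap_open + L * gap_extend.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO

__all__ = [
    "AlignScores",
    "AmpliconConfig",
    "IndelOp",
    "ReadAlignment",
    "IndelEvent",
    "IndelSummary",
    "align_read",
    "call_indels",
    "summarize",
    "quantify_fastq",
    "batch_quantify",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignScores:
    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0


@dataclass
class AmpliconConfig:
    amplicon_id: str
    amplicon_reference: str
    guide_window: tuple[int, int]  # 0-based half-open span of protospacer+PAM
    window_pad: int = 5
    min_read_length: int = 30
    scores: AlignScores = field(default_factory=AlignScores)

    def __post_init__(self) -> None:
        self.amplicon_reference = self.amplicon_reference.upper()
        w0, w1 = self.guide_window
        if not 0 <= w0 < w1 <= len(self.amplicon_reference):
            raise ValueError("guide_window must lie inside the amplicon")
        if self.window_pad < 0:
            raise ValueError("window_pad must be non-negative")

    @property
    def padded_window(self) -> tuple[int, int]:
        w0, w1 = self.guide_window
        return max(0, w0 - self.window_pad), min(len(self.amplicon_reference), w1 + self.window_pad)


@dataclass(frozen=True)
class IndelOp:
    kind: str  # "ins" or "del"
    position: int  # reference coordinate (for ins: insertion point)
    length: int
    inserted: str = ""

    def signature(self) -> str:
        if self.kind == "ins":
            return f"ins@{self.position}x{self.length}:{self.inserted}"
        return f"del@{self.position}x{self.length}"


@dataclass
class ReadAlignment:
    score: float
    ops: list[IndelOp]
    ref_start: int
    ref_end: int


@dataclass
class IndelEvent:
    read_id: str
    ops: list[IndelOp]
    net_length_change: int
    in_window: bool


@dataclass
class IndelSummary:
    amplicon_id: str
    total_reads: int
    analyzed_reads: int
    indel_reads: int
    indel_frequency: float | None  # percent; None when no analyzable reads
    out_of_frame_fraction: float | None  # percent of indel reads
    patterns: list[tuple[str, int, str]]  # (signature, count, frame class)


@lru_cache(maxsize=16)
def _aligner(scores: AlignScores) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scores.match
    a.mismatch_score = scores.mismatch
    # gap of length L costs gap_open + L * gap_extend
    a.open_gap_score = scores.gap_open + scores.gap_extend
    a.extend_gap_score = scores.gap_extend
    # reference overhang beyond the read's ends is free (end-gap-free on the
    # read): gaps in the query at its ends are unpenalised
    a.open_left_deletion_score = 0
    a.extend_left_deletion_score = 0
    a.open_right_deletion_score = 0
    a.extend_right_deletion_score = 0
    return a


def _left_normalize(ops: list[IndelOp], ref: str) -> list[IndelOp]:
    """VCF-style left alignment of each gap within repeated context."""
    out = []
    for op in ops:
        p = op.position
        if op.kind == "del":
            l = op.length
            while p > 0 and ref[p - 1] == ref[p + l - 1]:
                p -= 1
            out.append(IndelOp("del", p, l))
        else:
            s = op.inserted
            while p > 0 and s and s[-1] == ref[p - 1]:
                s = ref[p - 1] + s[:-1]
                p -= 1
            out.append(IndelOp("ins", p, op.length, s))
    out.sort(key=lambda o: (o.position, o.kind))
    return out


def align_read(read: str, config: AmpliconConfig) -> ReadAlignment:
    """Affine-gap alignment of one read to the amplicon reference.

    Raises ``ValueError`` for reads shorter than ``min_read_length`` (the
    batch layer excludes and counts them).  Gap placement is deterministic
    and left-normalised.
    """
    read = read.upper()
    if len(read) < config.min_read_length:
        raise ValueError(f"read shorter than min_read_length={config.min_read_length}")
    ref = config.amplicon_reference
    aln = _aligner(config.scores).align(ref, read)[0]
    tblocks, qblocks = aln.aligned
    ops: list[IndelOp] = []
    for (t1s, t1e), (q1s, q1e), (t2s, t2e), (q2s, q2e) in (
        (tblocks[i], qblocks[i], tblocks[i + 1], qblocks[i + 1])
        for i in range(len(tblocks) - 1)
    ):
        dgap = t2s - t1e  # reference advanced with no read bases: deletion
        igap = q2s - q1e  # read advanced with no reference bases: insertion
        if dgap > 0:
            ops.append(IndelOp("del", t1e, dgap))
        if igap > 0:
            ops.append(IndelOp("ins", t2s, igap, read[q1e:q2s]))
    ops = _left_normalize(ops, ref)
    ref_start = int(tblocks[0][0]) if len(tblocks) else 0
    ref_end = int(tblocks[-1][1]) if len(tblocks) else 0
    return ReadAlignment(score=float(aln.score), ops=ops, ref_start=ref_start, ref_end=ref_end)


def call_indels(alignment: ReadAlignment, config: AmpliconConfig, read_id: str = "") -> IndelEvent:
    """Windowed indel call for one aligned read.

    An op overlaps the padded window if its reference footprint intersects
    it (insertions are points; window boundaries count).  Substitutions are
    never indels.
    """
    w0, w1 = config.padded_window
    in_window = False
    net = 0
    for op in alignment.ops:
        if op.kind == "del":
            net -= op.length
            if op.position < w1 and op.position + op.length > w0:
                in_window = True
        else:
            net += op.length
            if w0 <= op.position <= w1:
                in_window = True
    return IndelEvent(read_id=read_id, ops=alignment.ops, net_length_change=net, in_window=in_window)


def summarize(events: Sequence[IndelEvent], total_reads: int, amplicon_id: str = "") -> IndelSummary:
    """Aggregate per-read events into the amplicon-level editing outcome.

    ``indel_frequency`` is 100 * indel_reads / analyzed_reads (None, not 0,
    when nothing was analyzable); the frame split is over indel reads only
    and always totals 100.
    """
    analyzed = len(events)
    indel_events = [e for e in events if e.in_window and e.ops]
    n_indel = len(indel_events)
    freq = 100.0 * n_indel / analyzed if analyzed else None
    oof = None
    if n_indel:
        out = sum(1 for e in indel_events if e.net_length_change % 3 != 0)
        oof = 100.0 * out / n_indel
    counts: dict[str, list] = {}
    for e in indel_events:
        sig = "+".join(op.signature() for op in e.ops)
        frame = "out-of-frame" if e.net_length_change % 3 != 0 else "in-frame"
        if sig not in counts:
            counts[sig] = [0, frame]
        counts[sig][0] += 1
    patterns = sorted(
        ((sig, c, fr) for sig, (c, fr) in counts.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return IndelSummary(
        amplicon_id=amplicon_id,
        total_reads=total_reads,
        analyzed_reads=analyzed,
        indel_reads=n_indel,
        indel_frequency=freq,
        out_of_frame_fraction=oof,
        patterns=patterns,
    )


def quantify_fastq(fastq, config: AmpliconConfig) -> IndelSummary:
    """Align + call + summarise one amplicon FASTQ."""
    events: list[IndelEvent] = []
    total = 0
    short = 0
    for rec in SeqIO.parse(str(fastq), "fastq"):
        total += 1
        seq = str(rec.seq)
        if len(seq) < config.min_read_length:
            short += 1
            continue
        aln = align_read(seq, config)
        events.append(call_indels(aln, config, read_id=rec.id))
    if short:
        logger.info("%s: excluded %d reads shorter than %d bp",
                    config.amplicon_id, short, config.min_read_length)
    return summarize(events, total, amplicon_id=config.amplicon_id)


def _as_config_map(configs) -> dict[str, AmpliconConfig]:
    if isinstance(configs, Mapping):
        return dict(configs)
    out: dict[str, AmpliconConfig] = {}
    for c in configs:
        if c.amplicon_id in out:
            raise ValueError(f"duplicate amplicon ID {c.amplicon_id!r}")
        out[c.amplicon_id] = c
    return out


def batch_quantify(fastqs: Mapping[str, object], configs, out_tsv=None) -> pd.DataFrame:
    """One summary row per amplicon.

    ``fastqs`` maps amplicon ID to FASTQ path; ``configs`` is a mapping or
    sequence of :class:`AmpliconConfig`.  A FASTQ without a config is an
    error naming the amplicon.
    """
    cmap = _as_config_map(configs)
    rows = []
    pattern_rows = []
    for amp_id in fastqs:
        if amp_id not in cmap:
            raise KeyError(f"no AmpliconConfig for amplicon {amp_id!r}")
        s = quantify_fastq(fastqs[amp_id], cmap[amp_id])
        logger.info("%s: %d reads, %d analyzed, %d indel",
                    amp_id, s.total_reads, s.analyzed_reads, s.indel_reads)
        rows.append(
            dict(
                amplicon_id=amp_id,
                total_reads=s.total_reads,
                analyzed_reads=s.analyzed_reads,
                indel_reads=s.indel_reads,
                indel_frequency=s.indel_frequency,
                out_of_frame_fraction=s.out_of_frame_fraction,
            )
        )
        for sig, count, frame in s.patterns:
            pattern_rows.append(dict(amplicon_id=amp_id, pattern=sig, count=count, frame=frame))
    df = pd.DataFrame(
        rows,
        columns=[
            "amplicon_id", "total_reads", "analyzed_reads", "indel_reads",
            "indel_frequency", "out_of_frame_fraction",
        ],
    )
    if out_tsv is not None:
        df.to_csv(out_tsv, sep="\t", index=False, na_rep="NA")
        pat_path = Path(str(out_tsv)).with_suffix(".patterns.tsv")
        pd.DataFrame(
            pattern_rows, columns=["amplicon_id", "pattern", "count", "frame"]
        ).to_csv(pat_path, sep="\t", index=False)
    return df
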