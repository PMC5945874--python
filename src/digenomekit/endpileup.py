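"""Strand-specific read 5'-end pileups from aligned digestion reads.

In digested-genome sequencing, in-vitro cleavage creates fragments whose
ends coincide at the cut, so read 5' termini pile up "vertically" at the two
strand-specific break coordinates.  This module reduces a SAM/BAM to, per
reference position: F (forward reads whose leftmost aligned base is there),
R (reverse reads whose rightmost aligned base — their 5' terminus — is
there), and the strand depths Df/Dr.  These four tracks are the entire
substrate of cleavage scoring.

Filtering follows common aligner conventions: a Phred base-quality cutoff
(default 15) applied to the terminal base for end counting and per base for
depth, duplicates kept by default, secondary/supplementary/unmapped records
skipped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "AlignmentFilter",
    "EndPileup",
    "build_end_pileup",
    "stream_pileups",
    "write_pileup_tsv",
]

logger = logging.getLogger(__name__)

_REF_CONSUMING_MATCH = (0, 7, 8)  # M, =, X
_DELETION = 2
_REF_SKIP = 3
_INSERTION = 1
_SOFT_CLIP = 4


@dataclass
class AlignmentFilter:
    min_base_quality: int = 15
    keep_duplicates: bool = True
    min_mapping_quality: int = 0
    primary_only: bool = True

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be non-negative")


@dataclass
class EndPileup:
    """Per-position 5'-end counts and strand depths over [start, end)."""

    contig: str
    start: int
    end: int
    F: np.ndarray
    R: np.ndarray
    Df: np.ndarray
    Dr: np.ndarray

    def __post_init__(self) -> None:
        n = self.end - self.start
        for name in ("F", "R", "Df", "Dr"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, span is {n}")

    def __len__(self) -> int:
        return self.end - self.start

    def slice(self, start: int, end: int) -> "EndPileup":
        """View of a sub-span (shares the underlying arrays)."""
        if start < self.start or end > self.end or start > end:
            raise ValueError("slice outside pileup span")
        a, b = start - self.start, end - self.start
        return EndPileup(
            self.contig, start, end,
            self.F[a:b], self.R[a:b], self.Df[a:b], self.Dr[a:b],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contig,
                "pos": np.arange(self.start, self.end),
                "F": self.F,
                "R": self.R,
                "Df": self.Df,
                "Dr": self.Dr,
            }
        )


def _resolve_region(af: pysam.AlignmentFile, region) -> tuple[str, int, int]:
    if isinstance(region, str):
        contig, start, end = region, 0, None
    else:
        contig, start, end = region
    if contig not in af.references:
        raise ValueError(f"unknown contig {contig!r}")
    clen = af.get_reference_length(contig)
    if end is None:
        end = clen
    if not 0 <= start <= end <= clen:
        raise ValueError(f"region [{start},{end}) outside contig {contig} of length {clen}")
    return contig, start, end


def _accumulate(
    reads: Iterable[pysam.AlignedSegment],
    contig: str,
    start: int,
    end: int,
    filt: AlignmentFilter,
) -> EndPileup:
    n = end - start
    F = np.zeros(n, dtype=np.int64)
    R = np.zeros(n, dtype=np.int64)
    df_diff = np.zeros(n + 1, dtype=np.int64)
    dr_diff = np.zeros(n + 1, dtype=np.int64)
    low_f: list[int] = []  # per-position low-quality depth corrections
    low_r: list[int] = []
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0, "filtered": 0}

    minbq = filt.min_base_quality
    for read in reads:
        if read.is_unmapped:
            skipped["unmapped"] += 1
            continue
        if read.is_secondary:
            if filt.primary_only:
                skipped["secondary"] += 1
                continue
        if read.is_supplementary:
            if filt.primary_only:
                skipped["supplementary"] += 1
                continue
        if read.reference_name != contig:
            continue
        if read.mapping_quality < filt.min_mapping_quality:
            skipped["filtered"] += 1
            continue
        if read.is_duplicate and not filt.keep_duplicates:
            skipped["filtered"] += 1
            continue
        cig = read.cigartuples
        if cig is None:
            continue
        quals = read.query_qualities
        reverse = read.is_reverse
        diff = dr_diff if reverse else df_diff
        low = low_r if reverse else low_f

        rpos = read.reference_start
        qpos = 0
        for op, ln in cig:
            if op in _REF_CONSUMING_MATCH:
                a = max(rpos, start)
                b = min(rpos + ln, end)
                if a < b:
                    diff[a - start] += 1
                    diff[b - start] -= 1
                    if quals is not None and minbq > 0:
                        q = np.frombuffer(bytes(quals[qpos : qpos + ln]), dtype=np.uint8)
                        for off in np.nonzero(q < minbq)[0].tolist():
                            p = rpos + off
                            if a <= p < b:
                                low.append(p - start)
                rpos += ln
                qpos += ln
            elif op == _DELETION:
                # deletions consume reference and count toward depth
                a = max(rpos, start)
                b = min(rpos + ln, end)
                if a < b:
                    diff[a - start] += 1
                    diff[b - start] -= 1
                rpos += ln
            elif op == _REF_SKIP:
                rpos += ln
            elif op in (_INSERTION, _SOFT_CLIP):
                qpos += ln
            # hard clips / pads consume neither

        # 5'-end counting: terminal aligned base must pass the quality cutoff
        if not reverse:
            p = read.reference_start
            if start <= p < end:
                lead_clip = cig[0][1] if cig[0][0] == _SOFT_CLIP else 0
                tq = quals[lead_clip] if quals is not None else 255
                if tq >= minbq:
                    F[p - start] += 1
        else:
            p = read.reference_end - 1
            if start <= p < end:
                tail_clip = cig[-1][1] if cig[-1][0] == _SOFT_CLIP else 0
                tq = quals[len(quals) - 1 - tail_clip] if quals is not None else 255
                if tq >= minbq:
                    R[p - start] += 1

    Df = np.cumsum(df_diff[:-1])
    Dr = np.cumsum(dr_diff[:-1])
    # low-quality bases are removed from depth (they were added via the
    # interval diff above); apply point corrections after the cumsum
    if low_f:
        corr = np.zeros(n, dtype=np.int64)
        np.add.at(corr, np.array(low_f, dtype=np.int64), 1)
        Df = Df - corr
    if low_r:
        corr = np.zeros(n, dtype=np.int64)
        np.add.at(corr, np.array(low_r, dtype=np.int64), 1)
        Dr = Dr - corr
    if any(skipped.values()):
        logger.info("build_end_pileup skipped records: %s", skipped)
    return EndPileup(contig, start, end, F, R, Df, Dr)


def build_end_pileup(alignments, region, filt: AlignmentFilter | None = None) -> EndPileup:
    """Reduce alignments over ``region`` to an :class:`EndPileup`.

    ``alignments`` may be a SAM/BAM path or an open ``pysam.AlignmentFile``.
    ``region`` is a contig name (whole contig) or ``(contig, start, end)``
    in 0-based half-open coordinates.
    """
    filt = filt or AlignmentFilter()
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=True) as af:
            contig, start, end = _resolve_region(af, region)
            reads = _fetch_or_scan(af, contig, start, end)
            return _accumulate(reads, contig, start, end, filt)
    af = alignments
    contig, start, end = _resolve_region(af, region)
    return _accumulate(_fetch_or_scan(af, contig, start, end), contig, start, end, filt)


def _fetch_or_scan(af: pysam.AlignmentFile, contig: str, start: int, end: int):
    if af.has_index():
        yield from af.fetch(contig, start, end)
        return
    # no index (plain SAM): stream everything and keep overlapping reads;
    # note this consumes the handle, so non-indexed inputs support only one
    # pass per open file (path-based callers reopen per call)
    for read in af:
        if read.is_unmapped or read.reference_name != contig:
            continue
        if read.reference_start < end and (read.reference_end or 0) > start:
            yield read


def stream_pileups(
    alignments,
    window_size: int,
    *,
    contig: str | None = None,
    overlap: int = 5,
    filt: AlignmentFilter | None = None,
) -> Iterator[EndPileup]:
    """Tile a contig into overlapping :class:`EndPileup` windows.

    Tiles span ``[k*w, min(L, k*w + w + overlap))`` so that adjacent tiles
    share ``overlap`` positions; any cut geometry narrower than the overlap
    is fully contained in at least one tile.  Overlapping positions carry
    identical counts in both tiles.
    """
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    if window_size <= 2 * overlap:
        raise ValueError("window_size must exceed twice the overlap")
    filt = filt or AlignmentFilter()

    own = isinstance(alignments, (str, Path))
    af = pysam.AlignmentFile(str(alignments), check_sq=True) if own else alignments
    try:
        if contig is None:
            if len(af.references) != 1:
                raise ValueError("contig must be given for multi-contig inputs")
            contig = af.references[0]
        length = af.get_reference_length(contig)
        if af.has_index():
            for tstart in range(0, length, window_size):
                tend = min(length, tstart + window_size + overlap)
                yield build_end_pileup(af, (contig, tstart, tend), filt)
        else:
            # plain SAM cannot fetch by region: one pass, slice views
            whole = build_end_pileup(af, (contig, 0, length), filt)
            for tstart in range(0, length, window_size):
                tend = min(length, tstart + window_size + overlap)
                yield whole.slice(tstart, tend)
    finally:
        if own:
            af.close()


def write_pileup_tsv(pileup: EndPileup, path) -> None:
    """Six-column debug export: contig, pos, F, R, Df, Dr."""
    pileup.to_frame().to_csv(path, sep="\t", index=False)
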