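"""PAM-anchored, mismatch-tolerant candidate target-site enumeration.

Cpf1 (Cas12a) binds a T-rich PAM (5'-TTTV-3') immediately 5' of the
protospacer.  Candidate off-target sites are genomic loci whose PAM matches
the IUPAC pattern exactly and whose protospacer differs from the guide by at
most ``max_mismatches`` substitutions (Hamming distance; no bulges).  Both
strands are scanned exhaustively, which is entirely adequate at the genome
sizes this package targets.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GuideTarget",
    "OffTargetHit",
    "find_candidate_sites",
    "annotate_calls",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtnRYSWKMBDHV", "TGCANtgcanYRSWMKVHDB")

# IUPAC nucleotide codes as 4-bit masks (A=1, C=2, G=4, T=8).
IUPAC_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

_BASE_LUT = np.zeros(256, dtype=np.uint8)
for _b, _m in (("A", 1), ("C", 2), ("G", 4), ("T", 8)):
    _BASE_LUT[ord(_b)] = _m
    _BASE_LUT[ord(_b.lower())] = _m
# every other character (including N) encodes to 0 and can never satisfy a
# pattern mask, so ambiguous genome bases never match


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GuideTarget:
    """A crRNA guide with its intended genomic target.

    ``protospacer`` is written PAM-proximal-first on the strand carrying the
    PAM.  ``expected_cut`` is the top-strand cut coordinate c_top expressed as
    an offset from ``start`` (the first PAM base); Cpf1 cleaves distal to the
    PAM, by default after the 18th protospacer base.
    """

    guide_id: str
    protospacer: str
    pam_pattern: str = "TTTV"
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "+"
    expected_cut: int | None = None

    def __post_init__(self) -> None:
        self.protospacer = self.protospacer.upper()
        self.pam_pattern = self.pam_pattern.upper()
        if not set(self.protospacer) <= set("ACGT"):
            raise ValueError(
                f"protospacer must be over ACGT, got {self.protospacer!r}"
            )
        if not set(self.pam_pattern) <= set(IUPAC_MASKS):
            raise ValueError(f"pam_pattern has non-IUPAC codes: {self.pam_pattern!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def expected_cut_position(self) -> int | None:
        """Absolute c_top of the intended cut, if the locus is placed."""
        if self.start is None or self.expected_cut is None:
            return None
        return self.start + self.expected_cut


@dataclass(frozen=True)
class OffTargetHit:
    """One candidate site: protospacer span (0-based half-open) + PAM."""

    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    pam_observed: str
    site_sequence: str


def _load_contigs(genome) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return {str(k): str(v).upper() for k, v in genome.items()}
    if isinstance(genome, (str, Path)) and os.path.exists(str(genome)):
        from Bio import SeqIO

        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}
    if isinstance(genome, str):
        return {"seq": genome.upper()}
    raise TypeError("genome must be a FASTA path, a mapping name->sequence, or a sequence string")


def _scan_strand(bits: np.ndarray, pam_mask: np.ndarray, proto_mask: np.ndarray, k: int):
    """Window positions and mismatch counts on one encoded strand."""
    width = len(pam_mask) + len(proto_mask)
    if len(bits) < width:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    win = sliding_window_view(bits, width)
    pam_ok = ((win[:, : len(pam_mask)] & pam_mask) != 0).all(axis=1)
    mm = ((win[:, len(pam_mask):] & proto_mask) == 0).sum(axis=1)
    keep = np.nonzero(pam_ok & (mm <= k))[0]
    return keep, mm[keep]


def find_candidate_sites(genome, guide: GuideTarget, max_mismatches: int) -> list[OffTargetHit]:
    """Enumerate every PAM-anchored site within ``max_mismatches`` of the guide.

    Returns hits sorted by (contig, start, strand).  The on-target locus, if
    present in the genome, appears with ``mismatches == 0``.
    """
    if not 0 <= max_mismatches <= len(guide.protospacer):
        raise ValueError("max_mismatches must be in [0, protospacer length]")
    contigs = _load_contigs(genome)
    pam_mask = np.array([IUPAC_MASKS[c] for c in guide.pam_pattern], dtype=np.uint8)
    proto_mask = np.array([IUPAC_MASKS[c] for c in guide.protospacer], dtype=np.uint8)
    npam, nproto = len(pam_mask), len(proto_mask)
    width = npam + nproto

    hits: list[OffTargetHit] = []
    for name, seq in contigs.items():
        fwd_bits = _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
        length = len(seq)

        idx, mm = _scan_strand(fwd_bits, pam_mask, proto_mask, max_mismatches)
        for p, m in zip(idx.tolist(), mm.tolist()):
            hits.append(
                OffTargetHit(
                    contig=name,
                    start=p + npam,
                    end=p + width,
                    strand="+",
                    mismatches=m,
                    pam_observed=seq[p : p + npam],
                    site_sequence=seq[p + npam : p + width],
                )
            )

        rc = reverse_complement(seq)
        rc_bits = _BASE_LUT[np.frombuffer(rc.encode(), dtype=np.uint8)]
        idx, mm = _scan_strand(rc_bits, pam_mask, proto_mask, max_mismatches)
        for j, m in zip(idx.tolist(), mm.tolist()):
            # window [j, j+width) on the reverse strand maps to
            # [length-j-width, length-j) on the forward strand
            hits.append(
                OffTargetHit(
                    contig=name,
                    start=length - j - width,
                    end=length - j - npam,
                    strand="-",
                    mismatches=m,
                    pam_observed=rc[j : j + npam],
                    site_sequence=rc[j + npam : j + width],
                )
            )

    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def hits_to_frame(hits: Sequence[OffTargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                contig=h.contig, start=h.start, end=h.end, strand=h.strand,
                mismatches=h.mismatches, pam_observed=h.pam_observed,
                site_sequence=h.site_sequence,
            )
            for h in hits
        ],
        columns=["contig", "start", "end", "strand", "mismatches", "pam_observed", "site_sequence"],
    )


def write_hits(hits: Sequence[OffTargetHit], path) -> None:
    """BED6-style TSV with a mismatch column, header line included."""
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def _distance_to_span(pos: int, start: int, end: int) -> int:
    if start <= pos < end:
        return 0
    return min(abs(pos - start), abs(pos - (end - 1)))


def annotate_calls(calls, hits: Sequence[OffTargetHit], guide: GuideTarget | None = None,
                   window: int = 25) -> pd.DataFrame:
    """Label cleavage calls as ON, OT-n, or UNEXPLAINED.

    A call within ``window`` bp of the guide's intended locus is ON; otherwise
    a call within ``window`` of a candidate hit is OT-n where n is the
    smallest mismatch count among neighbouring hits; anything else is
    UNEXPLAINED.  With no guide locus, a 0-mismatch neighbouring hit counts
    as ON.
    """
    rows = []
    for call in calls:
        label = "UNEXPLAINED"
        near = [
            h for h in hits
            if h.contig == call.contig
            and _distance_to_span(call.cut_position, h.start, h.end) <= window
        ]
        if (
            guide is not None
            and guide.contig == call.contig
            and guide.start is not None
            and _distance_to_span(call.cut_position, guide.start, guide.end) <= window
        ):
            label = "ON"
        elif near:
            n = min(h.mismatches for h in near)
            if n == 0 and guide is None:
                label = "ON"
            else:
                label = f"OT-{n}" if n > 0 or guide is not None else "ON"
        rows.append(
            dict(
                contig=call.contig,
                cut_position=call.cut_position,
                score=call.score,
                best_overhang=call.best_overhang,
                label=label,
            )
        )
    return pd.DataFrame(
        rows, columns=["contig", "cut_position", "score", "best_overhang", "label"]
    )
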