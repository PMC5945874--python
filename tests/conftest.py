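"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities from first principles
(text-level SAM parsing, per-position brute force, plain-Python dynamic
programming) so they share no code path with the package.
"""
from __future__ import annotations

import re
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def write_sam(path, contig, length, reads):
    """Minimal SAM writer for hand-built fixtures.

    ``reads``: dicts with name, flag, pos (0-based), cigar, seq; optional
    qual (string) and mapq (default 60).
    """
    lines = [f"@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{contig}\tLN:{length}"]
    for r in sorted(reads, key=lambda r: r["pos"]):
        qual = r.get("qual", "I" * len(r["seq"]))
        lines.append(
            f"{r['name']}\t{r['flag']}\t{contig}\t{r['pos'] + 1}\t{r.get('mapq', 60)}\t"
            f"{r['cigar']}\t*\t0\t0\t{r['seq']}\t{qual}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def naive_end_pileup(sam_path, contig, start, end, *, min_base_quality=15,
                     keep_duplicates=True, min_mapping_quality=0):
    """Per-read recount of F/R/Df/Dr from the SAM text itself."""
    n = end - start
    F = [0] * n
    R = [0] * n
    Df = [0] * n
    Dr = [0] * n
    for line in open(sam_path):
        if line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        flag = int(f[1])
        if flag & 4 or flag & 256 or flag & 2048:
            continue
        if f[2] != contig:
            continue
        if int(f[4]) < min_mapping_quality:
            continue
        if (flag & 1024) and not keep_duplicates:
            continue
        pos = int(f[3]) - 1
        qual = f[10]
        reverse = bool(flag & 16)
        depth = Dr if reverse else Df
        rpos, qpos = pos, 0
        aligned = []  # (ref position, phred or None-for-deletion)
        for num, op in _CIGAR_RE.findall(f[5]):
            num = int(num)
            if op in "M=X":
                for i in range(num):
                    aligned.append((rpos + i, ord(qual[qpos + i]) - 33 if qual != "*" else 255))
                rpos += num
                qpos += num
            elif op == "D":
                for i in range(num):
                    aligned.append((rpos + i, None))
                rpos += num
            elif op == "N":
                rpos += num
            elif op in "IS":
                qpos += num
        for p, q in aligned:
            if start <= p < end and (q is None or q >= min_base_quality):
                depth[p - start] += 1
        bases = [(p, q) for p, q in aligned if q is not None]
        if not bases:
            continue
        if reverse:
            p, q = bases[-1]
            if start <= p < end and q >= min_base_quality:
                R[p - start] += 1
        else:
            p, q = bases[0]
            if start <= p < end and q >= min_base_quality:
                F[p - start] += 1
    return F, R, Df, Dr


def naive_cleavage_score(F, R, Df, Dr, i, *, overhang_min=1, overhang_max=5, min_support=3):
    """Direct evaluation of the overhang-sweep score at index i."""
    best, best_o = 0.0, overhang_min
    for o in range(overhang_min, overhang_max + 1):
        j = i + o - 1
        if j >= len(R) or Df[i] == 0 or Dr[j] == 0 or F[i] < min_support or R[j] < min_support:
            s = 0.0
        else:
            s = (F[i] / Df[i]) * (R[j] / Dr[j]) * (F[i] + R[j]) / 2.0
        if s > best:
            best, best_o = s, o
    return best, best_o


def brute_force_sites(seq, pam_pattern, protospacer, max_mismatches, contig="seq"):
    """Position-by-position candidate-site recount on both strands.

    Returns a set of (contig, start, end, strand, mismatches) tuples with
    protospacer spans in forward-genome coordinates.
    """
    out = set()
    width = len(pam_pattern) + len(protospacer)
    length = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        for p in range(length - width + 1):
            window = s[p : p + width]
            if any(window[i] not in _IUPAC_SETS[pam_pattern[i]] for i in range(len(pam_pattern))):
                continue
            mm = sum(
                1
                for a, b in zip(window[len(pam_pattern):], protospacer)
                if a != b or a not in "ACGT"
            )
            if mm > max_mismatches:
                continue
            if strand == "+":
                start, end = p + len(pam_pattern), p + width
            else:
                start, end = length - p - width, length - p - len(pam_pattern)
            out.add((contig, start, end, strand, mm))
    return out


def affine_dp_score(ref, read, *, match=2.0, mismatch=-4.0, gap_open=-10.0, gap_extend=-1.0):
    """Plain-Python Gotoh score: global over the read, free reference
    overhang at both read ends, gap of length L costing open + L*extend."""
    NEG = float("-inf")
    m, n = len(ref), len(read)
    go = gap_open + gap_extend
    ge = gap_extend
    M = [NEG] * (m + 1)
    D = [0.0] * (m + 1)  # free leading reference skip
    I = [NEG] * (m + 1)
    M[0] = 0.0
    for i in range(1, n + 1):
        newM = [NEG] * (m + 1)
        newD = [NEG] * (m + 1)
        newI = [NEG] * (m + 1)
        newI[0] = max(M[0] + go, I[0] + ge if I[0] > NEG else NEG)
        for j in range(1, m + 1):
            s = match if ref[j - 1] == read[i - 1] else mismatch
            newM[j] = s + max(M[j - 1], D[j - 1], I[j - 1])
            newD[j] = max(newM[j - 1] + go, newD[j - 1] + ge, newI[j - 1] + go)
            newI[j] = max(M[j] + go, I[j] + ge, D[j] + go)
        M, D, I = newM, newD, newI
    # free trailing reference skip: best over all reference end points
    return max(max(M), max(I))


@pytest.fixture
def toy_genome():
    """Deterministic 2 kb sequence with mixed composition."""
    import numpy as np

    rng = np.random.default_rng(123)
    return "".join("ACGT"[i] for i in rng.integers(4, size=2000).tolist())
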