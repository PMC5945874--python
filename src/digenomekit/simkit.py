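"""Seeded simulators: synthetic genomes, in-vitro digestion reads, amplicons.

The digestion simulator emulates the library that nuclease-digested
whole-genome sequencing produces: many genome copies ("molecules") are
sheared at Poisson-distributed background breakpoints (Covaris-style, blunt)
and, with per-site probability ``efficiency``, additionally cleaved at each
planted site with the staggered geometry of a 5'-overhang-producing
nuclease.  A cut at top-strand coordinate ``c_top`` with overhang ``o``
breaks the top strand between ``c_top - 1`` and ``c_top`` and the bottom
strand between ``c_top + o - 1`` and ``c_top + o``; consequently forward
reads from the downstream fragment start exactly at ``c_top`` and reverse
reads from the upstream fragment have their 5' terminus at ``c_top + o - 1``.
Both ends of every fragment are sequenced (paired ends) and emitted as
Phred+33 FASTQ plus an already-coordinate-sorted SAM with correct
POS/CIGAR/FLAG, so downstream stages run without an external aligner.

Every generator draws from a stream derived from one root seed by a fixed
per-stage label, making all outputs byte-reproducible.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .sitescan import GuideTarget, reverse_complement

__all__ = [
    "SimConfigError",
    "PlantedSite",
    "SimSpec",
    "IndelSpectrum",
    "IndelSpectrumEntry",
    "make_genome",
    "write_fasta",
    "plant_guide_site",
    "simulate_digest",
    "simulate_amplicon",
    "DigestResult",
    "AmpliconSimResult",
]


class SimConfigError(ValueError):
    """Invalid simulation parameterization."""


# fixed labels deriving independent RNG streams from the root seed
_STREAMS = {
    "genome": 101,
    "plant": 102,
    "background": 103,
    "site": 104,
    "readerr": 105,
    "amplicon_class": 106,
    "amplicon_ins": 107,
    "amplicon_err": 108,
}


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[label], int(seed)])


@dataclass
class PlantedSite:
    """A cleavage site planted into the simulated digest.

    ``position`` is the 0-based top-strand cut coordinate c_top.
    """

    position: int
    overhang: int = 4
    efficiency: float = 1.0
    guide_id: str | None = None

    def validate(self) -> None:
        if self.overhang not in (1, 2, 3, 4, 5):
            raise SimConfigError(f"overhang must be in 1..5, got {self.overhang}")
        if not 0.0 <= self.efficiency <= 1.0:
            raise SimConfigError(f"efficiency must be in [0,1], got {self.efficiency}")


@dataclass
class SimSpec:
    """Full parameterization of a synthetic digestion experiment."""

    seed: int
    genome_length: int
    gc_content: float = 0.42
    planted_sites: list[PlantedSite] = field(default_factory=list)
    fragment_mean: int = 400
    read_length: int = 150
    coverage: float = 30.0
    sequencing_error_rate: float = 0.001
    contig: str = "sim1"

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise SimConfigError("genome_length must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise SimConfigError("gc_content must be in [0,1]")
        if self.coverage <= 0:
            raise SimConfigError("coverage must be > 0")
        if self.genome_length < 10 * self.fragment_mean:
            raise SimConfigError("genome_length must be >= 10 x fragment_mean")
        if not 0.0 <= self.sequencing_error_rate <= 1.0:
            raise SimConfigError("sequencing_error_rate must be in [0,1]")
        for s in self.planted_sites:
            s.validate()
            if not 0 <= s.position < self.genome_length:
                raise SimConfigError(f"planted site {s.position} outside genome")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["planted_sites"] = [PlantedSite(**s) for s in data.get("planted_sites", [])]
        return cls(**data)


def write_fasta(path, contigs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_genome(spec: SimSpec, fasta_path=None) -> str:
    """Draw a random genome with the requested length and GC content."""
    if spec.genome_length <= 0:
        raise SimConfigError("genome_length must be positive")
    if not 0.0 <= spec.gc_content <= 1.0:
        raise SimConfigError("gc_content must be in [0,1]")
    rng = _rng(spec.seed, "genome")
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=spec.genome_length, p=probs)
    seq = codes.tobytes().decode()
    if fasta_path is not None:
        write_fasta(fasta_path, {spec.contig: seq})
    return seq


def plant_guide_site(
    genome: str,
    guide_id: str,
    protospacer: str,
    pam_position: int,
    mismatches: int = 0,
    *,
    seed: int = 0,
    contig: str = "sim1",
    cut_offset: int = 18,
) -> tuple[str, GuideTarget]:
    """Write a TTTV-PAM locus carrying ``protospacer`` into the genome.

    The written locus is PAM (TTT + one of A/C/G) followed by the
    protospacer with exactly ``mismatches`` seeded substitutions.  Returns
    the modified genome and the guide with its placement; ``expected_cut``
    is PAM length + ``cut_offset`` (the nuclease cuts distal to the PAM).
    """
    protospacer = protospacer.upper()
    span = 4 + len(protospacer)
    if pam_position < 0 or pam_position + span > len(genome):
        raise ValueError("locus does not fit in the genome at pam_position")
    if not 0 <= mismatches <= len(protospacer):
        raise ValueError("mismatches must be in [0, protospacer length]")
    rng = _rng(seed, "plant")
    pam_seq = "TTT" + "ACG"[rng.integers(3)]
    written = list(protospacer)
    if mismatches:
        pos = rng.choice(len(protospacer), size=mismatches, replace=False)
        for p in sorted(pos.tolist()):
            alt = [b for b in "ACGT" if b != written[p]]
            written[p] = alt[rng.integers(3)]
    locus = pam_seq + "".join(written)
    new_genome = genome[:pam_position] + locus + genome[pam_position + span :]
    guide = GuideTarget(
        guide_id=guide_id,
        protospacer=protospacer,
        pam_pattern="TTTV",
        contig=contig,
        start=pam_position,
        end=pam_position + span,
        strand="+",
        expected_cut=4 + cut_offset,
    )
    return new_genome, guide


@dataclass
class DigestResult:
    sam: Path
    fastq1: Path | None
    fastq2: Path | None
    truth: Path
    n_molecules: int
    n_fragments: int
    ledger: pd.DataFrame  # one row per molecule x planted site: cut or not


def _background_breaks(rng: np.random.Generator, length: int, mean: float) -> np.ndarray:
    """Poisson-process breakpoints: exponential spacings, mean ``mean``."""
    draws = max(8, int(length / mean * 1.5) + 8)
    pos = np.array([], dtype=float)
    total = 0.0
    while total < length:
        inc = rng.exponential(mean, size=draws)
        pos = np.concatenate([pos, (total + np.cumsum(inc))])
        total = pos[-1]
    pts = pos[pos < length].astype(np.int64)
    return pts[(pts > 0)]


def simulate_digest(
    genome: str,
    spec: SimSpec,
    outdir,
    prefix: str = "digest",
    write_fastq: bool = True,
) -> DigestResult:
    """Simulate the sequencing library of an in-vitro digested genome.

    Emits coordinate-sorted SAM (and optionally paired FASTQ), a truth TSV
    ledger with the cut/uncut status of every molecule at every planted
    site, and the SimSpec as YAML.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    length = len(genome)
    if length != spec.genome_length:
        raise SimConfigError("genome length does not match spec.genome_length")
    read_len = spec.read_length

    sites = []
    for s in spec.planted_sites:
        if s.position < read_len or s.position > length - read_len:
            warnings.warn(
                f"planted site at {s.position} is within read_length of the contig edge; skipped",
                stacklevel=2,
            )
            continue
        sites.append(s)

    # one molecule contributes ~2*read_len/fragment_mean fold coverage
    n_mol = max(1, int(round(spec.coverage * spec.fragment_mean / (2.0 * read_len))))
    rng_bg = _rng(spec.seed, "background")
    rng_site = _rng(spec.seed, "site")
    rng_err = _rng(spec.seed, "readerr")

    ledger_rows = []
    frags: list[tuple[int, int, int, int]] = []  # top_start, top_end, bot_start, bot_end
    for mol in range(n_mol):
        cuts: dict[int, int] = {0: 0, length: length}  # top pos -> bottom pos
        for b in _background_breaks(rng_bg, length, spec.fragment_mean).tolist():
            cuts[b] = max(cuts.get(b, -1), b)
        for s in sites:
            cut = bool(rng_site.random() < s.efficiency)
            ledger_rows.append(
                (mol, s.guide_id or "", s.position, s.overhang, s.efficiency, int(cut))
            )
            if cut:
                bot = min(s.position + s.overhang, length)
                cuts[s.position] = max(cuts.get(s.position, -1), bot)
        tops = sorted(cuts)
        for t1, t2 in zip(tops, tops[1:]):
            b1, b2 = cuts[t1], min(cuts[t2], length)
            if t2 - t1 >= 1 and b2 - b1 >= 1:
                frags.append((t1, t2, b1, b2))

    # build reads: forward from the top-strand 5' end, reverse from the
    # bottom-strand 5' end; reads never extend past their fragment
    n_frag = len(frags)
    records = []  # (pos, name, flag, cigar_len, seq, qual, pnext, tlen)
    lengths = np.empty(2 * n_frag, dtype=np.int64)
    for i, (t1, t2, b1, b2) in enumerate(frags):
        lengths[2 * i] = min(read_len, t2 - t1)
        lengths[2 * i + 1] = min(read_len, b2 - b1)
    n_err = (
        rng_err.binomial(lengths, spec.sequencing_error_rate)
        if spec.sequencing_error_rate > 0
        else np.zeros(2 * n_frag, dtype=np.int64)
    )

    def _mutate(seq: str, k: int) -> tuple[str, str]:
        if k == 0:
            return seq, "I" * len(seq)
        qual = ["I"] * len(seq)
        out = list(seq)
        pos = rng_err.choice(len(seq), size=min(k, len(seq)), replace=False)
        for p in pos.tolist():
            alt = [b for b in "ACGT" if b != out[p]]
            out[p] = alt[rng_err.integers(3)]
            qual[p] = "#"
        return "".join(out), "".join(qual)

    for i, (t1, t2, b1, b2) in enumerate(frags):
        name = f"frag{i:07d}"
        lf = int(lengths[2 * i])
        lr = int(lengths[2 * i + 1])
        fseq, fqual = _mutate(genome[t1 : t1 + lf], int(n_err[2 * i]))
        rstart = b2 - lr
        rseq, rqual = _mutate(genome[rstart:b2], int(n_err[2 * i + 1]))
        tlen = b2 - t1
        records.append((t1, name, 99, lf, fseq, fqual, rstart, tlen))
        records.append((rstart, name, 147, lr, rseq, rqual, t1, -tlen))

    records.sort(key=lambda r: (r[0], r[1], r[2]))

    sam_path = outdir / f"{prefix}.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{spec.contig}\tLN:{length}\n")
        fh.write("@PG\tID:digenomekit.simkit\tPN:digenomekit.simkit\n")
        for pos, name, flag, clen, seq, qual, pnext, tlen in records:
            fh.write(
                f"{name}\t{flag}\t{spec.contig}\t{pos + 1}\t60\t{clen}M\t=\t{pnext + 1}\t{tlen}\t{seq}\t{qual}\n"
            )

    fq1 = fq2 = None
    if write_fastq:
        fq1 = outdir / f"{prefix}_R1.fastq"
        fq2 = outdir / f"{prefix}_R2.fastq"
        by_name: dict[str, dict[int, tuple[str, str]]] = {}
        for pos, name, flag, clen, seq, qual, pnext, tlen in records:
            by_name.setdefault(name, {})[flag] = (seq, qual)
        with open(fq1, "w") as f1, open(fq2, "w") as f2:
            for name in sorted(by_name):
                seq1, q1 = by_name[name][99]
                seq2, q2 = by_name[name][147]
                f1.write(f"@{name}/1\n{seq1}\n+\n{q1}\n")
                # reverse mate is stored reference-oriented in SAM; FASTQ
                # carries it as sequenced
                f2.write(f"@{name}/2\n{reverse_complement(seq2)}\n+\n{q2[::-1]}\n")

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["molecule", "guide_id", "position", "overhang", "efficiency", "cut"],
    )
    truth_path = outdir / f"{prefix}.truth.tsv"
    ledger.to_csv(truth_path, sep="\t", index=False)
    spec.to_yaml(outdir / f"{prefix}.spec.yaml")

    return DigestResult(
        sam=sam_path,
        fastq1=fq1,
        fastq2=fq2,
        truth=truth_path,
        n_molecules=n_mol,
        n_fragments=n_frag,
        ledger=ledger,
    )


@dataclass(frozen=True)
class IndelSpectrumEntry:
    net_length_change: int
    offset_from_cut: int
    fraction: float


@dataclass
class IndelSpectrum:
    """Mixture of mutant indel classes planted into amplicon reads."""

    entries: list[IndelSpectrumEntry]
    wild_type_fraction: float

    def validate(self) -> None:
        total = self.wild_type_fraction + sum(e.fraction for e in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"spectrum fractions sum to {total}, not 1")
        for e in self.entries:
            if e.net_length_change == 0:
                raise SimConfigError("net_length_change must be nonzero for mutant entries")
            if e.fraction < 0 or self.wild_type_fraction < 0:
                raise SimConfigError("fractions must be non-negative")

    @classmethod
    def from_dict(cls, entries: dict[tuple[int, int], float], wild_type: float) -> "IndelSpectrum":
        return cls(
            entries=[IndelSpectrumEntry(n, o, f) for (n, o), f in entries.items()],
            wild_type_fraction=wild_type,
        )


@dataclass
class AmpliconSimResult:
    fastq: Path
    truth: Path
    class_counts: dict[str, int]


def simulate_amplicon(
    amplicon_reference: str,
    spectrum: IndelSpectrum,
    n_reads: int,
    error_rate: float,
    cut_position: int,
    seed: int,
    outdir,
    prefix: str = "amplicon",
) -> AmpliconSimResult:
    """Simulate amplicon deep-seq reads carrying a planted indel spectrum.

    Each read is drawn from the spectrum; a deletion of k bases removes
    ``[cut+offset, cut+offset+k)``, an insertion adds seeded random bases at
    ``cut+offset``.  Substitution errors are sprinkled at ``error_rate``.
    The truth TSV records each read's class and net length change.
    """
    spectrum.validate()
    ref = amplicon_reference.upper()
    if not 0 <= cut_position < len(ref):
        raise SimConfigError("cut_position must lie inside the amplicon")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rng_class = _rng(seed, "amplicon_class")
    rng_ins = _rng(seed, "amplicon_ins")
    rng_err = _rng(seed, "amplicon_err")

    labels = ["WT"]
    fracs = [spectrum.wild_type_fraction]
    variants = {"WT": ref}
    for e in spectrum.entries:
        label = f"net{e.net_length_change:+d}@{e.offset_from_cut:+d}"
        p = cut_position + e.offset_from_cut
        if e.net_length_change < 0:
            k = -e.net_length_change
            if p < 0 or p + k > len(ref) or k >= len(ref):
                raise SimConfigError(f"deletion of {k} nt at {p} does not fit the amplicon")
            variants[label] = ref[:p] + ref[p + k :]
        else:
            if p < 0 or p > len(ref):
                raise SimConfigError(f"insertion position {p} outside the amplicon")
            ins = "".join(
                "ACGT"[j] for j in rng_ins.integers(4, size=e.net_length_change).tolist()
            )
            variants[label] = ref[:p] + ins + ref[p:]
        labels.append(label)
        fracs.append(e.fraction)

    draws = rng_class.choice(len(labels), size=n_reads, p=np.array(fracs) / sum(fracs))
    nets = {lab: (0 if lab == "WT" else int(lab.split("@")[0][3:])) for lab in labels}

    fq_path = outdir / f"{prefix}.fastq"
    truth_path = outdir / f"{prefix}.truth.tsv"
    counts = {lab: 0 for lab in labels}
    truth_rows = []
    with open(fq_path, "w") as fh:
        for i, d in enumerate(draws.tolist()):
            lab = labels[d]
            counts[lab] += 1
            seq = variants[lab]
            qual = ["I"] * len(seq)
            if error_rate > 0:
                k = rng_err.binomial(len(seq), error_rate)
                if k:
                    out = list(seq)
                    pos = rng_err.choice(len(seq), size=k, replace=False)
                    for p in pos.tolist():
                        alt = [b for b in "ACGT" if b != out[p]]
                        out[p] = alt[rng_err.integers(3)]
                        qual[p] = "#"
                    seq = "".join(out)
            rid = f"amp{i:06d}"
            fh.write(f"@{rid}\n{seq}\n+\n{''.join(qual)}\n")
            truth_rows.append((rid, lab, nets[lab]))

    pd.DataFrame(truth_rows, columns=["read_id", "class", "net_length_change"]).to_csv(
        truth_path, sep="\t", index=False
    )
    return AmpliconSimResult(fastq=fq_path, truth=truth_path, class_counts=counts)
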