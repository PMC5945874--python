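# Methods

## Coordinate and cut conventions

All coordinates are 0-based, half-open. A "cut at c_top" breaks the
top-strand phosphodiester bond between `c_top − 1` and `c_top`. A staggered
double-strand break with a 5′ overhang of `o` nt breaks the bottom strand
between `c_top + o − 1` and `c_top + o`. Both resulting fragments then carry
protruding 5′ ends of length `o`: the downstream fragment's top strand
starts at `c_top`, and the upstream fragment's bottom strand ends (5′
terminus) at `c_top + o − 1`. Sequencing reads start at fragment ends, so
forward-read 5′ ends accumulate at `c_top` and reverse-read 5′ ends at
`c_top + o − 1`. The simulator and the scorer share this single convention.

## Cleavage scoring

For each position `f` and overhang `o ∈ [overhang_min, overhang_max]`
(default 1–5, matching the overhang range of Cpf1-class nucleases), with
`r = f + o − 1`:

```
S_o(f) = (F(f) / Df(f)) · (R(r) / Dr(r)) · (F(f) + R(r)) / 2
```

`F`/`R` are counts of forward/reverse reads whose 5′ terminus falls exactly
at the position; `Df`/`Dr` are strand depths. `S_o` is defined as 0 when
either depth is 0 or either end count is below `min_support` (default 3
reads per strand; this floor suppresses division-noise calls at low depth).
The position's score is `max_o S_o`, with the smallest `o` winning ties for
determinism. The statistic is calibrated so that a fully cleaved site scores
approximately the local depth (both ratios → 1, mean end support → depth),
while random Covaris-style fragmentation scores far below 1; the default
calling cutoff is 2.5. Because variants of this per-position statistic
exist in the literature, the scoring callable is pluggable
(`digenome.ScoreFn`); the cutoff is a first-class parameter, not a
constant.

Positions scoring at or above the cutoff are emitted and then merged within
`merge_distance` (default 10 bp, comfortably above the 5 bp overhang
ambiguity), keeping the highest-scoring representative (smaller coordinate
on ties).

## End pileups and alignment filtering

`F`, `R`, `Df`, `Dr` are accumulated from SAM/BAM records. Unmapped,
secondary and supplementary records are skipped; duplicates are **kept** by
default (flag provided), and the Phred base-quality cutoff defaults to 15 —
both following common practice for digestion-sequencing alignment
pipelines. The quality cutoff is applied to the terminal (5′-end) base for
end counting — terminal miscalls are what corrupt end counts — and per base
for depth. CIGAR deletions consume reference and count toward depth;
insertions and soft clips never contribute to ends or depth (standard
pileup semantics). Whether duplicates should also be dropped from depth is
left to the same `keep_duplicates` flag; the default keeps them everywhere.

Genome-scale inputs are processed as overlapping tiles
(`stream_pileups`); tiles overlap by at least `overhang_max` so any cut
geometry is wholly contained in one tile, and overlapping positions carry
identical counts, which the tests assert position-for-position. Indexed
BAMs are fetched per tile; plain SAM falls back to one streaming pass.

## Candidate-site scanning

The scanner is an exhaustive both-strand sweep: a candidate requires an
exact IUPAC match of the PAM pattern (default TTTV) immediately 5′ of the
protospacer on the candidate's strand, and a protospacer Hamming distance
≤ k (default 4). No DNA/RNA bulges are modelled, and mismatch positions are
unweighted. Ambiguous genome bases (N) never match the PAM and always count
as protospacer mismatches. Sequences are bit-encoded (A/C/G/T → one-hot
4-bit masks) and scanned with a vectorised sliding window; at the genome
sizes this package targets, exhaustive scanning is faster to validate and
audit than an index. Calls are annotated ON when within `window` bp
(default 25) of the guide's intended locus, OT-n for the smallest mismatch
count among neighbouring candidates, otherwise UNEXPLAINED.

## Amplicon indel quantification

Reads are aligned to the amplicon reference with affine gap costs
(match +2, mismatch −4, gap of length L costing `gap_open + L·gap_extend`
= −10 − L by default) via Biopython's pairwise aligner, configured global
over the read with free reference overhang at the read's ends, so truncated
reads align without penalty. Gaps are left-normalised (VCF-style) before
any downstream use, which makes op lists deterministic and pattern tables
stable. An alignment-score oracle — an independently written quadratic
Gotoh DP — is part of the test suite.

A read is an indel read iff at least one insertion/deletion op overlaps the
guide window (protospacer + PAM span) padded by `window_pad` (default 5 bp).
A span rather than a point estimate is used because Cpf1 cuts distal to the
PAM and can re-cut after small indels, making the exact cut position
uncertain. Substitutions never count as indels, which is also what makes
the frequency estimate robust to substitution sequencing error. Frame
classification uses the read's net length change (Σ insertions − Σ
deletions) mod 3 — per read, not per op, since per-op classing is
ill-defined for multi-op reads. `indel_frequency` = 100 × indel reads /
analyzed reads; with zero analyzable reads it is reported as missing, not
0. The in-frame/out-of-frame split is over indel reads only and always
totals 100 by construction.

## Synthetic data generation

The digestion simulator emulates: (a) background fragmentation as a Poisson
process (exponential inter-break spacing, mean `fragment_mean`, default
400 bp) — a standard idealisation of acoustic shearing, as the true size
distribution of sheared libraries is instrument-dependent; (b) site
cleavage as an independent Bernoulli draw per genome copy at probability
`efficiency`, with the staggered geometry above; (c) paired 150 bp reads
from both ends of every fragment, truncated to the fragment when shorter;
(d) uniform substitution errors (default 0.1%) marked by a low quality
character. The number of genome copies is set so expected depth matches
`coverage` (one copy contributes ≈ 2·read_length/fragment_mean fold
coverage). Reads are emitted as Phred+33 FASTQ and as an
already-coordinate-sorted SAM with correct POS/CIGAR/FLAG, removing any
aligner dependence from unit tests while the FASTQ still supports
integration through a real aligner. A truth ledger (TSV) records the
cut/uncut status of every molecule at every planted site; every downstream
estimator can be scored against it without re-simulation.

One root seed drives everything; each generator stage derives an
independent stream via a fixed integer label, so identical parameterisation
reproduces byte-identical FASTA/FASTQ/SAM/TSV outputs.

**Ascertainment bias worth knowing about.** At a site of efficiency *e*,
the end-fraction `F(c_top)/Df(c_top)` does **not** estimate *e*: cut
molecules always place a read 5′ end at the cut, while uncut molecules
cover it on the forward strand only with probability ≈
read_length/fragment_mean. The ratio therefore concentrates around
`e / (e + (1−e)·read_length/fragment_mean)` — e.g. ≈ 0.8 at *e* = 0.6 with
the defaults. This inflation is a property of fragment-end sequencing
itself, helps detection (scores rise steeply with efficiency), and is why
tests validate efficiency against the molecule ledger rather than against
the raw end fraction.

What the simulator does **not** emulate: PCR amplification bias, duplicate
reads, realistic quality-score error profiles, indel sequencing errors,
adapter read-through, chromatin accessibility, or genome repeat structure
(backgrounds are i.i.d. base draws). Passing tests therefore demonstrate
the correctness of the computational pipeline under the stated model — not
calling performance on real genomes, where repeats and coverage
non-uniformity will matter.

For amplicons, each read is drawn from a planted spectrum of indel classes
(net length change, offset from the cut, fraction); deletions remove
reference bases at the planted position, insertions add seeded random
bases; substitution errors are sprinkled at the stated rate; a truth TSV
records each read's class.

## Problem sizes used by tests and the acceptance script

The test suite runs 20 planted plus 10 background digestion simulations at
1 Mb / 30× for recovery and specificity checks (the background arm totals
10 Mb, enough to resolve a 0.1 calls/Mb bound); scanner oracles use 20–100
kb genomes; amplicon checks use 1000 reads per condition. The acceptance
script uses 8 planted + 8 background 1 Mb runs and the same scanner and
amplicon settings. These sizes were chosen as the smallest at which the
binomial and rate bounds being asserted are informative.

## Numerical and degenerate-input choices

- Score ties across overhangs: smallest overhang wins; merge ties: smallest
  coordinate wins; pattern ties: lexicographic signature order.
- Division by zero cannot occur: zero-depth positions score 0 by
  definition.
- Planted sites within a read length of a contig edge are skipped with a
  warning (their fragments could not be sequenced realistically).
- Fragments shorter than the read length yield truncated reads; fragments
  shorter than the stagger on one strand are dropped entirely (both strand
  spans must be non-empty).
- Empty inputs produce empty-but-valid outputs: header-only BED/TSV,
  zero-count pileups, missing (NA) indel frequencies.
- Reads shorter than `min_read_length` are excluded and counted, never
  silently dropped.

## Known limitations

- The scoring statistic is one member of a family of published
  end-enrichment scores; absolute score values (and hence the 2.5 cutoff)
  are comparable only within a fixed statistic. The pluggable interface and
  parameterised cutoff exist for exactly this reason.
- Blunt cuts (overhang 0) are outside the default sweep; set
  `overhang_min` accordingly for blunt-cutting nucleases.
- The candidate scanner does not model bulges, alternative PAMs beyond the
  IUPAC pattern, or mismatch-position weighting.
- Amplicon quantification treats reads as single-ended and ignores
  substitution outcomes (base editing) by design.
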