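# digenomekit

Genome-wide specificity and editing-efficiency analysis for staggered-cutting
CRISPR nucleases (Cpf1/Cas12a family), built around three computations:

1. **In-vitro cleavage-site calling** from nuclease-digested whole-genome
   sequencing alignments. Cpf1 leaves 5′ 1–5 nt overhangs, so a genuine cut
   at top-strand coordinate *f* aligns forward-read 5′ ends at *f* and
   reverse-read 5′ ends at *r = f + o − 1* for overhang *o*. Each position
   is scored

   S<sub>o</sub>(f) = (F(f)/D<sub>f</sub>(f)) · (R(r)/D<sub>r</sub>(r)) · (F(f)+R(r))/2

   where F/R are strand-specific counts of read 5′ termini and
   D<sub>f</sub>/D<sub>r</sub> the strand depths. The per-position score is
   the maximum over the overhang sweep; positions scoring ≥ 2.5 (default
   cutoff) are called and merged. A fully cleaved site scores ≈ sequencing
   depth; random fragmentation scores ≪ 1.
2. **Candidate off-target enumeration**: exhaustive both-strand scanning for
   loci whose IUPAC PAM (default 5′-TTTV-3′) matches exactly and whose
   protospacer is within a Hamming distance *k* (default 4) of the guide;
   cleavage calls are then annotated ON / OT-*n* / UNEXPLAINED.
3. **Amplicon indel quantification**: per-read affine-gap alignment to the
   amplicon, windowed indel calling around the guide, indel frequency, and
   the in-frame vs out-of-frame split by the net-length-change mod-3 rule.

A seeded simulation module (`digenomekit.simkit`) generates synthetic
genomes, digestion libraries with planted staggered cuts of configurable
efficiency, and amplicon reads with planted indel spectra — with truth
ledgers — so the entire pipeline is testable end to end without any
external data.

## Worked example

Plant a TTTV-PAM protospacer in a 200 kb random genome, digest it in silico
at 30× with 80% cleavage efficiency and a 4-nt overhang, and run the
specificity workflow:

```python
from pathlib import Path
from digenomekit import *
from digenomekit.simkit import write_fasta

work = Path("demo"); work.mkdir(exist_ok=True)
spec = SimSpec(seed=42, genome_length=200_000, coverage=30)
genome = make_genome(spec)
genome, guide = plant_guide_site(genome, "Vg1", "GACGTAGAGTCCTAGCAATGCCA",
                                 80_000, seed=42)
spec.planted_sites = [PlantedSite(position=guide.expected_cut_position,
                                  overhang=4, efficiency=0.8, guide_id="Vg1")]
write_fasta(work / "genome.fa", {"sim1": genome})
res = simulate_digest(genome, spec, work, prefix="digest")
outputs = run_specificity(dict(
    guide=guide, genome_fasta=str(work / "genome.fa"),
    digest_alignments=str(res.sam), outdir=str(work / "out")))
print(open(outputs["annotated_calls_tsv"]).read())
```

Output:

```
contig	cut_position	score	best_overhang	label
sim1	80022	33.08108108108108	4	ON
```

One site is called, exactly at the planted cut (position 80022 = PAM start
80000 + 4 nt PAM + 18 nt into the protospacer), with the planted 4-nt
overhang recovered and a score of 33.1 — far above the 2.5 cutoff, and close
to the ~36× local depth as expected at 80% efficiency. The BED export
carries the same call with its supporting end counts, and
`cleavage_score.bedgraph` holds the genome-wide score track.

The same stages are available from a shell:

```sh
digenomekit simulate-genome --length 200000 --seed 42 --out genome.fa
digenomekit score --alignments digest.sam --out-prefix scored
digenomekit sitescan --genome genome.fa --guide guide.yaml -k 4 --out hits.tsv
digenomekit indelquant --fastq amp.fastq --amplicon amp.fa --window 31-58 --out summary.tsv
digenomekit run-specificity --config pipeline.yaml
```

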