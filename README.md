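# plastmarker

Species-diagnostic marker discovery for chloroplast genomes (plastomes).

Given closely related plastomes and pooled multi-genotype short reads, the
pipeline:

1. characterizes genome structure — inverted-repeat (IR) detection,
   quadripartite LSC/IRa/SSC/IRb partitioning, GC content, gene copy
   counts, gene-order inversion blocks;
2. maps each species' pooled reads to a reference, tallies per-site allele
   counts, and classifies sites as **fixed interspecific**, **intraspecific
   polymorphic**, monomorphic, low-coverage or ambiguous (IR-resident calls
   are canonicalized onto one IR copy);
3. labels variants with functional context (coding / intron / intergenic
   with flanking genes), transition vs transversion, and synonymous vs
   non-synonymous (translation table 11);
4. converts fixed SNPs into gel-scorable assays — **CAPS** markers (primer
   pair + discriminating restriction enzyme + predicted digestion
   fragments) and **tetra-primer ARMS-PCR** markers (allele-specific inner
   primers terminating on the SNP with a deliberate destabilizing
   mismatch) — and predicts per-species Fixed/Polymorphic band-pattern
   status across genotype panels;
5. ranks shared coding regions by pairwise percent identity and emits a
   sliding identity profile plus a cross-genome coordinate lift-over.

A first-class synthetic-data module generates a three-species plastome trio
(tree `((A,B),C)`), genotype panels with contrasting diversity, and pooled
FASTQ reads with a complete planted truth table, so every stage is testable
offline.

## CLI

```bash
# full synthetic workflow: simulate -> structure -> call -> effects ->
# design -> status -> diverge, with a checksummed manifest and report
plastmarker run --seed 1 --outdir out/

# individual stages
plastmarker simulate --seed 1 --outdir sim/
plastmarker structure genome.fasta --gff genes.gff3
plastmarker call --ref ref.fasta --pool-a a.fastq --pool-b b.fastq --out calls.vcf
plastmarker effects genome.fasta --gff genes.gff3 --pos 199 --ref-allele T --alt-allele A
plastmarker design-caps --genome-a a.fasta --genome-b b.fasta --pos 56829
plastmarker design-arms --genome-a a.fasta --genome-b b.fasta --pos 19580
plastmarker diverge a.fasta b.fasta --gff-a a.gff3 --gff-b b.gff3 --top 15
plastmarker report out/
```

`plastmarker run` accepts a YAML config (`--config cfg.yaml`) whose top
level holds the classification/primer thresholds (see
`plastmarker.plastome_io.RunConfig`) and whose `synthetic:` section holds
the simulator parameters (`plastmarker.synthetic.SynthConfig`).

## File formats

FASTA (60-column), a documented GFF3 subset (one line per interval,
multi-exon features share an `ID`), minimal GenBank flat records, VCF v4.2
subset, a single-end SAM subset (soft clips honored, spliced/paired records
rejected), tab-separated enzyme catalogs (`name<TAB>IUPAC site<TAB>cut
offset`), and YAML configs. Coordinates are 1-based inclusive; circular
intervals may wrap the origin (`end < start`).
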