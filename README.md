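# satevol

Mining, classification and evolutionary analysis of tandem satellite-DNA
monomers, validated end-to-end against a bundled simulator of concerted
evolution.

The package implements a desk-scale pipeline for studying satellite-DNA
families across related genomes:

- **simgen** — simulates multi-species genomes containing heterochromatic
  tandem arrays homogenized within each species (a gene-conversion-like
  Moran process on a species tree), independently diverging dispersed
  euchromatic copies, a derived subfamily carrying a contiguous internal
  deletion (360 bp → 190 bp units), gene annotations at planted distances,
  and shotgun reads with per-base qualities. Everything is seeded and
  byte-reproducible, with exact truth tables.
- **mining** — tandem-array detection by k-mer periodicity, seed-and-extend
  consensus search on both strands (identity ≥ 0.65, query coverage ≥ 0.70),
  dot-plot-style boundary refinement, period confirmation, and extraction of
  phased monomers (units < 75 % of the expected size flagged partial).
- **msa** — reference-anchored star alignment with affine gaps, the 85 %
  site-coverage column mask, and IUPAC majority consensus.
- **phylo** — p-distance, Kimura 2-parameter and gamma-corrected K2P
  distances with pairwise deletion, Saitou–Nei neighbor joining, and a
  species-specific clustering index on unrooted trees.
- **classify** — subfamily typing from the internal-deletion signature
  (F360/F190, canonical-deletion flag), chromatin-domain assignment from
  flanking annotation (genes → euchromatic, repeat-covered flanks →
  heterochromatic) and propagation through average-linkage clusters.
- **stats** — intra/interspecific divergence tables, Tajima's D (complete
  deletion), a concerted-evolution index (intra/inter ratio), and a
  conserved-block finder (10–200 bp windows, permutation p-values with a
  conservative multiplicity correction).
- **annotate** — satellite density in non-overlapping 100 kb windows,
  strand-aware gene proximity (5 kb flanks, midpoint containment), read
  quality filtering (trim to 100 bp, drop reads with > 10 % of bases below
  Q30) and graph-based read clustering for genomic-proportion estimation
  (90 % identity over ≥ 65 % of the read, 0.01 % reporting floor).

## CLI

```bash
satevol simulate --config sim.yaml --outdir out/sim     # genomes, reads, truth
satevol mine --genome out/sim/A.fasta --query out/sim/ancestor.fasta \
             --out-bed arrays.bed --out-fasta monomers.fasta
satevol align --monomers monomers.fasta --reference ref.fasta --out aln.fasta
satevol tree --alignment aln.fasta --model k2p --gamma 1.0 --out tree.nwk
satevol classify --monomers monomers.fasta --reference ref.fasta
satevol stats --alignment aln.fasta --out divergence.tsv
satevol density --arrays arrays.bed --genome out/sim/A.fasta
satevol proximity --arrays arrays.bed --gff out/sim/genes.gff3
satevol proportion --reads out/sim/reads.fastq
satevol run --config pipeline.yaml --outdir out/run     # whole pipeline + manifest
```

A pipeline config is a YAML file with a master `seed`, an optional `stages`
list and a `simulate` section holding simulator parameters; `satevol run`
writes every stage's outputs plus a `manifest.json` with content checksums
(reruns with the same config reproduce the checksums).

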