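# circpipe

A compact, fully tested pipeline for cataloging circular RNAs (circRNAs)
from RNA-seq reads, exercised end-to-end on synthetic data with known
ground truth:

* **simulate** — toy genomes with multi-exon genes (canonical GT/AG splice
  signals), planted back-spliced circles, single-end reads from a
  linear/circular fragment mixture, RNase R digestion as differential read
  survival, and qPCR Ct tables with spike-in/housekeeper channels;
* **detect** — anchor-split back-splice junction calling: 20-nt terminal
  anchors placed exactly with a k-mer index, reversed-order test, maximal
  extension to a unique AG/GT-flanked breakpoint, collapse per junction
  with a ≥ 2 unique-read support threshold;
* **annotate** — host transcript assignment and one of five categories
  (coding_exon / antisense / intronic / noncoding_gene / intergenic),
  genomic and spliced lengths, category share summary;
* **quantify** — junction and linear 5′/3′ boundary read counts and the
  circular-to-linear ratio `CLR = circular / max(linear5', linear3')`
  (pseudocount 1 when no linear reads), plus host-gene TPM;
* **tiers** — per-sample ordinal expression classes (not detected /
  detected / high = top 10%, 5% for platelet-style samples), the plotted
  matrix restricted to circRNAs high somewhere, hierarchical clustering,
  and tissue-overlap counts;
* **orf** — junction-spanning ORFs on the doubled circular sequence and an
  in-silico tryptic junction-peptide FASTA database with exact-match hit
  filtering;
* **ddct** — ΔCt with spike-in + housekeeper (or rRNA) normalization,
  ΔΔCt fold changes and Student/Welch group comparisons.

## CLI

Each stage is a subcommand; stages communicate through files and write
JSON provenance sidecars (parameters, seed, input/output checksums):

```sh
circpipe simulate --outdir run/s1 --seed 1 --n-circles 3
circpipe detect --genome run/s1/genome.fa --reads run/s1/reads.fastq \
    --out-bed run/s1/candidates.bed
circpipe annotate --bed run/s1/candidates.bed --gtf run/s1/genes.gtf \
    --reads run/s1/reads.fastq --out-catalog run/s1/catalog.tsv
circpipe tier --catalogs s1=run/s1/catalog.tsv --catalogs s2=run/s2/catalog.tsv \
    --out-matrix run/tiers.tsv
circpipe orf --catalog run/s1/catalog.tsv --gtf run/s1/genes.gtf \
    --genome run/s1/genome.fa --out-fasta run/peps.fasta --out-tsv run/orfs.tsv
circpipe ddct --ct-table run/ct.tsv --case case --control control --out run/ddct.tsv
circpipe all --outdir run --seed 1          # full toy run, two samples
circpipe check-provenance --sidecar run/sampleA/catalog.tsv.prov.json
```

Simulation parameters can be supplied as a flat `key=value` config file
via `--config` (e.g. `n_genes=20`, `depth=2000`, `circular_fraction=0.5`).

## Conventions

All internal coordinates are 0-based half-open on the forward genomic
strand; GTF (1-based inclusive) is converted on read/write. A catalog
record's `start` is the first base of the circle's 5′-most exon and `end`
is one past its 3′-most exon; `circ_id = chrom:start-end:strand`.
Simulated read names carry truth tags (`|`-delimited fields) documented in
`circpipe/simulate.py`.
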