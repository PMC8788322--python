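# magscreen

Analysis pipeline for barcoded transposon mutant screens with a physical
(magnetic-column) selection step, plus a forward simulator that makes every
stage testable without external data.

Stages:

1. **genome_io** — FASTA/GFF3 reading and writing, 1-based gene coordinates,
   and the central-region convention (default 10–90% of the gene body) that
   defines which insertions disrupt a gene.
2. **pool** — TnSeq read parsing (flank + 20-nt barcode + flank + genomic
   junction), exact-match junction mapping on both strands, modal-locus pool
   construction with a 0.25 minority-conflict multimap rule, and library QC
   (hits per protein, read bias = mean − median reads per hit protein).
3. **essentiality** — per-gene central insertion densities, exclusion of short
   (<100 nt) and duplicate-like genes, a Poisson minimum-length threshold
   (smallest L with exp(−d·L) < α, α = 0.02 by default), and an essential call
   for threshold-length genes with zero central insertions.
4. **barseq** — sample-sheet validation, BarSeq demultiplexing by index
   prefix, and barcode × sample count matrices (zero rows retained, off-pool
   reads tallied).
5. **scoring** — strain log2 scores versus time zero (pseudocount 1,
   depth-normalized), inverse-variance weighted gene scores, the normalized
   magnetic column score (fraction score minus precolumn score, per
   replicate), replicate means, and threshold-based hit calls.
6. **simulate** — seeded end-to-end screen simulator: random genome, planted
   essential genes and per-gene column-retention effects, binomial column
   partitioning with closed-form expected scores log2(p_gene/p_wt), and
   error-free FASTQ emission that round-trips exactly through the pipeline.
7. **morpho** — length-measurement summaries and the Shapiro-gated
   two-sample comparison (Student's t when both samples pass normality,
   Mann–Whitney U otherwise).

## CLI

```bash
# simulate a screen (writes FASTA, GFF3, pool/truth/sample/count TSVs, FASTQ)
magscreen simulate --seed 1 --out screen/ --fastq

# map TnSeq reads into a barcode pool, then QC it
magscreen build-pool --reads screen/tnseq.fastq --genome screen/genome.fasta \
    --genes screen/genes.gff3 --out pool.tsv
magscreen pool-qc --pool pool.tsv --genes screen/genes.gff3 --out qc.json

# call essential genes
magscreen essentials --pool pool.tsv --genes screen/genes.gff3 \
    --alpha 0.02 --min-gene-len 100 --out calls.tsv --summary summary.json

# count barcodes per sample, score, and call hits
magscreen count --reads screen/barseq.fastq --samples screen/samples.tsv \
    --pool pool.tsv --out counts.tsv
magscreen score --counts counts.tsv --samples screen/samples.tsv \
    --pool pool.tsv --out scores.tsv
magscreen report --counts counts.tsv --samples screen/samples.tsv \
    --pool pool.tsv --threshold 1.0 --out hits.tsv

# normality-gated length comparisons
magscreen morpho --lengths lengths.csv --out comparisons.tsv
```

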