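# editscope

Tools for base-editor screens read out by single-cell sequencing: design
sgRNAs for requested amino-acid substitutions, enumerate every achievable
editing outcome (bystanders included), genotype engineered mutations per
cell from aligned long reads of the target transcript, validate calls
against short-read evidence, and classify each variant's expression
phenotype as wild-type-like or functionally significant.

## Modules

| module                   | role |
| ------------------------ | ---- |
| `editscope.refmodel`     | reference slice + transcript model; genomic↔codon maps; amino-acid-change calling over editing windows |
| `editscope.guide_design` | sgRNA design per editor chemistry (CBE/ABE × NGG/NG); exhaustive window-haplotype outcome enumeration; library summaries |
| `editscope.longread`     | soft-clip CB/UMI extraction, CIGAR window base calls, edit-distance UMI consolidation, per-UMI consensus, per-cell genotypes with heterozygote exclusion |
| `editscope.concordance`  | per-UMI identity between platforms, amplicon parsing by anchored matching, variant frequencies, frequency R² |
| `editscope.phenotype`    | QC, normalization, clustering (built-in PCA+k-means or precomputed labels), module scores, cluster-proportion profiles, hierarchical classification, Welch tests, rank-sum DGE |
| `editscope.simulate`     | fully synthetic truth-annotated datasets: errored long reads (SAM) with adapter+CB+UMI soft clips, NB expression with genotype-dependent pathway shifts, NMD-like capture thinning for stop gains |

## CLI

```sh
# synthetic dataset with complete truth tables
editscope simulate --out sim/ --seed 1

# guide design: mutations TSV (gene, ref_aa, codon_index, alt_aa) or a
# single `mutation` column of labels such as V197M
editscope design --mutations muts.tsv --fasta ref.fa --annot tx.json \
    --editor ngg-cbe --editor ng-abe [--byproducts] [--window 3:8]

# per-cell genotyping from aligned long reads (SAM/BAM, soft clips intact)
editscope genotype --bam reads.sam --fasta ref.fa --annot tx.json \
    --whitelist whitelist.txt --windows windows.tsv \
    --min-umi-reads 10 --max-umi-dist 2 --majority-frac 1.0

# long/short-read per-UMI concordance + frequency R^2
editscope concord --long-umis long.tsv --short-umis short.tsv [--log-scale]

# genotype ↔ expression integration and variant classification
editscope integrate --cells genotype.cells.tsv --mtx-dir mtx/ \
    --gene-set pathway_genes.txt [--labels clusters.tsv] --k 10 --min-cells 5

# classify a precomputed variant × cluster proportion matrix
editscope classify --proportions prop.tsv --k-cut 2
```

## File dialects

* **Reference**: FASTA; a `offset=<n>` token in the header restores full
  chromosome coordinates for a locus-only slice.
* **Annotation**: minimal GTF (`exon` + `CDS` features, 1-based inclusive,
  CDS including the stop codon) or the JSON dialect written by
  `TranscriptModel.to_json` (0-based half-open).
* **Windows TSV**: `guide_id  chrom  start  end` (1-based inclusive).
* **Whitelist**: one barcode per line; a trailing `-1` is stripped.
* **Expression**: MatrixMarket triplet directory (`matrix.mtx`,
  `features.tsv`, `barcodes.tsv`; optionally gzipped).

Coordinates are 0-based half-open inside the library; all file output and
log messages print 1-based inclusive positions.

## Conventions that matter

* Window haplotypes are always reported on the genomic **plus strand**;
  amino-acid calling complements internally for minus-strand transcripts.
* Cell-barcode matching is exact (no 1-mismatch rescue).
* UMI consolidation is single-linkage at Levenshtein distance ≤ 2 with
  count-ordered representatives, applied per cell before the minimum
  read-count filter.
* Consensus ties and deletion/uncovered pluralities drop the UMI rather
  than emit ambiguous haplotypes; cells whose consensus UMIs disagree are
  flagged heterozygous and excluded from phenotype analysis.
* Variants seen in fewer than 5 cells are dropped before classification;
  the classifier cuts a complete-linkage dendrogram of cluster-proportion
  rows into 2 groups and labels the group containing WT wild-type-like.
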