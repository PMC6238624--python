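# tierseq

Map endoribonuclease cleavage sites from comparative single-nucleotide
5'-end RNA-seq coverage of a wild-type and a nuclease-deficient strain.

Positions whose first-base-in-read (5'-end) coverage is significantly
depleted when the nuclease is inactivated are called cleavage sites;
positions enriched in the mutant are stabilized primary/upstream 5' ends.
The package provides:

- **coverage** — strand-aware sparse 5'-end coverage from aligned reads or
  variableStep wiggle tracks; multi-library position tables.
- **difftest** — per-position differential enrichment: median-of-ratios size
  factors, method-of-moments NB dispersions with trend shrinkage, a Wald
  test on the log2 wild-type/mutant ratio, Benjamini-Hochberg adjustment.
- **sitecalling** — the >=10-count coverage filter, fold-change >=2 /
  adjusted-p < 0.05 candidate classification, 3-nt single-linkage
  clustering with center selection, BED6 export.
- **annotation** — GFF3 parsing, precedence-based RNA-category assignment
  of cluster centers, per-gene sites-per-kilobase densities, frequencies
  relative to start and stop codons.
- **motif** — 11-nt sequence windows around centers (transcript
  orientation), count/frequency matrices with information content against
  the genome background, iterative one-base shift alignment, per-column
  AU-enrichment tests, FASTA/MEME-minimal export.
- **synthetic** — fully deterministic generator of genomes (~68.8% GC),
  annotations, implanted sites with AU context, and NB count tables with
  configurable effect sizes, plus precision/recall scoring against truth.

## CLI

```sh
# generate a synthetic experiment with ground truth
tierseq simulate --out demo --seed 1

# run the whole pipeline from the generated manifest
tierseq run-all --manifest demo/manifest.yml --out-dir demo/out

# score called clusters against the implanted truth
tierseq evaluate --clusters demo/out/clusters.tsv --truth demo/truth.tsv
```

Individual stages are also exposed (`coverage`, `call`, `annotate`,
`motif`) and compose through plain-text intermediates (TSV / wiggle / BED /
GFF3 / FASTA). A run manifest is a small YAML file listing the genome
FASTA, GFF3 annotation, per-library wiggle pairs with condition labels
(`wild_type` / `mutant`, at least two replicates each) and thresholds
(`min_cov` 10, `fc_min` 2.0, `alpha` 0.05, `proximity` 3, `flank` 5).

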