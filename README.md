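# covbias

Interlaboratory coverage-bias analysis for RNA-seq gene-body profiles.

## The problem

Gene coverage profiles — the per-nucleotide read counts along a gene —
feed directly into expression and exon-usage estimates, yet they carry
systematic, protocol-dependent distortions. Comparing many mRNA and
genome sequencing experiments produced by different laboratories shows
that profiles of the *same* gene are more similar between experiments
from one laboratory (even across tissues) than between laboratories
(even for the same tissue and platform), and that the laboratory
signature survives both 5'–3' linear-trend correction and mappability
normalization. `covbias` packages that analysis as a tested, reusable
pipeline, together with a synthetic-study generator that injects known
laboratory bias signatures so every step can be validated against ground
truth.

## The method

Starting from alignments (SAM) of uniquely mapped reads and a set of
single-exon genes (BED6) — single-exon so genomic and transcriptomic
coverage are directly comparable and splicing cannot distort profiles:

1. **Coverage** — for each gene *g* and experiment *e*, the profile
   `c_{g,e}(i)` counts reads spanning position *i*, oriented 5'→3'.
   Multi-mapped reads are discarded; counts are never depth-scaled
   (Pearson correlation is scale-invariant).
2. **Presence filter** — genes covered by reads in fewer than 90% of
   experiments are discarded.
3. **Similarity** — for each experiment pair, `r_g = corr(c_{g,a}, c_{g,b})`
   per gene, averaged over genes with defined correlation, giving an
   experiment × experiment similarity matrix.
4. **Clustering** — UPGMA (average linkage) on `d = 1 − r`.
5. **Lab contrast** — Wilcoxon rank-sum test of within-laboratory vs
   between-laboratory pair similarities (exact by enumeration at small
   sizes, midrank ties handled).
6. **5'–3' correction** — each experiment's profiles, scaled to gene
   mean 1, are averaged over relative gene position; an OLS line
   `a + b·x` summarizes the trend and profiles are divided by it.
7. **Mappability normalization** — for each read length *L*, every
   genomic L-mer is re-aligned to both strands of the genome under the
   same mismatch allowance as the reads (1 below 26 nt, 2 for 26–50 nt,
   3 above 50 nt); coverage is divided by the fraction of covering
   placements that are unique, masking zero-mappability positions.

## Worked example

Generate a synthetic study — 3 laboratories × 3 experiments, 20 genes,
20 000 reads each, lab-specific bias (linear trends +0.8/0/−0.8 plus a
Gaussian over-coverage bump at a lab-specific position) — and run the
pipeline:

```bash
covbias simulate --out study --seed 1 --n-labs 3 --experiments-per-lab 3 \
    --n-genes 20 --reads 20000 --read-length 50 --slopes 0.8,0,-0.8
covbias run --genome study/genome.fasta --genes study/genes.bed \
    --metadata study/metadata.tsv --out results
```

The run prints its attrition accounting:

```json
{
  "between_pairs": 27,
  "genes_discarded": 0,
  "genes_retained": 20,
  "genes_total": 20,
  "reads_kept": 180000,
  "reads_multimapper": 0,
  "reads_total": 180000,
  "within_pairs": 9
}
```

`results/lab_comparison.tsv` holds the laboratory contrast: here
within-lab mean correlation 0.760 ± 0.040 vs between-lab 0.412 ± 0.094,
with the one-sided exact rank-sum p = 1.06e-08 — the smallest value
attainable with 9 within and 27 between pairs, i.e. every within-lab
pair is more similar than every between-lab pair. The UPGMA tree in
`results/dendrogram.newick` places each laboratory's three experiments
in their own subtree:

```
((lab3_e2,(lab3_e1,lab3_e3)),((lab1_e2,(lab1_e1,lab1_e3)),(lab2_e1,(lab2_e2,lab2_e3))));
```

`covbias run-normalized` repeats the correlation/clustering after the
5'–3' and mappability corrections; normalized profile sets are written
alongside the originals so the two dendrograms can be compared.

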