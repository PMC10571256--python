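# gbmdyn

Read-level CG methylation heterogeneity analysis for plant methylomes:
discovery of **Dynamic gene body methylation (GbM)** — genes whose gene-body
CGs are methylated in only a subset of cells because a DNA demethylase
("eraser") pathway keeps removing methylation that a maintenance
methyltransferase keeps writing back — and its downstream biology:
cross-species conservation of the heterogeneous state, association with
regulatory ("promoter-like") chromatin inside gene bodies, and enhanced
gene-expression plasticity.

## Who this is for

Epigenomics groups working with whole-genome bisulfite or enzymatic
methyl-seq (EM-seq) data from a wild type and a demethylase mutant, who want
to classify genes by the *cell-population heterogeneity* of their gene-body
CG methylation rather than by bulk methylation level alone.

## The statistic

Because PCR duplicates are removed, each remaining read at a cytosine derives
from an independent cell. For each symmetric CG dinucleotide (both strand
cytosines pooled) the heterogeneity fraction

&nbsp;&nbsp;&nbsp;&nbsp;*h* = methylated reads / total reads

estimates the fraction of cells in which that CG is methylated. Sites are
classified with two cutoffs: *h* ≤ 0.10 unmethylated, *h* ≥ 0.85 fully
methylated, otherwise **heterogeneously methylated**. A gene is **Dynamic
GbM** when (1) a hypermethylated wild-type-vs-mutant DMR (aggregation of
≥ 5 differential CGs in a 200-bp window) overlaps its body and (2) at least
5 CG dinucleotides in the body gain > 20 percentage points of methylation in
the mutant. **Stable GbM** genes pass a one-sided per-gene binomial test for
excess fully-methylated CGs over the genome background (BH *q* < 0.05) with
< 1 % gene-body CHG/CHH methylation. Expression plasticity is quantified by
the coefficient of variation (σ/μ) and the Fano factor (σ²/μ) across
tissues/conditions, a decile dynamic-range report with a variance-ratio
F-test, and an inverse regression of mutant-vs-WT fold change on
tissue-specificity fold change.

## Worked example

Everything runs on the built-in synthetic dataset (three gene epigenotypes
with known ground truth; see `docs/methods.md`):

```bash
gbmdyn simulate --out demo_data --seed 3
gbmdyn qc --methylome demo_data/wt.cx.tsv --control ChrC
gbmdyn dmr --ref demo_data/wt.cx.tsv --alt demo_data/mut.cx.tsv --out demo_data/dmrs.bed
```

The QC step prints

```json
{
  "control_contig": "ChrC",
  "apparent_methylation": 0.0025196780163667582,
  "conversion_rate": 0.9974803219836332,
  "n_calls": 44847,
  "passed": true
}
```

i.e. the apparent methylation on the unmethylated control contig is ~0.25 %,
so conversion is > 99.7 % and the library passes. The DMR step reports
`120 DMRs -> demo_data/dmrs.bed`: the 100 simulated dynamic genes each yield
a gene-body hyper-DMR and 20 unmethylated genes carry a simulated intergenic
demethylase target in their 2-kb flank. The first BED line

```
Chr1  4930  5072  DMR_0  8  +  hyper  86.999
```

is a hypermethylated region built from 8 differential CG dinucleotides with a
mean gain of 87 percentage points in the mutant. The full pipeline
(`gbmdyn run --synthetic --out demo_run`) adds classification
(100/100 Dynamic/Stable at 100 % label recovery on the default dataset),
conservation enrichment, chromatin-state overlap, and the plasticity reports.

Library use mirrors the CLI:

```python
from gbmdyn import read_cytosine_report, pool_cg_dinucleotides, classify_site

wt = read_cytosine_report("demo_data/wt.cx.tsv")
sites = pool_cg_dinucleotides(wt)
sites["class"] = sites["h"].map(classify_site)
```

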