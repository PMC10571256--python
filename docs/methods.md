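# Methods

## Model and assumptions

The core quantity is the per-CG heterogeneity fraction *h* = methylated
deduplicated reads / total deduplicated reads. The model behind it is that
after duplicate removal each read is an independent cell, so the read count
at a site is a Binomial(*n*, *p*) draw where *p* is the fraction of cells in
which the CG is methylated. Three per-cell regimes are distinguished:
near-zero *p* (unmethylated genes), near-one *p* (Stable GbM, faithfully
maintained at replication) and intermediate *p* (Dynamic GbM, where eraser
and writer activities balance). Adjacent CGs are treated independently; no
read-level phasing of multiple CGs on one molecule is attempted.

Both cytosines of a symmetric CG are pooled into one dinucleotide site
(the + strand C at position *p* with the − strand C at *p* + 1). A cytosine
whose partner strand is uncovered still forms a single-strand site: at low
depth, dropping unpaired cytosines would censor exactly the sites whose *h*
estimates are noisiest and bias the site-class proportions.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `low`, `high` | 0.10, 0.85 | site-class cutoffs on *h*; both boundaries leave the heterogeneous class (≤ low unmethylated, ≥ high methylated) |
| `min_coverage` | 5 reads | pooled-site floor below which *h* is uncallable; with fewer reads the cutoffs are not meaningful |
| `window_bp` | 200 | DMR aggregation window |
| `min_dmr_sites` | 5 | same-direction differential CGs required in one window |
| `min_delta_pp` | 20 | per-site differential threshold, percentage points, both samples covered |
| `min_gaining` | 5 dinucleotides | second Dynamic cutoff: gene-body CGs gaining > 20 pp in the mutant |
| `flank_bp` | 2000 | intergenic association distance, strand-aware |
| `conversion_threshold` | 0.997 | QC floor on (1 − apparent control-contig methylation) |
| `k_random_sets` | 10 | random same-size gene sets for the conservation baseline |

DMR window placement is exhaustive: a region is seeded by any run of
`min_dmr_sites` consecutive same-direction differential CGs whose span is
below `window_bp`, which is provably identical to enumerating every possible
200-bp window (a stepped grid is not — clusters spanning a grid boundary
with span between step and window size would be missed). Seeds trimmed to
their member sites are merged when they overlap or touch; trimming avoids
inflating downstream overlap statistics with window-edge bases.

The Stable-GbM test is a one-sided binomial tail on the count of fully
methylated gene-body CG sites against the genome-wide fraction of fully
methylated sites, Benjamini–Hochberg corrected across tested genes
(*q* < 0.05), requiring ≥ 10 callable sites and < 1 % gene-body CHG and CHH
methylation (genes with non-CG methylation are targets of de novo pathways
and are excluded throughout, including from homolog sets). A pre-computed
stable-gene list can be supplied instead. Genes classified both Dynamic and
Stable stay in the Venn summary but are excluded from all expression-set
comparisons.

Conservation enrichment keeps one-to-one orthologs only, drops targets with
> 1 % gene-body non-CG methylation (the two filters commute), and compares
the mean per-gene count and per-covered-CG density of heterogeneous CGs in
the target set against the average of k = 10 random same-size source sets
mapped through the same table and filters, with unpaired two-tailed Welch
t-tests (Welch rather than pooled-variance: set sizes and variances differ).
Random sets are drawn from all source genes present in the homolog table;
by default the target set is excluded from the draw pool (for null
calibration the full pool is used, since exchangeability is the hypothesis).

ChIP tracks are normalized per base to log2(depth / genome-wide mean depth);
zero-depth positions are floored at a pseudocount of 0.5 before the ratio
(applying the pseudocount only to zeros keeps the exact identities: a
uniform track maps to 0 and a position at 4× the mean to +2). Feature
enrichment averages the normalized value per feature and reports Cohen's D
((μ₁ − μ₂) / pooled sd) between groups. State overlap is plain interval
intersection against a validated non-overlapping state partition;
percentages are of gene-set base pairs inside the annotation, so they sum
to 100 when the states partition the annotated genome.

Plasticity uses linear (not log) expression values: the Fano factor is only
meaningful on a count-like scale. Unbiased (ddof = 1) variance is used so
Poisson counts give Fano ≈ 1. Replicates are averaged per condition before
CV/Fano. Zero-mean genes are flagged and excluded with a count. The decile
report computes edges from the wild-type genome-wide distribution, so the WT
universe occupies 10 % per decile by construction; the F-test is the
classical two-sample variance-ratio test, two-tailed, assuming normality.
The tissue-specificity regression is ordinary least squares of the
mutant-vs-WT log2 fold change (pseudocount 1 when computed from means) on
the focal-tissue-vs-other-tissues log2 fold change (mean aggregation over
the other conditions; a median flag is provided); genes with zero coverage
in either genotype are excluded upstream, and a perfectly flat response is
reported as slope 0, R² 0 rather than an ill-defined fit.

## What the synthetic generator emulates — and what it does not

`gbmdyn.simulate` generates a two-contig genome (~300 genes, 100 per
epigenotype) plus a 10-kb unmethylated control contig. Per-cell methylation
probabilities are 0.95/0.95 (stable, WT/mutant), 0.50/0.95 (dynamic) and
0.01/0.01 (unmethylated); reads are Binomial draws at Poisson-distributed
coverage (mean 30 per dinucleotide, split over both strands), and an
unmethylated cell reads as methylated with the non-conversion rate
(0.003, matching > 99.7 % conversion chemistry). Each gene carries a dense
CHG/CHH complement (240 cytosines at ~0.2 % methylation — non-CG cytosines
outnumber CGs in real gene bodies, and a sparse complement would make the
1 % ceiling a coin flip). Twenty unmethylated genes get an upstream CG
cluster that hypermethylates in the mutant, exercising the 2-kb flank
association and the intergenic control. A second species carries homologs
with the same class probabilities, 10 % of pairs flagged non-one-to-one and
10 % given > 1 % non-CG methylation to exercise the filters. ChIP tracks
paint a 4× multiplier over dynamic (regulatory mark) or stable (gene-body
mark) bodies on Poisson tile noise; states partition each contig into
promoter / dynamic-body / other-body / intergenic intervals.

Expression matrices use the study-scale set sizes (581 dynamic, 600 stable,
1000 background genes — the sizes the decile and regression analyses
operate on) over 20 conditions: each gene has a latent mean (~500 ± 10) and
per-condition effects with class-dependent spread (dynamic 100 > background
50 > stable 20) plus measurement noise (sd 5). The mutant *redraws* the
dynamic-class condition effects with the spread multiplied by the
canalization factor (default 0.7) — it explores an independently sampled,
proportionally narrower range around the same mean — while other classes
keep the wild-type response up to measurement noise. The redraw (rather
than a deterministic affine shrink of the same profile) is what makes the
mutant-vs-WT variance-ratio test exactly calibrated: at factor 1.0 the two
genotypes are independent equal-variance samples and the F-test rejects at
its nominal 5 % rate, while a shared-profile shrink would make the null
rejection rate 0. Keeping the non-dynamic classes' condition response
shared between genotypes is equally deliberate: redrawing them too would
inject a regression-to-the-mean artifact that fakes the inverse
tissue-specificity relationship for every gene class.

Not emulated: realistic sequence composition, transposons and repeat
methylation, read-level linkage of neighbouring CGs, mapping artifacts,
replicate structure (replicate pooling is a pre-step), and biological
correlation between methylation state and absolute expression level.
Passing tests therefore demonstrate that the statistics recover known
generating structure under the stated sampling model — not that the
thresholds are optimal for any particular real genome.

## Numerical choices and degenerate inputs

Gains and deltas are strict inequalities (> 20 pp); cutoff boundaries are
inclusive as stated above. A gene with no callable CG site is flagged
`no_data` and receives no label. Sites covered in only one sample are
silently absent from differential analysis (both-sample coverage is
required). Cohen's D returns 0 when both groups are identical even if the
pooled sd is 0. Conservation folds are undefined (NaN) if the random
baseline is zero. All randomness (simulation, random gene sets) flows from
explicit seeds through `numpy.random.default_rng`; the full synthetic
pipeline is byte-identical across runs with the same seed, and the results
bundle records a hash of all parameters and input file contents (paths
excluded, so relocating a run does not change the hash).

## Problem sizes

The default simulation (~300 genes, ~21 k cytosine records per methylome,
~2200 expression genes × 20 conditions, 1 Mb of per-base ChIP track) runs
the whole pipeline in a few seconds on one CPU; the test suite, including
the 200-instance DMR oracle comparison and the 100-seed F-test calibration,
completes in well under a minute. These sizes were chosen so that every
stochastic acceptance property is estimated with comfortable precision at
study-scale set sizes (581/600 expression sets) while the methylome stays
small enough to inspect by eye.

## Known limitations

The Stable-GbM binomial procedure is a field-standard reconstruction, not a
re-implementation of any specific published pipeline; supplying a published
stable-gene list is supported for exact set reproduction. DMR calling is
threshold aggregation by design — no per-window hypothesis testing or
multiple-testing control. The heterogeneity statistic conflates cell-to-cell
variability with allele-to-allele variability within a cell; resolving that
requires read-level phasing, which is out of scope.
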