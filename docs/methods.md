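# Methods

## Scope and data flow

The package implements a two-condition bulk RNA-seq comparison between
premature and mature ovary samples as five analysis stages — PCR-duplicate
removal, FPKM quantification with ratio-threshold DE classification,
log2 GO-term enrichment over `is_a` graphs, enrichment-graph export, and
ΔCt qPCR fold changes — plus a synthetic-data generator that produces
every input with planted ground truth. Alignment and read counting are out
of scope: quantification starts from a per-gene, per-replicate count table
and a gene-length table. Likewise the gene→GO mapping is taken as input;
no homology search is performed.

## Duplicate removal

The operational duplicate definition is a pairwise predicate: identical
first 10 bases and whole-read similarity strictly above 0.90. Similarity
is positional identity over the longer read's length; no indel alignment
is attempted, since fixed-cycle Illumina reads from the same template
align column-to-column. The predicate gives no clustering rule, so the
module uses greedy keep-first-in-input-order within 10-base prefix
buckets, which is deterministic and provably identical to the all-pairs
keep-first scan (reads in different buckets fail the prefix clause by
construction; the test suite checks the equivalence against a brute-force
oracle). Boundary handling is strict: a pair at exactly 90% similarity is
kept. Adaptor trimming and quality filtering are intentionally absent —
no adaptor sequences or quality thresholds are part of this design.

Known tension in the source protocol: the sequencing is described as
single-end 101-cycle, yet elsewhere as paired-end. The module implements
single-end semantics.

## Quantification and classification

FPKM_g = count_g × 10⁹ / (length_g × T) with T the sum of the replicate's
per-gene counts; this "total mapped reads = column sum" reading keeps the
computation self-contained. Per-condition values are the arithmetic mean
of per-replicate FPKM (`replicate_mode="average_fpkm"`); pooling counts
before normalizing is available (`"pool_counts"`) and coincides with
averaging when replicate library sizes are equal.

"Expressed" means averaged FPKM strictly greater than 1.0. The
classification universe defaults to the union of the two conditions'
expressed sets (intersection and all-nonzero-genes are options). Ratio
thresholds are 1.5 and 0.67 exactly as stated, deliberately not
"corrected" to 1/1.5 = 0.6667; consequently the neither-band is
asymmetric, and a ratio of 2/3 falls (just) in the mature-up class. A
zero mature FPKM with positive premature FPKM yields ratio +∞ and the
premature-up class, keeping the three labels a partition of the universe.

## Enrichment score

For term t and DE gene sets pre/mat:

    Enrich(t) = log2( ((n_pre + c)/(N_pre + c)) / ((n_mat + c)/(N_mat + c)) )

with c = 0.05. Design choices, each selectable in configuration:

- **Pseudo-count placement** — added to all four quantities. This keeps
  the score finite for any counts and exactly antisymmetric under set
  swap, matching the red/blue duality of the intended visualization. A
  counts-only placement is available.
- **Propagation** — annotations are closed over `is_a` ancestors before
  counting (default on). Internal nodes of a GO graph only accumulate
  gene counts under a hierarchical reading; a no-propagation mode exists.
  Only `is_a` edges are honored; `part_of` and other OBO relations are
  ignored, and obsolete terms are skipped on load.
- **Totals** — N_X is the number of set-X genes with at least one GO
  mapping; unannotated genes are dropped from totals and logged.

## Enrichment graph

GO level is the shortest `is_a` path to the namespace root, with the root
at level 0 (the boundary is configurable, so a root-at-1 convention is
reachable by raising `min_level`). Visibility rules set `display_size` to
0 for level < 2 or fewer than 150 carrying genes (both strict) without
altering stored scores or counts; `n_genes` for sizing is the count of
genes over the union of both DE sets after propagation (the sets are
disjoint, so the two per-set counts add). "Significance" for branch
pruning is operationalized as |score| ≥ 1.0 — a two-fold frequency ratio
— a convention of this package, since no statistical test is part of the
score. A branch survives iff some descendant-or-self is significant.
Export is GraphML plus a SIF/node-attribute pair; both round-trip
losslessly through the provided readers.

## qPCR

ΔCt = Ct_mature − Ct_premature, so a positive value means earlier
detection (higher expression) in the premature ovary; fold change =
efficiency^ΔCt with efficiency fixed at the ideal 2.0 per cycle (exposed
as a parameter; no calibration data are modelled). No reference-gene
normalization (ΔΔCt) is applied — inputs are assumed to come from equal
template amounts. Ct values at or beyond the 44-cycle cap are non-detects
and are excluded, not extrapolated.

## Synthetic data: what it emulates, what it does not

The generator's defaults mirror the study design scaled to desk size:
2 conditions × 2 replicates; 2 000 genes with lengths uniform in
0.5–5 kb; 200 000 reads per library (the real libraries are ~10⁷ reads —
the smaller size changes nothing structural, only the FPKM magnitudes);
10% of genes planted up in each condition at a two-fold expression ratio;
a 60-term, three-namespace GO DAG with two terms planted at a 2× frequency
skew (base annotation probability 0.3); 101-base single-end reads with a
20% duplicate rate, 2% post-prefix mutation rate, and 10% boundary decoys.

Counts follow the NB2 negative-binomial (var = μ + dμ², default d = 0.1,
a typical bulk-RNA-seq value), sampled as a gamma–Poisson mixture so that
d → 0 degenerates exactly to Poisson. Fold changes are planted
symmetrically on the FPKM scale (×√f in one condition, /√f in the other)
so the expected FPKM ratio equals the nominal fold and per-condition
totals stay balanced; baseline abundances are lognormal (σ = 1).
Between-replicate biological variance defaults to 0 — each sample pools
RNA from three animals, so the two libraries per condition are treated as
near-technical replicates — with a lognormal variance knob available.

Planted GO terms are kept childless in the generated DAG: a planted term
with descendants would have its direct-annotation skew diluted by `is_a`
propagation, invalidating the planted truth. Planted duplicates mutate
only positions after the 10-base prefix, capped so similarity stays
strictly above 0.90; decoys carry exactly one mismatch more than that
cap, pinning the strict inequality.

What passing on these data does **not** show: robustness to adaptor
contamination, quality artefacts or indels in reads; transcript-level
ambiguity (the generator works at gene level); realistic GO topology
(real ontologies have thousands of terms and multiple inheritance far
deeper than the default depth-4 DAG); or calibration of the ratio
classifier's error rate on real biological replicates.

## Numerical and degenerate-input choices

- All threshold comparisons are strict (`>`/`<`), matching the stated
  rules; boundary fixtures (similarity exactly 0.90, FPKM exactly 1.0,
  ratios exactly 1.5/0.67, 149 genes) are pinned by tests.
- Empty libraries (T = 0), both-zero FPKM pairs, cycles in the ontology,
  terms that cannot reach a namespace root, and out-of-range Ct values
  raise typed errors rather than producing NaN.
- Ratio classification with a zero denominator returns +∞, not an error,
  preserving the class partition.
- Configuration validation reports the complete list of violated fields
  in one pass.
- Every random draw flows from a single integer seed through named child
  streams, one per generator, so outputs are independent of call order
  and byte-identical across runs. The run manifest records wall-clock
  timestamps and is therefore the one output excluded from the
  byte-identity guarantee.

## Known limitations

The ratio classifier has no dispersion model, so at the default noise
level (d = 0.1) genes planted at two-fold recover their class in roughly
80–85% of cases — an inherent property of thresholding noisy ratios from
two replicates, not an implementation artefact; recovery exceeds 95% only
for dispersion ≲ 0.02, fold ≥ 3, or more replicates. The enrichment score
is descriptive (no p-value), and the graph's significance bar is a
convention, not a test.
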