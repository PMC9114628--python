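# Methods

This note documents the models, conventions and design choices behind
`cellensemble`, in the spirit of a methods section: what each component
computes, which knobs matter, and what the synthetic benchmarks do and do not
demonstrate.

## The unified table

All cells live in one sparse cells × genes matrix over a fixed, closed gene
axis, with a 17-field free-text metadata record per cell (`user_id`,
`study_id`, `cell_id`, `organ`, `region`, `subregion`, `seq_tech`,
`sample_status`, `donor_id`, `donor_gender`, `donor_age`, `original_name`,
`cl_name`, `uhaf_name`, `tissue_type`, `cell_type`, `marker_gene`). Rows are
keyed by a contiguous 0-based integer cid assigned at insertion and never
reused; appends extend the cid range and leave existing rows untouched.
Missing metadata is stored as the empty string, never null, so string
comparisons are total. Stored values are depth-adjusted, log-normalized
expression; raw counts exist only upstream in the ingest pipeline.

Persistence is a four-file plain-text directory — `metadata.csv` (UTF-8,
minimal quoting), `matrix.mtx` (MatrixMarket coordinate real general,
1-based), `rows.txt`, `cols.txt` — chosen as a portable, language-neutral
interchange dialect. The MatrixMarket writer emits 16-digit exponents, so
float64 values round-trip bit-exactly; round-trip identity is asserted in the
test suite over randomized tables, including quoting-hostile metadata.

## Gene-symbol unification

Datasets name genes inconsistently. Ingest re-indexes every matrix onto the
approved-symbol list via case-sensitive exact matching: approved names map to
themselves, aliases through the alias map, anything else is dropped and
reported. Input names resolving to the same approved symbol are **summed** —
aliases denote the same locus, and summation conserves total counts exactly
(conservation and idempotence are tested as exact-integer identities).
Approved genes absent from a dataset become zero columns, so every dataset
lands on the identical axis. Ensembl-to-symbol conversion is out of scope;
it is accepted as a pre-supplied alias file.

## Normalization

Datasets deposited in log scale are first de-logged (v → baseᵛ − 1; the base
is per-dataset configuration, pseudo-count fixed at 1). Counts are then
library-size normalized: valueᵢ𝗀 = ln(1 + countᵢ𝗀 · s / Lᵢ) with s = 10,000
reads per cell and Lᵢ the cell's total. Natural log is the package's declared
convention (the common default of the standard normalization routines).
Consequences used as invariants: Σ𝗀 expm1(valueᵢ𝗀) = s for every non-empty
cell, and the transform is invariant to rescaling a cell's counts (depth
removal). Cells with zero library are kept as all-zero rows and reported —
dropping them is a QC policy that belongs to the caller, as do per-dataset
gene/cell filters.

## The annotation ontology

A typed DAG: nodes carry a kind (system, organ, region, subregion — the
macroscopic vocabulary — or tissue_type, cell_type — the microscopic one);
edges run child → parent and are typed `is_a` or `part_of`. `is_a` is
restricted to same-kind microscopic pairs (a subtype specializes a type);
`part_of` may cross kinds (a cell type is part of an anatomical unit).
Cycles, duplicate names and unknown edge types are construction errors, with
a cycle witness named. Marker references attach genes with a provenance tag
(knowledge- vs data-derived) to microscopic nodes, de-duplicated by symbol
keeping the first tag.

Subtree queries (`descendants`) are breadth-first over reversed edges of the
requested types with set semantics, so diamonds count once. The Cell
Ontology mapping is a deterministic cascade: exact whole-string match,
otherwise a breadth-first is-a parent walk (parents visited in file order,
which is the declared tie-break for multi-parent nodes), otherwise a curated
map standing in for the manual-judgment step, otherwise `"none"`. Standard
labels are composed as `organ-tissue_type-cell_type-markers`; clusters whose
cell type cannot be resolved are labeled `Unclassified`.

## The query language

Grammar: comparisons `column op value` with `== != > >= < <=`; `!` > `&&` >
`||` in precedence, left-associative, parentheses override. A value token
extends to the next logical operator or unbalanced `)` and is trimmed, which
lets unquoted multi-word labels parse without a quoting convention. Canonical
operator tokens only — an operator with interior whitespace (`= =`) is a
parse error. Parsing is a small recursive-descent pass over the raw string
(value tokens are context-dependent, so a conventional tokenizer fits
poorly); `unparse` emits a fully parenthesized canonical form and
`parse(unparse(ast)) == ast` is property-tested over generated ASTs.

Evaluation: metadata comparisons are exact, case-sensitive string tests;
ordering operators on metadata are errors unless the caller declares the
field numeric (`numeric_fields={"donor_age"}`), in which case non-numeric
entries compare false. Gene comparisons evaluate against the stored
normalized values — thresholds like 0.5 are therefore on the normalized
scale. No epsilon is applied to numeric comparisons; thresholds are
user-chosen. `!=` and `!` are complements over the evaluated row set. With
`include_children`, equality on `cell_type` expands through `is_a` and on
`organ` through `is_a` + `part_of`; both fields sit behind the one flag. The
engine is deliberately a linear scan with column pruning — correctness is
guaranteed by an oracle-equivalence test against per-row brute-force
evaluation over ≥ 1000 randomized table/expression pairs, not by an
optimizer.

## Portraits

Gene portraits report per group (organ or cell type): cell count, detected
count, detection fraction, and the median and quartiles of **non-zero**
values — zeros are truncated before the distribution summary because
dropout-inflated zeros would swamp it. "Expressed" means value > 0 here,
distinct from the 0.5 sorting threshold used in the worked queries. Display
fitting (ridge densities, embeddings) is out of scope; portraits expose the
statistics.

Cell-type markers: each gene is tested in-group vs all other cells with a
two-sided Wilcoxon rank-sum (normal approximation with tie correction;
genes constant across both groups get p = 1), adjusted by Bonferroni over
the tested genes (Benjamini–Hochberg available). Retained markers need
adjusted p ≤ 0.05, detection in ≥ 25 % of in-group cells, and positive fold
change; the top 50 by log fold change are reported, descending. Fold change
is computed on de-logged values with a unit pseudo-count,
ln((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)), so it reads on the
expression scale. Two-sided testing with a positive-FC filter is the
declared convention.

## Inverse-transform batch correction

Per gene: mean μ and standard deviation σ over the normalized values
(zero-variance genes get σ = 1); loadings W are the top-k right singular
vectors of the scaled matrix S = (X − μ)/σ, with a deterministic sign
convention (largest-magnitude entry of each component positive, lowest index
winning ties), embedding Z = S·W. k defaults to 100 components, the
dimensionality the per-organ pipeline operates in; at k = min(n, g) the
round trip is exact to numerical precision, and reconstruction error is
non-increasing in k.

The integration step itself is an external input: `inverse_correct` accepts
*any* corrected embedding and computes X̂ = (Z·Wᵀ)·σ + μ. This keeps the
inverse step — the part that turns an aligned embedding back into
biologically interpretable expression values — testable without
re-implementing any particular integration algorithm. Negative reconstructed
values are clipped to 0 and counted (expression semantics demand
non-negativity; whether to re-log or clip after inversion is genuinely open,
and clipping with a report is the least destructive choice). Per-organ
orchestration fits one model per organ and never corrects across organs,
which need not share cell types.

## Label transfer and evaluation

References are selected from the table by any sorting condition; unlabeled
cells are excluded with a warning. Transfer is k-nearest-neighbor majority
vote (k = 10) in a caller-chosen embedding with Euclidean distance; ties go
to the smallest summed distance among tied labels, then lexicographic — the
vote's tie-break is otherwise undefined, so it is pinned here for
determinism.

Evaluation: a prediction is correct iff it equals the truth or, when is-a
credit is enabled, is an is-a ancestor of it (predicting "Dendritic cell"
for a cDC1 cell is correct). Accuracy and its exact Clopper–Pearson 95 %
binomial interval use this lenient count; the confusion matrix and Cohen's
κ = (p_o − p_e)/(1 − p_e) always use raw labels — folding hierarchy credit
into the chance-correction term is undefined, so κ stays strict even when
accuracy is lenient. κ is implemented from the marginal formula and
cross-checked against an independent library implementation in the tests.

## Synthetic data: what it emulates and what it does not

The generator draws counts from a negative binomial with fixed dispersion
0.1 (variance m + 0.1 m²), gene baselines from a lognormal around 0.5,
planted markers as multiplicative mean shifts (default 4×, three markers per
type) inside their cell type, batches as library-size multipliers, and
aliases by renaming a fraction of genes with the mapping recorded in the
symbol table. Marker-gene baselines are floored at the typical mean: a
marker is by definition a detectably expressed gene, and a "marker" sitting
below the 25 % detection filter in its own type would be biologically
incoherent. The toy ontology is a three-level tree (organ → tissue type →
cell types with one is-a subtype each), enough to exercise subtree queries
and is-a scoring. Batch offsets for correction experiments are planted
directly in the embedding span (`plant_embedding_offset`), so known-offset
correction has an exact answer.

What passing these benchmarks shows: the machinery is correct — queries
match brute force, conservation identities hold exactly, planted signals of
specified size are recovered, the inverse transform is exact where algebra
says it must be. What it does not show: performance on real tissues. The
generator has no gene–gene covariance, no doublets or ambient RNA, no
continuous states, and its batch effects are exactly representable in the
PCA span — real batch effects are not, and real markers do not arrive as
clean 4× mean shifts.

## Problem sizes and numerical conventions

Test and acceptance runs use deliberately small instances — tables of tens
of cells for the randomized query oracle (1000 pairs), 200 cells/type and
120–150 genes for marker recovery, 500 × 60 for correction recovery — sizes
at which every oracle can be recomputed naively and the full suite runs in
seconds. Tolerances: conservation identities at 1e−6 relative or exact
integers; full-rank reconstruction at 1e−6 absolute; planted-offset recovery
at 1e−4 RMSE; orthonormality at 1e−8; composition fractions at 1e−12.
Degenerate inputs are kept total rather than erroring where a sensible value
exists: empty tables query to empty cid lists, zero-library cells normalize
to zero rows, constant genes get unit std, empty marker groups raise.
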