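# cellensemble

Cell-centric assembly and querying of single-cell transcriptomic atlases.

Most "atlas" resources are file-centric: data live as per-study matrices, and
using cells from many studies means downloading and reprocessing many files.
`cellensemble` implements the alternative: every cell from every study is a
row in one **unified table** — its full normalized expression vector over a
fixed approved-gene axis plus a 17-field metadata record (organ, region,
donor, sequencing technology, original and standardized annotations, ...).
On top of that single structure the package provides, for computational
biologists assembling or mining multi-study single-cell data:

- **"In data" cell sorting** — a logic-expression language over metadata and
  gene expression, the computational analogue of flow cytometry:
  `(organ==Heart) && (cell_type == T cell) && (PTPRC > 0.5) && ((CD3D >= 0.5) || (CD3E >= 0.5))`.
  Operators `== != > >= < <=` combined with `!`, `&&`, `||`
  (precedence NOT > AND > OR); unquoted multi-word values like `T cell` parse.
- **A hierarchical annotation ontology** — a typed DAG of macroscopic
  (system/organ/region/subregion) and microscopic (tissue type/cell type)
  entities with *is-a* and *part-of* edges and marker references. Equality
  queries on `cell_type`/`organ` can expand to the whole subtree
  (`include_children`); standard labels are composed as
  `organ-tissue_type-cell_type-markers`; cell-type names map onto Cell
  Ontology preferred labels by exact match → is-a parent walk → curated map
  → `"none"`.
- **Standardized ingest** — gene-symbol unification onto a closed
  approved-symbol axis (aliases translated, colliding names summed, missing
  genes zero-filled) and library-size normalization: for cell *i* with
  library size *L*ᵢ, the stored value is ln(1 + *x*ᵢ𝗀 · 10000 / *L*ᵢ), so
  expm1 of any cell's row sums back to 10,000.
- **Quantitative portraits** — per-group gene expression summaries (detection
  rate, non-zero medians and quantiles), cell-type marker tables (two-sided
  Wilcoxon rank-sum, Bonferroni ≤ 0.05, ≥ 25 % detection, top 50 by log fold
  change), and organ cell-type compositions.
- **Inverse-transform batch correction** — fit per-gene mean/std and top-*k*
  PCA loadings (default *k* = 100), hand the embedding to any external
  integration method, then invert: X̂ = (Z·Wᵀ)·σ + μ, returning corrected
  data on the expression scale rather than abstract coordinates.
- **Label transfer and evaluation** — customized references selected by any
  sorting condition; KNN majority vote (k = 10, Euclidean, ties by summed
  distance then lexicographic); confusion matrix, accuracy with exact
  Clopper–Pearson CI, Cohen's κ, and *is-a-aware* accuracy that credits
  predicting an ancestor of the true label.
- **A synthetic-atlas generator** — negative-binomial counts with planted
  marker folds, batches, gene aliases and a toy ontology, so the entire
  pipeline is testable with known ground truth and no downloads.

## Worked example

```python
import cellensemble as ce

spec = ce.SyntheticAtlasSpec(seed=0, n_genes=120, n_cells_per_type=150)
bundle = ce.generate_atlas(spec)           # counts + metadata + ontology + truth
table = ce.assemble(bundle)                # unify symbols -> normalize -> insert

expr = "(organ==Heart) && (cell_type == T cell) && ((GENE0000 >= 0.5) || (GENE0001 >= 0.5))"
strict = ce.query_cells(table, expr)
expanded = ce.query_cells(table, expr, include_children=True,
                          ontology=bundle.ontology)
print(len(strict), len(expanded))
```

prints `75 150`: the heart contains 150 T-lineage cells, half annotated with
a subtype label; the exact-label query returns the 75 cells labeled
`T cell`, and `include_children` folds the subtype back in. Projecting the
selection (`table.fetch(rows=expanded, cols=["cell_type", "GENE0000"])`)
shows every sorted cell passes the gene gate, and
`ce.celltype_organ_crosstab(table, expanded)` summarizes the selection as an
organ × cell-type count table. Running `examples/04_label_transfer.py`
transfers coarse reference labels onto a fine-grained query batch and prints

```
strict accuracy:     0.443  95% CI [0.393, 0.493]
is-a-aware accuracy: 0.907  95% CI [0.875, 0.934]
```

— the gap is exactly the subtype cells correctly annotated with their parent
type. The `examples/` directory holds one short script per capability
(sorting, portraits, batch correction, label transfer, ontology).

A thin CLI mirrors the library:
`cellensemble simulate|ingest|query|download|normalize|portrait|correct|annotate|uhaf …`
(e.g. `cellensemble query --atlas DIR --expr 'organ==Heart && CD3D>=0.5' --out cids.txt`).

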