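"""Synthetic-atlas generation with known ground truth.

Generates everything the pipeline ingests — counts, 17-column metadata, a toy
annotation ontology, an approved-symbol table with planted aliases, batch
structure — so every module is testable without any external download. Counts
follow a negative-binomial model (fixed dispersion 0.1, a standard stand-in
for scRNA-seq overdispersion); marker genes have their mean multiplied by a
planned fold within their cell type; batches scale library sizes. The toy
ontology is a three-level tree (organ -> tissue type -> cell types, each cell
type with one is-a subtype) so subtree queries and is-a evaluation are
exercised. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import CellEnsembleError
from .genes import GeneSymbolTable, unify_symbols
from .normalize import NormalizationConfig, normalize_library_size
from .store import UnifiedTable
from .uhaf import UHAFOntology, compose_uhaf_name


@dataclass(frozen=True)
class MarkerPlan:
    """Marker genes planted for one cell type: gene indices and the
    multiplicative mean shift inside the type (> 1)."""

    cell_type: str
    genes: tuple[int, ...]
    fold: float = 4.0


@dataclass(frozen=True)
class BatchPlan:
    """One batch: name and the library-size multiplier applied to its cells."""

    name: str
    lib_multiplier: float = 1.0


@dataclass
class SyntheticAtlasSpec:
    """Study conditions for one synthetic atlas.

    Defaults: 300 genes; two organs with overlapping cell types; 200 cells
    per (organ, cell type); three disjoint 4x markers per cell type; a single
    batch; 10% of gene names replaced by aliases.
    """

    seed: int = 0
    n_genes: int = 300
    organs: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "Heart": ("T cell", "Cardiomyocyte cell"),
            "Lung": ("T cell", "B cell"),
        }
    )
    n_cells_per_type: int = 200
    markers: tuple[MarkerPlan, ...] | None = None  # None -> auto plan
    markers_per_type: int = 3
    batches: tuple[BatchPlan, ...] = (BatchPlan("batch1"),)
    alias_rate: float = 0.1
    dispersion: float = 0.1
    base_mean: float = 0.5
    subtype_fraction: float = 0.5  # fraction of each type labeled as its subtype

    def cell_types(self) -> list[str]:
        seen: list[str] = []
        for types in self.organs.values():
            for ct in types:
                if ct not in seen:
                    seen.append(ct)
        return seen

    def resolve_markers(self) -> tuple[MarkerPlan, ...]:
        if self.markers is not None:
            return self.markers
        plans = []
        cursor = 0
        for ct in self.cell_types():
            genes = tuple(range(cursor, cursor + self.markers_per_type))
            plans.append(MarkerPlan(ct, genes, 4.0))
            cursor += self.markers_per_type
        return tuple(plans)

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_type <= 0:
            raise CellEnsembleError("n_genes and n_cells_per_type must be positive")
        if not self.organs or not self.batches:
            raise CellEnsembleError("at least one organ and one batch required")
        for plan in self.resolve_markers():
            if plan.fold <= 1.0:
                raise CellEnsembleError(f"marker fold must exceed 1: {plan}")
            if any(g < 0 or g >= self.n_genes for g in plan.genes):
                raise CellEnsembleError(f"marker gene index out of range: {plan}")
            if plan.cell_type not in self.cell_types():
                raise CellEnsembleError(f"marker for unknown cell type: {plan}")
        for batch in self.batches:
            if batch.lib_multiplier <= 0:
                raise CellEnsembleError(f"lib_multiplier must be positive: {batch}")
        if not 0 <= self.alias_rate < 1:
            raise CellEnsembleError("alias_rate must be in [0, 1)")


@dataclass
class AtlasBundle:
    """Everything :func:`generate_atlas` produces."""

    counts: sp.csr_matrix  # cells x genes, raw counts
    gene_names: list[str]  # as a dataset would report them (aliases included)
    metadata: pd.DataFrame  # 17-column schema
    ontology: UHAFOntology
    symbol_table: GeneSymbolTable
    truth: dict  # labels, base types, organs, batches, marker plan, aliases


def _toy_ontology(spec: SyntheticAtlasSpec) -> UHAFOntology:
    nodes, edges = [], []
    for organ in spec.organs:
        nodes.append({"id": organ, "name": organ, "kind": "organ"})
        tissue = f"{organ} tissue"
        nodes.append({"id": tissue, "name": tissue, "kind": "tissue_type"})
        edges.append({"child": tissue, "parent": organ, "type": "part_of"})
    for ct in spec.cell_types():
        nodes.append({"id": ct, "name": ct, "kind": "cell_type"})
        sub = f"{ct} subtype"
        nodes.append({"id": sub, "name": sub, "kind": "cell_type"})
        edges.append({"child": sub, "parent": ct, "type": "is_a"})
    for organ, types in spec.organs.items():
        for ct in types:
            edges.append({"child": ct, "parent": organ, "type": "part_of"})
    markers = []
    gene_name = lambda g: f"GENE{g:04d}"
    for plan in spec.resolve_markers():
        for g in plan.genes:
            markers.append(
                {"node": plan.cell_type, "gene": gene_name(g), "provenance": "planted"}
            )
    return UHAFOntology(nodes, edges, markers)


def generate_atlas(spec: SyntheticAtlasSpec) -> AtlasBundle:
    """Generate counts + metadata + ontology + symbol table + ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    approved = [f"GENE{g:04d}" for g in range(spec.n_genes)]
    marker_plans = spec.resolve_markers()
    fold_by_type = {
        plan.cell_type: dict.fromkeys(plan.genes, plan.fold) for plan in marker_plans
    }

    pairs = [(organ, ct) for organ, types in spec.organs.items() for ct in types]
    n_cells = len(pairs) * spec.n_cells_per_type
    base_mu = rng.lognormal(mean=np.log(spec.base_mean), sigma=1.0, size=spec.n_genes)
    # marker genes are detectably expressed by definition: floor their
    # baseline at the typical mean so the planted shift is observable
    for plan in marker_plans:
        for g in plan.genes:
            base_mu[g] = max(base_mu[g], spec.base_mean)

    rows_organ, rows_type, rows_label, rows_batch = [], [], [], []
    mean_rows = np.empty((n_cells, spec.n_genes))
    i = 0
    for organ, ct in pairs:
        fold = np.ones(spec.n_genes)
        for g, f in fold_by_type.get(ct, {}).items():
            fold[g] = f
        n_sub = int(round(spec.subtype_fraction * spec.n_cells_per_type))
        for j in range(spec.n_cells_per_type):
            batch = spec.batches[i % len(spec.batches)]
            mean_rows[i] = base_mu * fold * batch.lib_multiplier
            rows_organ.append(organ)
            rows_type.append(ct)
            rows_label.append(f"{ct} subtype" if j < n_sub else ct)
            rows_batch.append(batch.name)
            i += 1

    # NB with mean m and variance m + dispersion * m^2
    r = 1.0 / spec.dispersion
    p = r / (r + mean_rows)
    counts = sp.csr_matrix(rng.negative_binomial(r, p).astype(np.float64))

    # replace a deterministic fraction of gene names by recorded aliases
    n_alias = int(np.floor(spec.alias_rate * spec.n_genes))
    alias_idx = rng.choice(spec.n_genes, size=n_alias, replace=False)
    gene_names = list(approved)
    alias_map: dict[str, str] = {}
    for g in sorted(alias_idx):
        alias = f"{approved[g]}-OLD"
        gene_names[g] = alias
        alias_map[alias] = approved[g]
    symbol_table = GeneSymbolTable(tuple(approved), alias_map)

    ontology = _toy_ontology(spec)
    marker_gene = {
        plan.cell_type: approved[plan.genes[0]] if plan.genes else ""
        for plan in marker_plans
    }
    records = []
    for cid in range(n_cells):
        organ, base, label = rows_organ[cid], rows_type[cid], rows_label[cid]
        records.append(
            {
                "user_id": "synthetic",
                "study_id": rows_batch[cid],
                "cell_id": f"cell{cid:06d}",
                "organ": organ,
                "seq_tech": "simulated",
                "sample_status": "healthy",
                "donor_id": rows_batch[cid],
                "donor_gender": ("female", "male")[cid % 2],
                "donor_age": "40",
                "original_name": label,
                "uhaf_name": compose_uhaf_name(
                    organ, f"{organ} tissue", label, marker_gene.get(base, "")
                ),
                "tissue_type": f"{organ} tissue",
                "cell_type": label,
                "marker_gene": marker_gene.get(base, ""),
            }
        )
    metadata = pd.DataFrame(records)

    truth = {
        "base_type": rows_type,
        "assigned_label": rows_label,
        "organ": rows_organ,
        "batch": rows_batch,
        "markers": marker_plans,
        "alias_map": alias_map,
        "gene_means": base_mu,
    }
    return AtlasBundle(counts, gene_names, metadata, ontology, symbol_table, truth)


def assemble(
    bundle: AtlasBundle, config: NormalizationConfig | None = None
) -> UnifiedTable:
    """Run the standard ingest pipeline on a generated bundle:
    unify symbols -> library-size normalize -> insert into a fresh table."""
    unified, _ = unify_symbols(bundle.counts, bundle.gene_names, bundle.symbol_table)
    normalized, _ = normalize_library_size(unified, config)
    table = UnifiedTable(list(bundle.symbol_table.approved))
    table.insert_cells(normalized, bundle.metadata)
    return table


def plant_embedding_offset(
    normalized,
    batch_mask: np.ndarray,
    k: int,
    offset_scale: float = 5.0,
    seed: int = 0,
):
    """Plant an additive batch offset confined to the embedding span.

    Fits a correction model on the clean normalized matrix, shifts the
    embedding rows of the masked batch by a random offset of the given scale,
    and inverts back to expression space (without clipping, so the shift stays
    exactly in-span). Returns ``(model, clean_embedding, shifted_embedding,
    shifted_matrix, offset)`` — correcting the shifted embedding by the known
    offset must recover the clean matrix.
    """
    from .correction import fit_correction_model

    rng = np.random.default_rng(seed)
    model, z = fit_correction_model(normalized, k)
    offset = rng.normal(scale=offset_scale, size=model.k)
    z_shifted = z.copy()
    z_shifted[np.asarray(batch_mask, dtype=bool)] += offset
    x_shifted = (z_shifted @ model.loadings.T) * model.gene_std + model.gene_mean
    return model, z, z_shifted, x_shifted, offset
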