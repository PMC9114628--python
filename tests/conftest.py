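"""Shared fixtures: toy tables and ontologies, a brute-force query oracle,
and a random expression generator used by the oracle-equivalence tests."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

import cellensemble as ce


# -- independent query oracle -------------------------------------------------


def brute_force_eval(expr, row: dict, gene_names: set[str],
                     subtree=None) -> bool:
    """Evaluate a parsed expression on one cell, the slow obvious way.

    ``row`` maps column name -> value (str for metadata, float for genes).
    ``subtree`` maps (field, label) -> set of matching labels when mimicking
    include_children; None means exact matching.
    """
    if isinstance(expr, ce.Not):
        return not brute_force_eval(expr.child, row, gene_names, subtree)
    if isinstance(expr, ce.And):
        return all(brute_force_eval(c, row, gene_names, subtree) for c in expr.children)
    if isinstance(expr, ce.Or):
        return any(brute_force_eval(c, row, gene_names, subtree) for c in expr.children)
    col, op, val = expr.column, expr.op, expr.value
    if col in gene_names:
        left, right = float(row[col]), float(val)
        return {
            "==": left == right, "!=": left != right, ">": left > right,
            ">=": left >= right, "<": left < right, "<=": left <= right,
        }[op]
    left = row[col]
    if subtree is not None and (col, val) in subtree:
        hit = left in subtree[(col, val)]
    else:
        hit = left == val
    return hit if op == "==" else not hit


def random_expression(rng: np.random.Generator, genes: list[str],
                      meta_values: dict[str, list[str]], depth: int = 0):
    """Random well-formed AST over the given gene and metadata vocabulary."""
    kind = rng.choice(
        ["cmp", "and", "or", "not"] if depth < 3 else ["cmp"],
        p=[0.5, 0.2, 0.2, 0.1] if depth < 3 else [1.0],
    )
    if kind == "cmp":
        if rng.random() < 0.5:
            gene = genes[rng.integers(len(genes))]
            op = ["==", "!=", ">", ">=", "<", "<="][rng.integers(6)]
            value = f"{rng.uniform(0, 9):.2f}"
            return ce.Comparison(gene, op, value)
        field = list(meta_values)[rng.integers(len(meta_values))]
        op = ["==", "!="][rng.integers(2)]
        value = meta_values[field][rng.integers(len(meta_values[field]))]
        return ce.Comparison(field, op, value)
    if kind == "not":
        return ce.Not(random_expression(rng, genes, meta_values, depth + 1))
    children = tuple(
        random_expression(rng, genes, meta_values, depth + 1)
        for _ in range(rng.integers(2, 4))
    )
    return ce.And(children) if kind == "and" else ce.Or(children)


def random_table(rng: np.random.Generator, n_cells: int = 30, n_genes: int = 6):
    """Small random table with categorical metadata and sparse expression."""
    genes = [f"G{j}" for j in range(n_genes)]
    organs = ["Heart", "Lung", "Brain"]
    types = ["T cell", "B cell", "Neuron"]
    values = sp.random(
        n_cells, n_genes, density=0.5, random_state=np.random.RandomState(
            int(rng.integers(2**31))
        ),
        data_rvs=lambda n: np.round(
            np.random.RandomState(int(rng.integers(2**31))).uniform(0, 9, n), 2
        ),
    )
    meta = [
        {
            "organ": organs[rng.integers(3)],
            "cell_type": types[rng.integers(3)],
            "donor_gender": ["female", "male"][rng.integers(2)],
        }
        for _ in range(n_cells)
    ]
    table = ce.UnifiedTable(genes, values, meta)
    meta_values = {
        "organ": organs,
        "cell_type": types,
        "donor_gender": ["female", "male"],
    }
    return table, genes, meta_values


def oracle_cids(table, expr, gene_names, subtree=None):
    out = []
    for cid in range(table.n_cells):
        row = {f: table.metadata[f].iloc[cid] for f in ce.METADATA_FIELDS}
        dense = table.values[cid].toarray().ravel()
        row.update({g: dense[j] for j, g in enumerate(table.gene_axis)})
        if brute_force_eval(expr, row, set(gene_names), subtree):
            out.append(cid)
    return out


# -- fixtures -----------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_ontology():
    """T-cell subtree plus a two-organ macroscopic branch and a diamond."""
    return ce.UHAFOntology(
        nodes=[
            {"name": "Heart", "kind": "organ"},
            {"name": "left ventricle", "kind": "region"},
            {"name": "Lung", "kind": "organ"},
            {"name": "muscle tissue", "kind": "tissue_type"},
            {"name": "T cell", "kind": "cell_type"},
            {"name": "CD4 T cell", "kind": "cell_type"},
            {"name": "CD8 T cell", "kind": "cell_type"},
            {"name": "Treg", "kind": "cell_type"},
            {"name": "CD4 Tcm", "kind": "cell_type"},
            {"name": "B cell", "kind": "cell_type"},
            {"name": "Dendritic cell", "kind": "cell_type"},
            {"name": "cDC1", "kind": "cell_type"},
            # diamond: X is-a CD4 T cell and is-a CD8 T cell
            {"name": "DP-like", "kind": "cell_type"},
        ],
        edges=[
            ("left ventricle", "Heart", "part_of"),
            ("muscle tissue", "Heart", "part_of"),
            ("CD4 T cell", "T cell", "is_a"),
            ("CD8 T cell", "T cell", "is_a"),
            ("Treg", "CD4 T cell", "is_a"),
            ("CD4 Tcm", "CD4 T cell", "is_a"),
            ("cDC1", "Dendritic cell", "is_a"),
            ("DP-like", "CD4 T cell", "is_a"),
            ("DP-like", "CD8 T cell", "is_a"),
            ("T cell", "left ventricle", "part_of"),
            ("B cell", "Lung", "part_of"),
        ],
        markers=[("T cell", "CD3D", "knowledge"), ("T cell", "CD3D", "data")],
        cl_map={"Treg": "regulatory T cell"},
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Default synthetic atlas at reduced size, shared across tests."""
    spec = ce.SyntheticAtlasSpec(seed=7, n_genes=80, n_cells_per_type=60)
    return ce.generate_atlas(spec)


@pytest.fixture(scope="session")
def small_table(small_bundle):
    return ce.assemble(small_bundle)


@pytest.fixture()
def five_cell_table():
    """The worked 5-cell example: (organ, CD3D) pairs with known answers."""
    genes = ["PTPRC", "CD3D"]
    values = np.array([[1.0, 0.7], [0.2, 0.9], [0.0, 0.1], [0.6, 0.5], [0.3, 0.0]])
    meta = [
        {"organ": "Heart", "cell_type": "T cell"},
        {"organ": "Lung", "cell_type": "T cell"},
        {"organ": "Heart", "cell_type": "B cell"},
        {"organ": "Heart", "cell_type": "T cell"},
        {"organ": "Heart", "cell_type": "B cell"},
    ]
    return ce.UnifiedTable(genes, values, meta)
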