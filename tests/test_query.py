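"""Logic-expression parsing and in-data cell sorting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cellensemble as ce
from cellensemble.query import And, Comparison, Not, Or

from conftest import oracle_cids, random_expression, random_table

WORKED = (
    "(organ==Heart) && (cell_type == T cell) && (PTPRC > 0.5) && "
    "((CD3D >= 0.5) || (CD3E >= 0.5))"
)


class TestParser:
    def test_worked_expression_tree(self):
        ast = ce.parse_expression(WORKED)
        assert ast == And(
            (
                Comparison("organ", "==", "Heart"),
                Comparison("cell_type", "==", "T cell"),
                Comparison("PTPRC", ">", "0.5"),
                Or((Comparison("CD3D", ">=", "0.5"), Comparison("CD3E", ">=", "0.5"))),
            )
        )

    def test_single_comparison(self):
        assert ce.parse_expression("PTPRC > 0.5") == Comparison("PTPRC", ">", "0.5")

    def test_precedence_not_over_and_over_or(self):
        ast = ce.parse_expression("A==x || B==y && !C==z")
        assert ast == Or(
            (
                Comparison("A", "==", "x"),
                And((Comparison("B", "==", "y"), Not(Comparison("C", "==", "z")))),
            )
        )

    def test_multiword_unquoted_value(self):
        ast = ce.parse_expression("cell_type == CD4 T cell && organ == Heart")
        assert ast.children[0] == Comparison("cell_type", "==", "CD4 T cell")

    @pytest.mark.parametrize(
        "bad",
        [
            "organ = = Heart",  # whitespace inside the operator token
            "organ == Heart &&",  # dangling operator
            "(organ == Heart",  # unbalanced parenthesis
            "organ ==",  # missing value
            "== Heart",  # missing column
            "organ == Heart ) ",  # stray close paren
            "",
            "   ",
            "!",
        ],
    )
    def test_parse_errors(self, bad):
        with pytest.raises(ce.ParseError):
            ce.parse_expression(bad)

    def test_parse_error_carries_position(self):
        with pytest.raises(ce.ParseError) as err:
            ce.parse_expression("organ == Heart && (x ==")
        assert err.value.position is not None

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_generated_asts(self, seed):
        rng = np.random.default_rng(seed)
        ast = random_expression(
            rng, ["G0", "G1"], {"organ": ["Heart", "Lung"], "cell_type": ["T cell"]}
        )
        assert ce.parse_expression(ce.unparse(ast)) == ast


class TestQueryCells:
    def test_empty_table(self):
        table = ce.UnifiedTable(["G0"])
        assert ce.query_cells(table, "G0 > 0") == []

    def test_five_cell_worked_example(self, five_cell_table):
        got = ce.query_cells(five_cell_table, "organ==Heart && CD3D>=0.5")
        assert got == [0, 3]

    def test_include_children_expands_subtree(self, toy_ontology):
        table = ce.UnifiedTable(
            ["G0"],
            np.zeros((3, 1)),
            [{"cell_type": "T cell"}, {"cell_type": "CD4 T cell"},
             {"cell_type": "B cell"}],
        )
        expanded = ce.query_cells(
            table, "cell_type==T cell", include_children=True, ontology=toy_ontology
        )
        exact = ce.query_cells(table, "cell_type==T cell")
        assert expanded == [0, 1] and exact == [0]

    def test_include_children_equals_union_of_descendant_labels(
        self, small_table, small_bundle
    ):
        ontology = small_bundle.ontology
        for node in ontology.nodes.values():
            if node.kind != "cell_type":
                continue
            expanded = ce.query_cells(
                small_table, f"cell_type=={node.name}", include_children=True,
                ontology=ontology,
            )
            union = sorted(
                set().union(
                    *(
                        ce.query_cells(small_table, f"cell_type=={label}")
                        for label in ontology.descendants(node.name, ("is_a",))
                    )
                )
            )
            assert expanded == union
            assert set(ce.query_cells(small_table, f"cell_type=={node.name}")) <= set(
                expanded
            )

    def test_include_children_requires_known_name(self, small_table, small_bundle):
        with pytest.raises(ce.NameLookupError):
            ce.query_cells(
                small_table, "cell_type==Martian cell", include_children=True,
                ontology=small_bundle.ontology,
            )

    def test_ordering_on_text_column_rejected(self, five_cell_table):
        with pytest.raises(ce.QueryError):
            ce.query_cells(five_cell_table, "donor_age > 30")

    def test_numeric_field_opt_in(self):
        table = ce.UnifiedTable(
            ["G0"], np.zeros((3, 1)),
            [{"donor_age": "25"}, {"donor_age": "60"}, {"donor_age": ""}],
        )
        got = ce.query_cells(table, "donor_age > 30", numeric_fields={"donor_age"})
        assert got == [1]

    def test_unknown_column(self, five_cell_table):
        with pytest.raises(ce.ColumnError):
            ce.query_cells(five_cell_table, "NOPE == 1")

    def test_de_morgan(self, five_cell_table):
        a, b = "organ==Heart", "CD3D>=0.5"
        not_and = ce.query_cells(five_cell_table, f"!({a} && {b})")
        or_nots = ce.query_cells(five_cell_table, f"!{a} || !{b}")
        both = ce.query_cells(five_cell_table, f"{a} && {b}")
        assert not_and == or_nots
        assert sorted(not_and + both) == five_cell_table.get_all_rows()

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            table, genes, meta_values = random_table(rng)
            expr = random_expression(rng, genes, meta_values)
            assert ce.query_cells(table, expr) == oracle_cids(table, expr, genes)

    def test_restricted_row_set(self, five_cell_table):
        got = ce.query_cells(five_cell_table, "organ==Heart", rows=[0, 1, 2])
        assert got == [0, 2]


class TestCrosstab:
    def test_counting_by_hand(self):
        table = ce.UnifiedTable(
            ["G0"], np.zeros((3, 1)),
            [{"organ": "Heart", "cell_type": "T cell"},
             {"organ": "Heart", "cell_type": "B cell"},
             {"organ": "Lung", "cell_type": "T cell"}],
        )
        out = ce.celltype_organ_crosstab(table)
        assert out.index.tolist() == ["Heart", "Lung"]
        assert out.columns.tolist() == ["B cell", "T cell"]
        assert out.to_numpy().tolist() == [[1, 1], [0, 1]]

    def test_empty_selection(self, five_cell_table):
        assert ce.celltype_organ_crosstab(five_cell_table, rows=[]).empty

    def test_single_cell(self, five_cell_table):
        out = ce.celltype_organ_crosstab(five_cell_table, rows=[0])
        assert out.to_numpy().sum() == 1

    def test_marginals_match_subset_sizes(self, small_table):
        out = ce.celltype_organ_crosstab(small_table)
        organs = small_table.metadata["organ"]
        for organ, count in organs.value_counts().items():
            assert out.loc[organ].sum() == count
        assert out.to_numpy().sum() == small_table.n_cells
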