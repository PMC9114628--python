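"""The logic-expression language for "in data" cell sorting.

Cells are selected from the unified table with combinatorial filters over
metadata fields and gene expression, the computational analogue of flow
cytometry sorting::

    (organ==Heart) && (cell_type == T cell) && (PTPRC > 0.5)
        && ((CD3D >= 0.5) || (CD3E >= 0.5))

Grammar (normative for this package): comparisons ``column op value`` with
operators ``==  !=  >  >=  <  <=``, combined with ``!`` (NOT), ``&&`` (AND)
and ``||`` (OR); precedence NOT > AND > OR, left-associative, parentheses
override. Whitespace around tokens is ignored; a comparison's value token
extends to the next logical operator or unbalanced ``)`` and is trimmed, so
unquoted multi-word values like ``T cell`` parse. String comparisons are
exact and case-sensitive; gene comparisons evaluate against the stored
normalized values.

With ``include_children`` an equality test on ``cell_type`` or ``organ``
matches any label in the ontology subtree below the named entity (is_a for
cell types; is_a plus part_of for organs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ColumnError, ParseError, QueryError
from .store import METADATA_FIELDS, UnifiedTable
from .uhaf import UHAFOntology

OPERATORS = ("==", "!=", ">=", "<=", ">", "<")
_ORDERING_OPS = (">", ">=", "<", "<=")
#: metadata fields whose equality tests expand under include_children,
#: with the edge types used for the subtree walk.
SUBTREE_FIELDS = {"cell_type": ("is_a",), "organ": ("is_a", "part_of")}


# -- AST ---------------------------------------------------------------------


@dataclass(frozen=True)
class Comparison:
    column: str
    op: str
    value: str


@dataclass(frozen=True)
class Not:
    child: "QueryExpression"


@dataclass(frozen=True)
class And:
    children: tuple["QueryExpression", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["QueryExpression", ...]


QueryExpression = Comparison | Not | And | Or


def unparse(expr: QueryExpression) -> str:
    """Canonical text form; ``parse_expression(unparse(e)) == e``."""
    if isinstance(expr, Comparison):
        return f"{expr.column} {expr.op} {expr.value}"
    if isinstance(expr, Not):
        return f"!({unparse(expr.child)})"
    if isinstance(expr, And):
        return " && ".join(f"({unparse(c)})" for c in expr.children)
    if isinstance(expr, Or):
        return " || ".join(f"({unparse(c)})" for c in expr.children)
    raise TypeError(f"not a query expression: {expr!r}")


# -- parser ------------------------------------------------------------------


class _Parser:
    """Recursive descent over the raw string (no separate tokenizer: value
    tokens are context-dependent)."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def _ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def _peek(self, offset: int = 0) -> str:
        i = self.pos + offset
        return self.text[i] if i < len(self.text) else ""

    def parse(self) -> QueryExpression:
        expr = self.parse_or()
        self._ws()
        if self.pos != len(self.text):
            raise ParseError(
                f"unexpected trailing input {self.text[self.pos:]!r}", self.pos
            )
        return expr

    def parse_or(self) -> QueryExpression:
        parts = [self.parse_and()]
        while True:
            self._ws()
            if self.text[self.pos : self.pos + 2] == "||":
                self.pos += 2
                parts.append(self.parse_and())
            else:
                break
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> QueryExpression:
        parts = [self.parse_not()]
        while True:
            self._ws()
            if self.text[self.pos : self.pos + 2] == "&&":
                self.pos += 2
                parts.append(self.parse_not())
            else:
                break
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_not(self) -> QueryExpression:
        self._ws()
        if self._peek() == "!" and self._peek(1) != "=":
            self.pos += 1
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> QueryExpression:
        self._ws()
        if self.pos >= len(self.text):
            raise ParseError("expected an expression", self.pos)
        if self._peek() == "(":
            self.pos += 1
            inner = self.parse_or()
            self._ws()
            if self._peek() != ")":
                raise ParseError("unbalanced parenthesis: expected ')'", self.pos)
            self.pos += 1
            return inner
        return self.parse_comparison()

    def parse_comparison(self) -> Comparison:
        start = self.pos
        # column runs up to the first operator character
        i = self.pos
        while i < len(self.text) and self.text[i] not in "<>!=&|()":
            i += 1
        if i >= len(self.text) or self.text[i] not in "<>!=":
            raise ParseError("expected a comparison operator", i)
        column = self.text[start:i].strip()
        if not column:
            raise ParseError("comparison is missing a column name", start)
        two = self.text[i : i + 2]
        if two in OPERATORS:
            op, i = two, i + 2
        elif self.text[i] in "<>":
            op, i = self.text[i], i + 1
        else:
            # a lone '=' or '!' (including the typeset "= =") is not a token
            raise ParseError(f"invalid operator at {self.text[i:i + 2]!r}", i)
        # value extends to the next logical operator or closing parenthesis
        j = i
        while j < len(self.text):
            if self.text[j] == ")" or self.text[j : j + 2] in ("&&", "||"):
                break
            j += 1
        value = self.text[i:j].strip()
        if not value:
            raise ParseError("comparison is missing a value", i)
        self.pos = j
        return Comparison(column, op, value)


def parse_expression(text: str | QueryExpression) -> QueryExpression:
    """Parse query text into its AST (idempotent on already-parsed input)."""
    if isinstance(text, (Comparison, Not, And, Or)):
        return text
    if not isinstance(text, str) or not text.strip():
        raise ParseError("empty query expression", 0)
    return _Parser(text).parse()


# -- evaluation --------------------------------------------------------------


def _eval(
    expr: QueryExpression,
    table: UnifiedTable,
    cids: np.ndarray,
    include_children: bool,
    ontology: UHAFOntology | None,
    numeric_fields: frozenset[str],
) -> np.ndarray:
    if isinstance(expr, Comparison):
        return _eval_comparison(
            expr, table, cids, include_children, ontology, numeric_fields
        )
    if isinstance(expr, Not):
        return ~_eval(expr.child, table, cids, include_children, ontology, numeric_fields)
    if isinstance(expr, (And, Or)):
        masks = [
            _eval(c, table, cids, include_children, ontology, numeric_fields)
            for c in expr.children
        ]
        combine = np.logical_and if isinstance(expr, And) else np.logical_or
        out = masks[0]
        for m in masks[1:]:
            out = combine(out, m)
        return out
    raise TypeError(f"not a query expression: {expr!r}")


def _eval_comparison(
    cmp: Comparison,
    table: UnifiedTable,
    cids: np.ndarray,
    include_children: bool,
    ontology: UHAFOntology | None,
    numeric_fields: frozenset[str],
) -> np.ndarray:
    col = cmp.column
    if col in METADATA_FIELDS:
        series = table.metadata[col].to_numpy()[cids]
        if col in numeric_fields and cmp.op in _ORDERING_OPS:
            left = pd.to_numeric(pd.Series(series), errors="coerce").to_numpy()
            right = _numeric_value(cmp)
            with np.errstate(invalid="ignore"):
                return _compare(left, cmp.op, right)
        if cmp.op in _ORDERING_OPS:
            raise QueryError(
                f"ordering operator {cmp.op!r} on text column {col!r}"
            )
        if include_children and col in SUBTREE_FIELDS:
            if ontology is None:
                raise QueryError("include_children requires an ontology")
            labels = ontology.descendants(cmp.value, SUBTREE_FIELDS[col])
            mask = np.isin(series, sorted(labels))
        else:
            mask = series == cmp.value
        return mask if cmp.op == "==" else ~mask
    if table.is_gene(col):
        values = table.column(col, cids)
        return _compare(values, cmp.op, _numeric_value(cmp))
    raise ColumnError(f"unknown column: {col!r}")


def _numeric_value(cmp: Comparison) -> float:
    try:
        return float(cmp.value)
    except ValueError:
        raise QueryError(
            f"comparison on {cmp.column!r} needs a numeric value, got {cmp.value!r}"
        ) from None


def _compare(left: np.ndarray, op: str, right: float) -> np.ndarray:
    if op == "==":
        return left == right
    if op == "!=":
        return left != right
    if op == ">":
        return left > right
    if op == ">=":
        return left >= right
    if op == "<":
        return left < right
    return left <= right


def query_cells(
    table: UnifiedTable,
    condition: str | QueryExpression,
    include_children: bool = False,
    ontology: UHAFOntology | None = None,
    rows: Iterable[int] | None = None,
    numeric_fields: Iterable[str] = (),
) -> list[int]:
    """Return the cids of all cells (within ``rows``) satisfying the condition.

    ``numeric_fields`` opts metadata columns (e.g. ``donor_age``) into
    numeric ordering comparisons; by default every metadata field is text and
    ordering operators on it are rejected.
    """
    expr = parse_expression(condition)
    cids = table._check_cids(rows)
    if cids.size == 0:
        return []
    mask = _eval(
        expr, table, cids, include_children, ontology, frozenset(numeric_fields)
    )
    return [int(c) for c in cids[mask]]


def celltype_organ_crosstab(
    table: UnifiedTable, rows: Iterable[int] | None = None
) -> pd.DataFrame:
    """Cross table of cell counts, rows = organs, columns = cell types.

    Labels are sorted lexicographically; marginals equal the per-label subset
    sizes. An empty selection yields an empty table.
    """
    cids = table._check_cids(rows)
    if cids.size == 0:
        return pd.DataFrame()
    organs = table.metadata["organ"].to_numpy()[cids]
    types = table.metadata["cell_type"].to_numpy()[cids]
    out = pd.crosstab(pd.Series(organs, name="organ"), pd.Series(types, name="cell_type"))
    return out.sort_index(axis=0).sort_index(axis=1)
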