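"""The unified hierarchical annotation framework (uHAF).

A typed, acyclic directed graph over two vocabularies: macroscopic entities
(system, organ, region, subregion) describing where a cell sits in the body,
and microscopic entities (tissue type, cell type) describing what it is.
Edges run child -> parent and are typed "is_a" (specialization between
same-kind microscopic entities, e.g. inhibitory neuron is-a neuron) or
"part_of" (containment, possibly across kinds, e.g. left ventricle part-of
heart). "connect_to" marker references tag microscopic nodes with their
characteristic genes. The ontology is the atlas's index: subtree expansion
drives ``include_children`` queries, the is-a hierarchy drives lenient label
evaluation, and standard labels are composed from its node names.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import FormatError, NameLookupError, OntologyError

MACROSCOPIC_KINDS = ("system", "organ", "region", "subregion")
MICROSCOPIC_KINDS = ("tissue_type", "cell_type")
NODE_KINDS = MACROSCOPIC_KINDS + MICROSCOPIC_KINDS
EDGE_TYPES = ("is_a", "part_of")

#: Label for clusters whose identity cannot be resolved.
UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class Node:
    id: str
    name: str
    kind: str


class UHAFOntology:
    """Validated annotation DAG with marker references and a curated CL map.

    Parameters mirror the on-disk JSON: ``nodes`` (id/name/kind records),
    ``edges`` (child/parent/type, child -> parent direction), ``markers``
    (node/gene/provenance) and ``cl_map`` (curated node name -> Cell Ontology
    preferred label, covering the manual step of the mapping).
    """

    def __init__(
        self,
        nodes: Iterable[Mapping | Node],
        edges: Iterable[Mapping | tuple] = (),
        markers: Iterable[Mapping | tuple] = (),
        cl_map: Mapping[str, str] | None = None,
    ):
        self.nodes: dict[str, Node] = {}
        for rec in nodes:
            node = rec if isinstance(rec, Node) else Node(
                str(rec.get("id", rec["name"])), str(rec["name"]), str(rec["kind"])
            )
            if node.kind not in NODE_KINDS:
                raise FormatError(f"unknown node kind: {node.kind!r}")
            if node.name in self.nodes:
                raise OntologyError(f"duplicate node name: {node.name!r}")
            self.nodes[node.name] = node

        # child -> ordered [(parent, type)]; order is file order (tie-break rule)
        self._parents: dict[str, list[tuple[str, str]]] = {n: [] for n in self.nodes}
        self._children: dict[str, list[tuple[str, str]]] = {n: [] for n in self.nodes}
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        for rec in edges:
            if isinstance(rec, Mapping):
                child, parent, etype = rec["child"], rec["parent"], rec["type"]
            else:
                child, parent, etype = rec
            if etype not in EDGE_TYPES:
                raise FormatError(f"unknown edge type: {etype!r}")
            for name in (child, parent):
                if name not in self.nodes:
                    raise OntologyError(f"edge references unknown node: {name!r}")
            if etype == "is_a":
                ck, pk = self.nodes[child].kind, self.nodes[parent].kind
                if ck != pk or ck not in MICROSCOPIC_KINDS:
                    raise OntologyError(
                        f"is_a must connect same-kind microscopic nodes: "
                        f"{child!r} ({ck}) -> {parent!r} ({pk})"
                    )
            self._parents[child].append((parent, etype))
            self._children[parent].append((child, etype))
            graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(graph):
            witness = " -> ".join(n for n, _ in nx.find_cycle(graph))
            raise OntologyError(f"ontology graph contains a cycle: {witness}")
        self._graph = graph

        # marker references: per microscopic node, de-duplicated by symbol
        self.marker_refs: dict[str, list[tuple[str, str]]] = {}
        for rec in markers:
            if isinstance(rec, Mapping):
                name, gene, tag = rec["node"], rec["gene"], rec.get("provenance", "")
            else:
                name, gene, tag = (list(rec) + [""])[:3]
            if name not in self.nodes:
                raise OntologyError(f"marker references unknown node: {name!r}")
            refs = self.marker_refs.setdefault(name, [])
            if gene not in {g for g, _ in refs}:
                refs.append((str(gene), str(tag)))

        self.cl_map: dict[str, str] = dict(cl_map or {})

    # -- lookups -------------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def kind(self, name: str) -> str:
        self._require(name)
        return self.nodes[name].kind

    def parents(self, name: str, edge_types: Sequence[str] = EDGE_TYPES):
        self._require(name)
        return [p for p, t in self._parents[name] if t in edge_types]

    def _require(self, name: str) -> None:
        if name not in self.nodes:
            raise NameLookupError(f"unknown ontology name: {name!r}")

    def descendants(
        self, name: str, edge_types: Sequence[str] = ("is_a",)
    ) -> set[str]:
        """The node plus everything reachable below it via the given edge types.

        Multiple paths (diamonds) contribute each node once.
        """
        self._require(name)
        seen = {name}
        frontier = deque([name])
        while frontier:
            current = frontier.popleft()
            for child, etype in self._children[current]:
                if etype in edge_types and child not in seen:
                    seen.add(child)
                    frontier.append(child)
        return seen

    def ancestors(self, name: str, edge_types: Sequence[str] = ("is_a",)) -> set[str]:
        """The node plus everything reachable above it via the given edge types."""
        self._require(name)
        seen = {name}
        frontier = deque([name])
        while frontier:
            current = frontier.popleft()
            for parent, etype in self._parents[current]:
                if etype in edge_types and parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen

    def validate_markers(self, symbol_table) -> list[tuple[str, str]]:
        """Flag marker genes not on the approved axis; returns (node, gene) pairs."""
        approved = set(symbol_table.approved)
        return [
            (node, gene)
            for node, refs in self.marker_refs.items()
            for gene, _ in refs
            if gene not in approved and symbol_table.alias_map.get(gene) is None
        ]


def load_ontology(path) -> UHAFOntology:
    """Load and validate an ontology from its JSON file."""
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid ontology JSON: {exc}") from exc
    if "nodes" not in payload:
        raise FormatError("ontology file has no 'nodes' record")
    return UHAFOntology(
        payload["nodes"],
        payload.get("edges", ()),
        payload.get("markers", ()),
        payload.get("cl_map", {}),
    )


def save_ontology(ontology: UHAFOntology, path) -> None:
    """Write the JSON form read back by :func:`load_ontology`."""
    payload = {
        "nodes": [vars(n) for n in ontology.nodes.values()],
        "edges": [
            {"child": child, "parent": parent, "type": etype}
            for child, entries in ontology._parents.items()
            for parent, etype in entries
        ],
        "markers": [
            {"node": node, "gene": gene, "provenance": tag}
            for node, refs in ontology.marker_refs.items()
            for gene, tag in refs
        ],
        "cl_map": ontology.cl_map,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def compose_uhaf_name(
    organ: str,
    tissue_type: str,
    cell_type: str,
    markers: str | Sequence[str] = "",
    ontology: UHAFOntology | None = None,
) -> str:
    """Compose the standard "organ-tissue_type-cell_type-markers" label.

    A cluster whose cell type cannot be resolved (empty, or absent from the
    ontology when one is supplied) is labeled "Unclassified".
    """
    if not isinstance(markers, str):
        markers = ",".join(markers)
    if not cell_type or (ontology is not None and cell_type not in ontology):
        return UNCLASSIFIED
    return f"{organ}-{tissue_type}-{cell_type}-{markers}"


def map_to_cell_ontology(
    ontology: UHAFOntology, uhaf_cell_type: str, cl_terms: Iterable[str]
) -> str:
    """Deterministically map a cell-type name to a Cell Ontology label.

    Cascade: (1) exact whole-string match against the CL preferred labels;
    (2) walk is_a parents upward (breadth-first, file order) until one matches
    exactly; (3) curated ``cl_map`` lookup; otherwise "none".
    """
    ontology._require(uhaf_cell_type)
    labels = set(cl_terms)
    if uhaf_cell_type in labels:
        return uhaf_cell_type
    frontier = deque([uhaf_cell_type])
    seen = {uhaf_cell_type}
    while frontier:
        current = frontier.popleft()
        for parent, etype in ontology._parents[current]:
            if etype != "is_a" or parent in seen:
                continue
            if parent in labels:
                return parent
            seen.add(parent)
            frontier.append(parent)
    return ontology.cl_map.get(uhaf_cell_type, "none")
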