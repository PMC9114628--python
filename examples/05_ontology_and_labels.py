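"""The annotation ontology: subtree queries, standard labels, CL mapping.

Builds a small typed DAG by hand, walks subtrees the way include_children
queries do, composes the standard four-part cell label, and maps cell-type
names onto Cell Ontology preferred labels by the exact-match -> parent-walk
-> curated-map cascade.
"""

import cellensemble as ce

ontology = ce.UHAFOntology(
    nodes=[
        {"name": "Heart", "kind": "organ"},
        {"name": "left ventricle", "kind": "region"},
        {"name": "muscle tissue", "kind": "tissue_type"},
        {"name": "T cell", "kind": "cell_type"},
        {"name": "CD4 T cell", "kind": "cell_type"},
        {"name": "CD8 T cell", "kind": "cell_type"},
        {"name": "Treg", "kind": "cell_type"},
        {"name": "Cardiomyocyte cell", "kind": "cell_type"},
    ],
    edges=[
        ("left ventricle", "Heart", "part_of"),
        ("muscle tissue", "Heart", "part_of"),
        ("CD4 T cell", "T cell", "is_a"),
        ("CD8 T cell", "T cell", "is_a"),
        ("Treg", "CD4 T cell", "is_a"),
        ("T cell", "left ventricle", "part_of"),
    ],
    markers=[("Cardiomyocyte cell", "TNNT2", "knowledge")],
    cl_map={"Treg": "regulatory T cell"},
)

print("is-a subtree below 'T cell':", sorted(ontology.descendants("T cell")))
print("everything inside 'Heart':",
      sorted(ontology.descendants("Heart", ("is_a", "part_of"))))

label = ce.compose_uhaf_name("Heart", "muscle tissue", "Cardiomyocyte cell", "TNNT2")
print(f"\nstandard label: {label}")
print("unresolvable cluster:",
      ce.compose_uhaf_name("Heart", "muscle tissue", "Mystery", ontology=ontology))

cl_labels = {"T cell", "regulatory T cell"}
for name in ("T cell", "CD4 T cell", "Treg", "Cardiomyocyte cell"):
    print(f"CL mapping of {name!r}: "
          f"{ce.map_to_cell_ontology(ontology, name, cl_labels)!r}")
# CD4 T cell falls back to its is-a parent; Treg hits the exact CL label;
# the cardiomyocyte matches nothing and maps to 'none'
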