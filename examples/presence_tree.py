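"""Map three proteins' presence onto the taxonomy as a pie-annotated tree.

Organism presence sets are planted so that several protein combinations
occur. Each organism gets a combination code (bitmask over the protein
order), and every tree node accumulates the per-code organism counts of its
subtree — the numbers behind each node's pie chart. Pie slice angles are
count fractions; pie area is proportional to the organism count.
"""

import io
import tempfile
from pathlib import Path

from taxoprofile import fixtures, load_taxonomy
from taxoprofile.tree import TreeStyle, annotate_tree, combo_label, render_tree

spec = fixtures.PresenceSpec(
    clades=[
        fixtures.CladeSpec("Primobacteria", "Bacteria", n_species=4),
        fixtures.CladeSpec("Secundomycota", "Eukaryota", n_species=3),
    ],
    proteins={"p": {}},
)
db = load_taxonomy(*map(io.StringIO, fixtures.make_taxonomy(spec)))
species = sorted(t for t in db if db.rank(t) == "species")

presence = {
    "NAMPT-like": set(species[:4]),
    "NAPRT-like": set(species[2:6]),
    "QPRT-like": set(species[5:]),
}
tree = annotate_tree(db, presence)

print(f"{len(tree.nodes)} tree nodes, {tree.root.total_organisms} organisms")
print("combination counts at selected nodes:")
for node in tree.walk():
    if node.rank in ("no rank", "superkingdom", "phylum"):
        labels = {
            combo_label(code, tree.proteins): count
            for code, count in sorted(node.counts.items())
        }
        print(f"  {node.scientific_name:<16} total={node.total_organisms:2d}  {labels}")

with tempfile.TemporaryDirectory() as tmp:
    colors = ("#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
              "#ffff33", "#a65628")
    render_tree(
        tree, TreeStyle(colors=colors),
        image_path=Path(tmp) / "tree.svg",
        newick_path=Path(tmp) / "tree.nwk",
        counts_path=Path(tmp) / "tree_counts.tsv",
    )
    print("\nNewick:", (Path(tmp) / "tree.nwk").read_text().strip())
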