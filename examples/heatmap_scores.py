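"""Build, cluster, and render the organism x protein significance heatmap.

Every cell is floor(-log10 e-value) of the organism's best hit for the
protein, capped at 200, with 0 meaning no accepted hit. Rows and columns
are ordered by centroid-linkage hierarchical clustering, so organisms and
proteins with similar presence patterns end up adjacent. The rendered HTML
is self-contained: a grayscale relative view, a black/white absolute view
with an e-value-exponent slider (default threshold 1e-30), and an
alphabetical column toggle.
"""

import io
import tempfile
from pathlib import Path

from taxoprofile import fixtures, load_taxonomy, parse_blast_xml
from taxoprofile.combine import combine_protein
from taxoprofile.heatmap import (
    HeatmapConfig, build_score_matrix, cluster_axes, render_heatmap,
)

spec = fixtures.small_spec(seed=42)
db = load_taxonomy(*map(io.StringIO, fixtures.make_taxonomy(spec)))

combined = []
for protein in spec.proteins:
    xml = fixtures.make_blast_results(spec, protein, "seed1")
    table = parse_blast_xml(io.BytesIO(xml.encode()), protein)
    combined.append(combine_protein([table], db))

species = sorted(t for t in db if db.rank(t) == "species")
config = HeatmapConfig(organisms=tuple(species))
matrix = build_score_matrix(combined, config, db)
print("score matrix (0 = absent, 200 = capped):")
print(matrix.to_dataframe())

row_order, col_order, _, _ = cluster_axes(matrix, config.linkage)
print("\nclustered row order:", [matrix.names[i] for i in row_order])
print("clustered column order:", [matrix.proteins[j] for j in col_order])

with tempfile.TemporaryDirectory() as tmp:
    html = render_heatmap(matrix, (row_order, col_order), config,
                          Path(tmp) / "heatmap.html")
    print(f"\nrendered self-contained heatmap: {len(html)} characters of HTML")
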