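"""Detect cross-hits between two similar query proteins.

A cross-hit is a subject accession returned for two different query
proteins — the signature of paralog confusion. Here one shared accession is
planted between protA (at e-value 1e-60) and protB (at 1e-45); the matrix
entry is the more significant of the two, and a value of 0 means the
protein pair shares no hits. The e-value cutoff for both proteins should be
set more stringent than any cross-hit entry.
"""

import io

from taxoprofile import fixtures, parse_blast_xml
from taxoprofile.qc_filter import cross_hit_matrix

spec = fixtures.small_spec(seed=42)
spec.cross_hit = ("protA", "protB")

tables = {
    protein: [
        parse_blast_xml(
            io.BytesIO(fixtures.make_blast_results(spec, protein, "seed1").encode()),
            protein,
        )
    ]
    for protein in spec.proteins
}
matrix = cross_hit_matrix(tables)
print(matrix.to_dataframe())
print()
entry = matrix.values[0, 1]
print(f"protA/protB share a hit at e-value {entry:g}; any accepted cutoff")
print("should therefore be stricter than that, e.g. 1e-70 for both proteins.")
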