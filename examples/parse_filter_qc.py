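"""Parse one BLAST XML2 result, inspect QC summaries, apply cutoffs.

The synthetic query plants 40 hits with a bimodal subject-length mixture
(modes near 400 aa and 585 aa) and e-values log-uniform between 1e-120 and
1e-10, so both QC views have structure: the length histogram shows two
peaks, and the coverage profile spreads hits over the six e-value
intervals. The default cutoffs (e-value 1e-30, length 50 aa) then remove
the weakest hits.
"""

import io

from taxoprofile import fixtures, parse_blast_xml
from taxoprofile.qc_filter import (
    Limits, apply_limits, coverage_profile, length_histogram,
)

spec = fixtures.PresenceSpec(
    clades=[fixtures.CladeSpec("Demophyta", "Bacteria", n_species=40)],
    proteins={
        "demo": {
            "Demophyta": fixtures.PresenceRule(
                fraction=1.0,
                evalue_range=(1e-120, 1e-10),
                length_modes=((400.0, 15.0, 0.5), (585.0, 10.0, 0.5)),
            )
        }
    },
    seed=11,
)
xml = fixtures.make_blast_results(spec, "demo", "seed1")
table = parse_blast_xml(io.BytesIO(xml.encode()), "demo")
print(f"parsed {len(table)} hits for seed of length {table.seed_length} aa")

edges, counts = length_histogram([table], bin_width=50)
print("length histogram (bin start: count):")
for start, count in zip(edges[:-1], counts):
    if count:
        print(f"  {start:4d} aa: {'#' * count} ({count})")

profile = coverage_profile(table)
print("hits per e-value interval (least to most significant):",
      profile.counts)

filtered = apply_limits(table, Limits())
meta = filtered.metadata
print(
    f"default cutoffs kept {meta['kept']}/{meta['parsed']} hits "
    f"({meta['removed_by_evalue']} failed e-value <= {meta['evalue_cutoff']:g}, "
    f"{meta['removed_by_length']} shorter than {meta['min_length']} aa)"
)
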