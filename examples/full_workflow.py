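"""Run the complete workflow on a synthetic workspace.

Builds a miniature taxonomy (two superkingdoms, five species) plus BLAST
XML2 result files with planted presence, then runs every pipeline stage:
parse, QC, filter, combine, heatmap, tree. The printed report shows the
filtering arithmetic per seed query and the unique-organism counts per
protein — on this fixture protA is planted in all five species, protB only
in the bacterial clade (3) and protC only in the eukaryotic clade (2).
"""

import tempfile
from pathlib import Path

from taxoprofile import fixtures
from taxoprofile.workspace import Workspace, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp) / "workspace"
    spec = fixtures.small_spec(seed=42)
    fixtures.write_workspace_fixture(spec, root)
    report = run_pipeline(Workspace(root=root))
    print(report.to_text())
    print()
    print("outputs under the workspace root:")
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.suffix in (".html", ".csv", ".nwk", ".svg"):
            print(" ", path.relative_to(root))
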