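# taxoprofile

Phylogenetic profiling of protein presence-absence across the taxonomy.

`taxoprofile` is for researchers who want a large-scale overview of which
organisms carry which proteins — for example, to trace gains and losses of
pathway enzymes across kingdoms. It takes protein homology-search results
(BLASTp output in XML2 format, one file per seed sequence), filters them with
user-set e-value and minimum-length cutoffs, checks for cross-hits between
similar query proteins, combines the surviving hits per protein, and renders
presence-absence two ways:

* **taxonomy trees** whose topology follows the reference taxonomy (never the
  hit alignments), with a pie chart per node: slices are the combinations of
  up to three proteins present in the subtree (7 categories at 3 proteins),
  pie area is proportional to the number of organisms;
* an **interactive HTML heatmap** of organisms × proteins, where each cell is
  the integer significance score of the organism's best hit,

  score(e) = min(⌊−log10 e⌋, 200),  score(0) = 200,  score = 0 ⇔ no hit,

  with both axes ordered by hierarchical clustering (centroid linkage by
  default), a grayscale *relative* view, a black/white *absolute* view with an
  e-value-exponent slider, and per-cell best-e-value tooltips.

Presence is deliberately simple: an organism (species-collapsed taxid) is
"present" for a protein when at least one hit survives the cutoffs. No
orthology inference is attempted.

## Quick start

A workspace is a directory with four working folders (`blastresults/`,
`fastas/`, `resulttables/`, `combinedtables/`) and five plain-text config
files (`proteinlist.txt`, `limits.txt`, `heatmap_config.txt`,
`tree_config.txt`, `tree_to_prune.txt`). The CLI mirrors the pipeline stages:

```sh
taxoprofile init --root myws          # folder structure + config templates
# ... place seed FASTAs in fastas/, BLAST XML2 in blastresults/,
#     taxonomy dump (nodes.dmp/names.dmp) in taxonomy/ ...
taxoprofile run-all --root myws       # parse, qc, filter, combine, heatmap, tree
taxoprofile blast2fasta --root myws   # hit sequences as one FASTA
```

`taxoprofile fixtures --root demo` writes a fully synthetic, immediately
runnable workspace for experimentation. Every stage is equally usable from
Python — see `examples/` for one narrative script per capability.

## Worked example

`python examples/full_workflow.py` builds a synthetic workspace (two
superkingdoms, five species; protA planted everywhere, protB only in the
bacterial clade, protC only in the eukaryotic clade) and runs every stage:

```
stages run: parse, qc, filter, combine, heatmap, tree
  protA/seed1: parsed=5 kept=5 removed_by_evalue=0 removed_by_length=0
  protB/seed1: parsed=3 kept=3 removed_by_evalue=0 removed_by_length=0
  protC/seed1: parsed=2 kept=2 removed_by_evalue=0 removed_by_length=0
  protA: 5 unique organism(s)
  protB: 3 unique organism(s)
  protC: 2 unique organism(s)
  overall: 5 unique organism(s)
```

Per seed query, `parsed = kept + removed_by_evalue + removed_by_length` is the
filtering arithmetic at the default cutoffs (e-value ≤ 1e-30, subject length
≥ 50 aa); the organism lines count species-collapsed taxids with at least one
surviving hit, and `overall` is their union across proteins. The run leaves
`heatmap.html`, `matrix.csv` (cross-hit matrix, 0 = no cross-hit), per-protein
and combined trees (`.svg`, `.nwk`, per-node count `.tsv`) and QC plots in the
workspace.

`python examples/heatmap_scores.py` prints the score matrix behind the
heatmap, e.g. an organism whose best protA hit has e-value 2.1e-67 scores 66,
and an organism without any protC hit scores 0.

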