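# Methods

## Model and procedure

`taxoprofile` treats protein presence as a binary property of an organism
derived from sequence-similarity search: an organism is *present* for a
protein when at least one hit for any of that protein's seed sequences
survives the quality cutoffs. The pipeline is:

1. **Parse.** Each single-query BLASTp XML2 document becomes a result table
   of HSP-level hit records (accession, taxid, e-value, bit score, 1-based
   inclusive query coordinates, subject length, aligned subject segment),
   ordered by ascending e-value with ties broken by descending bit score and
   then accession. Coordinates stay in BLAST's convention end-to-end; an
   e-value of exactly 0.0 is preserved as 0.0 — capping to a finite score
   happens only in the heatmap. Hits without a taxid are skipped and counted.
2. **QC.** Two visual aids inform cutoff choice: a subject-length histogram
   (fixed-width bins from 0 to the longest hit), and a coverage profile that
   groups each hit's aligned query span into six e-value intervals of
   increasing significance. The cross-hit matrix reports, per protein pair,
   the best e-value of any shared hit accession; 0 means none. Cross-hit
   checking runs on parsed (pre-filter) tables so the user can tighten
   cutoffs in response.
3. **Filter.** A hit is kept when `evalue <= cutoff` **and**
   `subject_length >= min_length`, both inclusive — the conservative reading
   of "cutoff". The length tested is the full subject sequence length, not
   the aligned span, because the cutoff screens out hits that are short
   relative to the seed protein. Defaults: 1e-30 and 50 aa, overridable per
   protein in `limits.txt`.
4. **Combine.** Per protein, the filtered tables of all seeds are pooled.
   Identical accessions hit by different seeds are deduplicated *before*
   counting (one accession = one record, keeping the lowest-e-value
   occurrence). Organism identity is the species-collapsed taxid — the
   nearest ancestor-or-self of rank `species`, so strain-level hits never
   inflate organism counts (raw-taxid identity is available via
   `collapse_species=False`). Non-redundant organism listings are written per
   protein and overall.
5. **Heatmap.** Cell value for (organism, protein) is
   `floor(-log10 e + 1e-9)` of the organism's best e-value, clamped to
   [0, 200], with e = 0 mapping to the cap 200 and "no hit" to 0. The 1e-9
   epsilon absorbs binary floating-point representation error of decimal
   e-values so exact powers of ten score exactly their exponent; it does not
   affect monotonicity. Rows and columns are clustered hierarchically
   (scipy) with Euclidean distances on the score vectors — centroid linkage
   requires raw Euclidean input, and the same metric is used for all seven
   supported linkages for comparability. The HTML output embeds the full
   matrix as JSON, so the document's semantics (absolute-view thresholding,
   orderings, tooltips) are testable without a browser.
6. **Tree.** The tree is the union of reference-taxonomy lineages of all
   present organisms; topology is never inferred from the hits. With p ≤ 3
   proteins, each organism gets a combination code, a bitmask over the
   configured protein order (7 non-empty subsets at p = 3, the ceiling at
   which pie-chart color coding stays readable). Node counts aggregate
   bottom-up, so every internal node's counts equal the sum over its
   children plus its own organism if it is one. Pruning collapses named taxa
   into terminal nodes (counts retained) and can restrict rendering to one
   subtree, e.g. a single superkingdom.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| e-value cutoff | 1e-30 | max e-value of an accepted hit (inclusive) |
| min length | 50 aa | min subject sequence length (inclusive) |
| score cap | 200 | upper bound of the −log10 significance score |
| linkage | centroid | clustering linkage; any of single/complete/average/weighted/centroid/median/ward |
| slider default | 30 | initial absolute-view threshold exponent (1e-30) |
| coverage edges | 1e-3 … 1e-180 | see below |
| pie radius | ∝ √organisms, clamped [4, 40] display units | area ∝ organism count |
| search defaults | BLOSUM62, word size 6, gap open 11, gap extend 1, e-value 1e-3, 20 000 targets | recorded by the (never-tested) blastp wrapper |

Coverage intervals: the six intervals are log-uniform in the exponent
between the search-time e-value ceiling (1e-3) and a floor of 1e-180, i.e.
bounds at exponents −3, −32.5, −62, −91.5, −121, −150.5, −180. Hits more
significant than the floor (including e-value 0) land in the most
significant interval; hits above the ceiling in the least significant one.
The edges are overridable.

## Numerical and design choices

* **Integer score:** `floor` rather than `round`, so a score of k guarantees
  e ≤ 10^−k; boundary unit-tested.
* **Clustering determinism:** equal-distance merges are resolved by scipy's
  deterministic merge order; leaf order is canonicalised by rotating every
  merge so the subtree containing the smaller original index goes left.
  Identical input therefore always yields identical output across runs and
  platforms. Shuffling input rows preserves the dendrogram topology; the
  emitted leaf *order* is canonical with respect to input indices, not
  content.
* **Cross-hit sentinel:** 0 means "no cross-hit", so a true e-value of 0.0
  is floored to 1e-200 before entering the matrix (noted in the matrix.csv
  header).
* **Ambiguous scientific names** resolve to the lowest taxid (loader warns).
  **Unknown taxids** are errors in the taxonomy store itself but are
  soft-handled one layer up: organism listings name them
  `unknown taxid <n>`, heatmap selections get an all-zero row, tree
  organisms attach directly under the root — each with a warning. Merged or
  deleted taxid resolution is out of scope.
* **TSV dialect:** tab-separated, UTF-8, mandatory header, shortest exact
  float representation — round trips are byte-lossless. The aligned-sequence
  column is written only when at least one record carries a sequence.
* **blast2fasta** emits the gap-stripped *aligned* subject segments, since
  XML2 carries only those, deduplicated per accession by best e-value.
* **Workspace:** initialisation is idempotent; the pipeline is re-entrant by
  stage so cutoffs can be iterated without re-parsing; every threshold
  decision and soft-skip is logged to `run.log`.
* **Rendering:** tree graphics are drawn with matplotlib (wedge patches on a
  rectangular tree layout); the heatmap is a single self-contained HTML file
  generated from a string template. SVG output uses a fixed hash salt and no
  date metadata so reruns are byte-identical.

## The synthetic-data generator

`taxoprofile.fixtures` plants a known presence-absence structure and emits
the exact file formats the pipeline consumes: taxonomy dumps in the
pipe-and-tab dialect (two superkingdoms, phylum/genus/species ranks,
optional strain nodes) and single-query BLAST XML2 documents modelled on
genuine BLASTP 2.17.0 output. Per clade and protein, a presence fraction
decides which species carry the protein; e-values are drawn log-uniformly
within a configurable range (so any coverage interval can be populated),
subject lengths from a normal mixture (so bimodal length histograms can be
planted), and an optional shared accession exercises the cross-hit path.
The presence draw depends only on (seed, protein, clade), so planted truth
is recoverable independently of how many seeds are queried; a fixed seed
makes every emitted byte reproducible.

What the generator does **not** emulate: real sequence evolution (hit
sequences are random amino-acid strings), multi-HSP hits, multi-species
subject records, paralogy beyond the single planted cross-hit, and database
bias. Passing tests therefore demonstrate that the bookkeeping —
parsing, filtering arithmetic, organism collapsing, combination coding,
clustering, rendering — is correct on well-formed inputs, not that the
cutoffs are biologically optimal for any particular protein family.

Test and acceptance problem sizes are kept small by design (tens of
organisms, hundreds of hits); the known-truth recovery check uses 10 clades
× 5 species × 3 proteins, and the clustering oracle 6×4 matrices, where a
from-first-principles agglomeration is still affordable.

## Known limitations

* Presence is "≥ 1 surviving hit": no reciprocal-best-hit or orthology
  logic, exactly as intended for a coverage overview.
* Multi-taxid (multispecies) subject records use the first taxid only.
* The remote/local BLASTp wrapper is an interface with validated inputs and
  documented defaults; it is exercised only when a search backend is
  actually available and is never run by the test suite.
* The tree is limited to three proteins per figure; more proteins belong in
  the heatmap, which is the complementary view.
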