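"""Organism × protein significance matrix and the interactive HTML heatmap.

Each cell holds an integer significance score derived from the best hit's
e-value: ``floor(-log10 e)`` capped at 200, with 0 meaning "no accepted hit".
Both axes are ordered by hierarchical clustering (centroid linkage by
default, Euclidean distances on the score rows/columns). The rendered
heatmap is one self-contained HTML file whose embedded JSON payload carries
the full matrix, so its semantics can be checked without a browser.
"""

from __future__ import annotations

import json
import logging
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .combine import CombinedTable
from .qc_filter import ConfigurationError
from .taxonomy import TaxonomyDB

logger = logging.getLogger(__name__)

__all__ = [
    "SCORE_CAP",
    "significance_score",
    "HeatmapConfig",
    "ScoreMatrix",
    "build_score_matrix",
    "cluster_axes",
    "render_heatmap",
]

SCORE_CAP = 200
VALID_LINKAGES = ("single", "complete", "average", "weighted", "centroid",
                  "median", "ward")


def significance_score(evalue: float) -> int:
    """Integer significance of a hit: ``floor(-log10 evalue)`` capped at 200.

    An e-value of exactly 0 maps to the cap; e-values >= 1 map to 0. The tiny
    epsilon added before flooring absorbs the binary representation error of
    decimal e-values so that exact powers of ten score exactly their exponent.
    """
    if evalue < 0:
        raise ValueError(f"negative e-value {evalue}")
    if evalue == 0:
        return SCORE_CAP
    score = math.floor(-math.log10(evalue) + 1e-9)
    return max(0, min(SCORE_CAP, score))


@dataclass(frozen=True)
class HeatmapConfig:
    """User-facing heatmap settings (heatmap_config.txt).

    organisms: taxids or scientific names selecting the rows; empty means
        "use every organism with at least one combined hit".
    linkage: hierarchical-clustering linkage method, centroid by default.
    color: dark endpoint of the relative-view ramp (white = score 0).
    slider_default: initial absolute-view threshold exponent.
    """

    organisms: tuple = ()
    linkage: str = "centroid"
    color: str = "#000000"
    slider_default: int = 30

    def __post_init__(self):
        if self.linkage not in VALID_LINKAGES:
            raise ConfigurationError(
                f"unknown linkage {self.linkage!r}; valid: {', '.join(VALID_LINKAGES)}"
            )

    @classmethod
    def from_file(cls, source: str | Path | IO[str]) -> "HeatmapConfig":
        """Parse ``key = value`` lines; unknown keys are errors."""
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            label = str(source)
        else:
            text = source.read()
            label = getattr(source, "name", "<stream>")
        kwargs: dict = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{label}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "organisms":
                items = [v.strip() for v in value.split(",") if v.strip()]
                kwargs["organisms"] = tuple(
                    int(v) if v.isdigit() else v for v in items
                )
            elif key == "linkage":
                kwargs["linkage"] = value
            elif key in ("color", "colors"):
                kwargs["color"] = value
            elif key == "slider_default":
                try:
                    kwargs["slider_default"] = int(value)
                except ValueError:
                    raise ConfigurationError(
                        f"{label}:{lineno}: slider_default must be an integer"
                    ) from None
            else:
                raise ConfigurationError(f"{label}:{lineno}: unknown key {key!r}")
        return cls(**kwargs)


@dataclass
class ScoreMatrix:
    """Integer significance scores per (organism, protein), 0 = absent."""

    taxids: list[int]
    names: list[str]
    proteins: list[str]
    scores: np.ndarray  # int array, shape (organisms, proteins)
    evalues: np.ndarray  # float array, NaN where absent (tooltip payload)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.names, columns=self.proteins)

    def write_tsv(self, sink: str | Path | IO[str]) -> None:
        df = self.to_dataframe().copy()
        df.insert(0, "taxid", self.taxids)
        df.index.name = "organism"
        df.to_csv(sink, sep="\t", lineterminator="\n")


def build_score_matrix(
    combined: Sequence[CombinedTable],
    config: HeatmapConfig,
    db: TaxonomyDB,
) -> ScoreMatrix:
    """Score the selected organisms against every combined protein.

    Selection entries may be taxids or scientific names; strain-level
    selections are collapsed to their species so they line up with the
    combined tables' organisms. Entries that resolve nowhere produce a
    warning and an all-zero row rather than an error.
    """
    if not config.organisms:
        raise ConfigurationError("organism selection is empty")
    taxids: list[int] = []
    names: list[str] = []
    for entry in config.organisms:
        if isinstance(entry, int):
            taxid = entry
        else:
            resolved = db.taxid_of_name(str(entry))
            if resolved is None:
                logger.warning("organism %r not in taxonomy; all-zero row", entry)
                taxids.append(0)
                names.append(str(entry))
                continue
            taxid = resolved
        if taxid in db:
            taxid = db.species_of(taxid)
            names.append(db.name(taxid))
        else:
            logger.warning("taxid %d not in taxonomy; all-zero row", taxid)
            names.append(f"unknown taxid {taxid}")
        taxids.append(taxid)

    proteins = [t.protein for t in combined]
    scores = np.zeros((len(taxids), len(proteins)), dtype=int)
    evalues = np.full((len(taxids), len(proteins)), np.nan)
    for j, table in enumerate(combined):
        for i, taxid in enumerate(taxids):
            if taxid and taxid in table.best_by_organism:
                ev = table.best_evalue(taxid)
                scores[i, j] = significance_score(ev)
                evalues[i, j] = ev
    return ScoreMatrix(
        taxids=taxids, names=names, proteins=proteins,
        scores=scores, evalues=evalues,
    )


# -- clustering ------------------------------------------------------------

def _canonical_leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Leaf order with each merge rotated to put the smaller-index subtree left."""
    if n == 1:
        return [0]
    children: dict[int, tuple[int, int]] = {}
    min_leaf = list(range(n))
    for k in range(Z.shape[0]):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        left, right = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        children[n + k] = (left, right)
        min_leaf.append(min(min_leaf[a], min_leaf[b]))
    order: list[int] = []
    stack = [n + Z.shape[0] - 1]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            left, right = children[node]
            stack.append(right)
            stack.append(left)
    return order


def cluster_axes(
    matrix: ScoreMatrix, linkage: str = "centroid"
) -> tuple[list[int], list[int], np.ndarray | None, np.ndarray | None]:
    """Cluster rows and columns; returns (row_order, col_order, row_Z, col_Z).

    Distances are Euclidean on the integer score vectors (centroid/median
    linkage require raw Euclidean input). Axes with fewer than two entries
    pass through in input order with no dendrogram. Leaf orders are
    canonicalised (smaller-index subtree left) so results are reproducible
    across runs and platforms.
    """
    if linkage not in VALID_LINKAGES:
        raise ConfigurationError(
            f"unknown linkage {linkage!r}; valid: {', '.join(VALID_LINKAGES)}"
        )
    data = matrix.scores.astype(float)
    n_rows, n_cols = data.shape
    import warnings

    with warnings.catch_warnings():
        # the input is always an observation matrix, never a precomputed
        # distance matrix, so scipy's square-matrix heuristic is moot
        warnings.simplefilter("ignore", sch.ClusterWarning)
        if n_rows >= 2:
            row_Z = sch.linkage(data, method=linkage)
            row_order = _canonical_leaf_order(row_Z, n_rows)
        else:
            row_Z, row_order = None, list(range(n_rows))
        if n_cols >= 2:
            col_Z = sch.linkage(data.T, method=linkage)
            col_order = _canonical_leaf_order(col_Z, n_cols)
        else:
            col_Z, col_order = None, list(range(n_cols))
    return row_order, col_order, row_Z, col_Z


# -- HTML rendering --------------------------------------------------------

_HTML_TEMPLATE = string.Template("""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>$title</title>
<style>
body { font-family: sans-serif; margin: 1em; }
table.heatmap { border-collapse: collapse; }
table.heatmap td.cell { width: 18px; height: 18px; border: 1px solid #ddd; }
table.heatmap th.colhead { writing-mode: vertical-rl; font-size: 11px;
  font-weight: normal; padding: 2px; }
table.heatmap th.rowhead { text-align: right; font-size: 11px;
  font-weight: normal; padding-right: 6px; white-space: nowrap; }
#controls { margin-bottom: 1em; }
#controls label { margin-right: 1.5em; }
</style>
</head>
<body>
<h1>$title</h1>
<div id="controls">
  <label><input type="radio" name="view" value="relative" checked>
    relative (grayscale)</label>
  <label><input type="radio" name="view" value="absolute">
    absolute (black/white)</label>
  <label><input type="checkbox" id="alpha"> alphabetical proteins</label>
  <label>e-value exponent threshold:
    <input type="range" id="slider" min="1" max="200" value="$slider_default"
           disabled>
    1e-<span id="sliderval">$slider_default</span></label>
</div>
<div id="heatmap"></div>
<script id="heatmap-data" type="application/json">
$payload
</script>
<script>
const data = JSON.parse(document.getElementById("heatmap-data").textContent);

function hexToRgb(hex) {
  const m = /^#?([0-9a-f]{2})([0-9a-f]{2})([0-9a-f]{2})$$/i.exec(hex);
  return m ? [parseInt(m[1], 16), parseInt(m[2], 16), parseInt(m[3], 16)]
           : [0, 0, 0];
}
const dark = hexToRgb(data.color);

function cellColor(score, view, threshold) {
  if (view === "absolute") {
    return score >= threshold ? "rgb(0,0,0)" : "rgb(255,255,255)";
  }
  const f = score / data.score_cap;
  const c = dark.map((d) => Math.round(255 + (d - 255) * f));
  return "rgb(" + c.join(",") + ")";
}

function render() {
  const view = document.querySelector('input[name="view"]:checked').value;
  const alpha = document.getElementById("alpha").checked;
  const threshold = parseInt(document.getElementById("slider").value, 10);
  document.getElementById("slider").disabled = view !== "absolute";
  document.getElementById("sliderval").textContent = threshold;
  const colOrder = alpha ? data.alpha_col_order : data.col_order;
  let html = '<table class="heatmap"><tr><th></th>';
  for (const j of colOrder) {
    html += '<th class="colhead">' + data.proteins[j] + "</th>";
  }
  html += "</tr>";
  for (const i of data.row_order) {
    html += '<tr><th class="rowhead">' + data.organisms[i] + "</th>";
    for (const j of colOrder) {
      const score = data.scores[i][j];
      const ev = data.evalues[i][j];
      const tip = data.organisms[i] + " / " + data.proteins[j] +
        (ev === null ? ": no hit" : ": best e-value " + ev + " (score " + score + ")");
      html += '<td class="cell" style="background:' +
        cellColor(score, view, threshold) + '" title="' + tip + '"></td>';
    }
    html += "</tr>";
  }
  html += "</table>";
  document.getElementById("heatmap").innerHTML = html;
}

for (const el of document.querySelectorAll("#controls input")) {
  el.addEventListener("input", render);
}
render();
</script>
</body>
</html>
""")


def render_heatmap(
    matrix: ScoreMatrix,
    orders: tuple[list[int], list[int]] | None,
    config: HeatmapConfig,
    sink: str | Path | IO[str],
    title: str = "Protein presence heatmap",
) -> str:
    """Write the self-contained interactive heatmap; returns the HTML text.

    The matrix travels inside the document as a JSON payload (scores, best
    e-values, both column orders, the row order) which the embedded script
    renders client-side: grayscale relative view, thresholded absolute view
    with the e-value slider (enabled only there), a clustered/alphabetical
    protein toggle, and per-cell best-e-value tooltips.
    """
    if orders is None:
        row_order = list(range(len(matrix.names)))
        col_order = list(range(len(matrix.proteins)))
    else:
        row_order, col_order = orders
    if sorted(row_order) != list(range(len(matrix.names))) or sorted(
        col_order
    ) != list(range(len(matrix.proteins))):
        raise ValueError("orders do not match matrix shape")
    alpha_col_order = sorted(
        range(len(matrix.proteins)), key=lambda j: matrix.proteins[j].lower()
    )
    payload = {
        "organisms": matrix.names,
        "taxids": matrix.taxids,
        "proteins": matrix.proteins,
        "scores": matrix.scores.tolist(),
        "evalues": [
            [None if math.isnan(ev) else repr(float(ev)) for ev in row]
            for row in matrix.evalues
        ],
        "row_order": list(map(int, row_order)),
        "col_order": list(map(int, col_order)),
        "alpha_col_order": alpha_col_order,
        "score_cap": SCORE_CAP,
        "color": config.color,
        "slider_default": config.slider_default,
        "linkage": config.linkage,
    }
    html = _HTML_TEMPLATE.substitute(
        title=title,
        payload=json.dumps(payload, indent=1, sort_keys=True),
        slider_default=config.slider_default,
    )
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(html)
    else:
        sink.write(html)
    return html


def extract_payload(html: str) -> dict:
    """Recover the embedded JSON payload from a rendered heatmap document."""
    start = html.index('<script id="heatmap-data" type="application/json">')
    start = html.index("\n", start) + 1
    end = html.index("</script>", start)
    return json.loads(html[start:end])
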