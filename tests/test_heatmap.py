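import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from taxoprofile import fixtures as fx
from taxoprofile.combine import combine_protein
from taxoprofile.heatmap import (
    HeatmapConfig,
    ScoreMatrix,
    SCORE_CAP,
    build_score_matrix,
    cluster_axes,
    extract_payload,
    render_heatmap,
    significance_score,
)
from taxoprofile.qc_filter import ConfigurationError
from conftest import make_record, make_table, parse_xml_text
from cluster_oracle import brute_force_leaf_order


class TestSignificanceScore:
    @pytest.mark.parametrize(
        "evalue,score",
        [
            (1e-30, 30),
            (1e-250, 200),  # capped
            (0.5, 0),  # floor(0.301) = 0
            (0.0, 200),
            (1.0, 0),
            (10.0, 0),
            (1e-199, 199),
            (1e-200, 200),
        ],
    )
    def test_examples(self, evalue, score):
        assert significance_score(evalue) == score

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            significance_score(-1e-5)

    @given(st.floats(min_value=0, max_value=10, allow_nan=False))
    def test_bounded(self, evalue):
        assert 0 <= significance_score(evalue) <= SCORE_CAP

    def test_monotone_non_increasing(self):
        rng = np.random.RandomState(0)
        evalues = np.sort(10.0 ** rng.uniform(-260, 1, size=500))
        scores = [significance_score(e) for e in evalues]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


def _combined(db, protein, taxid_evalues):
    table = make_table(
        [make_record(subject_accession=f"{protein}{t}", subject_taxid=t,
                     evalue=e) for t, e in taxid_evalues],
        protein=protein,
    )
    return combine_protein([table], db)


class TestBuildScoreMatrix:
    def test_organism_without_hits_gets_zero_row(self, small_db):
        combined = [_combined(small_db, "p1", [(12, 1e-45)])]
        config = HeatmapConfig(organisms=(12, 17))
        matrix = build_score_matrix(combined, config, small_db)
        assert matrix.scores[0, 0] == 45
        assert (matrix.scores[1] == 0).all()

    def test_best_evalue_scored(self, small_db):
        combined = [_combined(small_db, "p1", [(12, 1e-45), (13, 1e-7)])]
        matrix = build_score_matrix(
            combined, HeatmapConfig(organisms=(12, 13)), small_db
        )
        assert matrix.scores[:, 0].tolist() == [45, 7]

    def test_names_resolve_to_taxids(self, small_db):
        combined = [_combined(small_db, "p1", [(12, 1e-45)])]
        matrix = build_score_matrix(
            combined,
            HeatmapConfig(organisms=("Alphabacteria species 1",)),
            small_db,
        )
        assert matrix.taxids == [12] and matrix.scores[0, 0] == 45

    def test_unknown_organism_warned_not_fatal(self, small_db):
        combined = [_combined(small_db, "p1", [(12, 1e-45)])]
        matrix = build_score_matrix(
            combined, HeatmapConfig(organisms=("Atlantis weirdii", 12)), small_db
        )
        assert (matrix.scores[0] == 0).all()
        assert matrix.scores[1, 0] == 45

    def test_strain_hit_scores_on_species_row(self, strain_spec, strain_db):
        xml = fx.make_blast_results(strain_spec, "protX", "seed1")
        table = parse_xml_text(xml, "protX")
        strain_taxids = {r.subject_taxid for r in table.records
                        if strain_db.rank(r.subject_taxid) == "no rank"}
        assert strain_taxids  # the spec plants strain-level hits
        combined = [combine_protein([table], strain_db)]
        species = sorted(t for t in strain_db if strain_db.rank(t) == "species")
        matrix = build_score_matrix(
            combined, HeatmapConfig(organisms=tuple(species)), strain_db
        )
        for strain in strain_taxids:
            row = species.index(strain_db.species_of(strain))
            assert matrix.scores[row, 0] > 0

    def test_empty_selection_rejected(self, small_db):
        with pytest.raises(ConfigurationError):
            build_score_matrix([], HeatmapConfig(), small_db)


def _matrix(scores):
    scores = np.asarray(scores, dtype=int)
    n, p = scores.shape
    return ScoreMatrix(
        taxids=list(range(1, n + 1)),
        names=[f"org{i}" for i in range(n)],
        proteins=[f"prot{chr(65 + j)}" for j in range(p)],
        scores=scores,
        evalues=np.where(scores > 0, 10.0 ** (-scores.astype(float)), np.nan),
    )


class TestClusterAxes:
    def test_identical_rows_merge_first(self):
        matrix = _matrix([[10, 20], [10, 20], [90, 5]])
        _, _, row_Z, _ = cluster_axes(matrix, "average")
        assert row_Z[0, 2] == 0.0  # first merge at distance zero
        assert {int(row_Z[0, 0]), int(row_Z[0, 1])} == {0, 1}

    def test_single_row_passthrough(self):
        matrix = _matrix([[10, 20, 30]])
        row_order, col_order, row_Z, _ = cluster_axes(matrix, "centroid")
        assert row_order == [0] and row_Z is None
        assert sorted(col_order) == [0, 1, 2]

    def test_unknown_linkage_lists_options(self):
        with pytest.raises(ConfigurationError, match="centroid"):
            cluster_axes(_matrix([[1, 2], [3, 4]]), "closest")

    @pytest.mark.parametrize(
        "linkage",
        ["single", "complete", "average", "weighted", "centroid", "median", "ward"],
    )
    def test_matches_brute_force_oracle(self, linkage):
        rng = np.random.RandomState(11)
        for _ in range(4):
            scores = rng.randint(0, 201, size=(6, 4))
            matrix = _matrix(scores)
            row_order, col_order, _, _ = cluster_axes(matrix, linkage)
            assert row_order == brute_force_leaf_order(scores, linkage)
            assert col_order == brute_force_leaf_order(scores.T, linkage)

    def test_permutation_invariant_topology(self):
        """Shuffling rows preserves the dendrogram topology (cluster
        memberships and merge heights); identical input gives an identical
        leaf order."""
        rng = np.random.RandomState(5)
        scores = rng.randint(0, 201, size=(6, 4))
        matrix = _matrix(scores)

        def merge_structure(m):
            _, _, Z, _ = cluster_axes(m, "average")
            members = [frozenset([m.names[i]]) for i in range(len(m.names))]
            merges = set()
            for a, b, dist, _ in Z:
                merged = members[int(a)] | members[int(b)]
                members.append(merged)
                merges.add((merged, round(float(dist), 9)))
            return merges

        base = merge_structure(matrix)
        perm = rng.permutation(6)
        shuffled = ScoreMatrix(
            taxids=[matrix.taxids[i] for i in perm],
            names=[matrix.names[i] for i in perm],
            proteins=matrix.proteins,
            scores=scores[perm],
            evalues=matrix.evalues[perm],
        )
        assert merge_structure(shuffled) == base
        order_a, _, _, _ = cluster_axes(matrix, "average")
        order_b, _, _, _ = cluster_axes(matrix, "average")
        assert order_a == order_b


class TestRenderHeatmap:
    def _render(self, matrix, config=None):
        config = config or HeatmapConfig(organisms=tuple(matrix.taxids))
        orders = cluster_axes(matrix, config.linkage)[:2]
        buf = io.StringIO()
        html = render_heatmap(matrix, orders, config, buf)
        return html

    def test_payload_round_trips(self):
        matrix = _matrix([[30, 0], [45, 12], [0, 0]])
        payload = extract_payload(self._render(matrix))
        assert payload["scores"] == matrix.scores.tolist()
        assert payload["proteins"] == matrix.proteins
        assert payload["score_cap"] == SCORE_CAP

    def test_absolute_view_threshold_semantics(self):
        matrix = _matrix([[30, 29], [31, 0]])
        payload = extract_payload(self._render(matrix))
        threshold = payload["slider_default"]
        assert threshold == 30
        visible = {
            (i, j)
            for i, row in enumerate(payload["scores"])
            for j, score in enumerate(row)
            if score >= threshold
        }
        assert visible == {(0, 0), (1, 0)}
        # one step tighter hides the boundary cell
        assert {(i, j) for i, row in enumerate(payload["scores"])
                for j, s in enumerate(row) if s >= threshold + 1} == {(1, 0)}

    def test_slider_enabled_only_in_absolute_view(self):
        html = self._render(_matrix([[30, 0], [45, 12]]))
        assert 'disabled' in html
        assert 'slider").disabled = view !== "absolute"' in html

    def test_alphabetical_toggle_order(self):
        matrix = _matrix([[1, 2, 3], [4, 5, 6]])
        matrix.proteins = ["zeta", "alpha", "midd"]
        payload = extract_payload(self._render(matrix))
        assert payload["alpha_col_order"] == [1, 2, 0]

    def test_all_zero_matrix_renders(self):
        payload = extract_payload(self._render(_matrix([[0, 0], [0, 0]])))
        assert payload["scores"] == [[0, 0], [0, 0]]
        assert all(ev is None for row in payload["evalues"] for ev in row)

    def test_tooltip_payload_has_best_evalues(self):
        matrix = _matrix([[45, 0]])
        payload = extract_payload(self._render(matrix))
        assert float(payload["evalues"][0][0]) == 1e-45
        assert payload["evalues"][0][1] is None

    def test_mismatched_orders_rejected(self):
        matrix = _matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            render_heatmap(matrix, ([0], [0, 1]),
                           HeatmapConfig(organisms=(1, 2)), io.StringIO())
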