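import numpy as np
import pytest
from hypothesis import given, strategies as st

from taxoprofile import fixtures as fx
from taxoprofile.qc_filter import (
    ConfigurationError,
    Limits,
    ZERO_EVALUE_FLOOR,
    apply_limits,
    coverage_profile,
    cross_hit_matrix,
    default_interval_edges,
    length_histogram,
)
from conftest import make_record, make_table, parse_xml_text


class TestLimits:
    def test_defaults(self):
        limits = Limits()
        assert limits.resolve("anything") == (1e-30, 50)

    def test_override_or_default(self):
        limits = Limits(overrides={"NAPRT": (1e-120, 200)})
        assert limits.resolve("NAPRT") == (1e-120, 200)
        assert limits.resolve("APT") == (1e-30, 50)

    def test_from_file(self, tmp_path):
        path = tmp_path / "limits.txt"
        path.write_text("# comment\nNAPRT 1e-120 200\n* 1e-10 30\n")
        limits = Limits.from_file(path)
        assert limits.resolve("NAPRT") == (1e-120, 200)
        assert limits.resolve("other") == (1e-10, 30)

    def test_bad_line_rejected(self, tmp_path):
        path = tmp_path / "limits.txt"
        path.write_text("NAPRT 1e-120\n")
        with pytest.raises(ConfigurationError, match="limits.txt:1"):
            Limits.from_file(path)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ConfigurationError):
            Limits(default_evalue=0.0)


class TestLengthHistogram:
    def test_hand_binned_example(self):
        table = make_table(
            [make_record(subject_length=l, subject_accession=f"A{l}")
             for l in (400, 401, 598)]
        )
        edges, counts = length_histogram([table], bin_width=50)
        assert counts[8] == 2  # [400, 450)
        assert counts[11] == 1  # [550, 600)
        assert counts.sum() == 3

    def test_single_record(self):
        edges, counts = length_histogram([make_table([make_record()])], 50)
        assert counts.sum() == 1 and (counts > 0).sum() == 1

    def test_empty_input(self):
        edges, counts = length_histogram([make_table([])], 50)
        assert counts.size == 0

    def test_count_conservation(self, small_spec):
        tables = [
            parse_xml_text(fx.make_blast_results(small_spec, p, "seed1"), p)
            for p in small_spec.proteins
        ]
        n_records = sum(len(t) for t in tables)
        _, counts = length_histogram(tables, 25)
        assert counts.sum() == n_records

    def test_bimodal_lengths_give_two_peaks(self):
        # planted length mixture peaking near 400 aa and just below 600 aa
        clades = [fx.CladeSpec("Epsilonia", "Bacteria", n_species=40)]
        rule = fx.PresenceRule(
            fraction=1.0,
            length_modes=((400.0, 12.0, 0.5), (585.0, 8.0, 0.5)),
        )
        spec = fx.PresenceSpec(
            clades=clades, proteins={"napralog": {"Epsilonia": rule}}, seed=3
        )
        table = parse_xml_text(
            fx.make_blast_results(spec, "napralog", "seed1"), "napralog"
        )
        _, counts = length_histogram([table], bin_width=50)
        valley = counts[9:11].max()  # 450..550 aa, between the two modes
        assert counts[7:9].max() > valley  # peak near 400 aa
        assert counts[11] > valley  # peak just below 600 aa


class TestCoverageProfile:
    def test_default_edges_span_search_threshold_to_floor(self):
        edges = default_interval_edges()
        assert edges.shape == (7,)
        assert np.allclose(np.log10(edges),
                           [-3, -32.5, -62, -91.5, -121, -150.5, -180])

    def test_one_hit_per_interval(self):
        evs = [1e-5, 1e-35, 1e-65, 1e-95, 1e-125, 1e-155]
        table = make_table(
            [make_record(evalue=e, subject_accession=f"A{i}")
             for i, e in enumerate(evs)]
        )
        profile = coverage_profile(table)
        assert profile.counts == [1, 1, 1, 1, 1, 1]

    def test_full_span_single_hit(self):
        table = make_table(
            [make_record(evalue=1e-150, query_start=1, query_end=450)]
        )
        profile = coverage_profile(table)
        assert profile.counts == [0, 0, 0, 0, 1, 0]
        assert profile.intervals[4] == [(1, 450)]

    def test_empty_table(self):
        profile = coverage_profile(make_table([]))
        assert profile.counts == [0] * 6

    def test_zero_evalue_lands_in_most_significant_interval(self):
        profile = coverage_profile(make_table([make_record(evalue=0.0)]))
        assert profile.counts[5] == 1

    def test_span_exceeding_query_rejected(self):
        table = make_table([make_record(query_end=9999)], seed_length=450)
        with pytest.raises(ValueError, match="ACC00001"):
            coverage_profile(table)

    def test_spans_sorted_by_significance_within_interval(self):
        table = make_table([
            make_record(evalue=1e-40, query_start=5, query_end=50,
                        subject_accession="A1"),
            make_record(evalue=1e-55, query_start=7, query_end=60,
                        subject_accession="A2"),
        ])
        profile = coverage_profile(table)
        assert profile.intervals[1] == [(7, 60), (5, 50)]


class TestApplyLimits:
    def test_boundary_inclusive(self):
        table = make_table([make_record(evalue=1e-30, subject_length=50)])
        assert len(apply_limits(table, Limits())) == 1

    def test_default_evalue_cutoff_removes_weaker_hit(self):
        table = make_table([make_record(evalue=1e-29, subject_length=500)])
        filtered = apply_limits(table, Limits())
        assert len(filtered) == 0
        assert filtered.metadata["removed_by_evalue"] == 1

    def test_empty_table(self):
        filtered = apply_limits(make_table([]), Limits())
        assert len(filtered) == 0 and filtered.metadata["parsed"] == 0

    def test_counts_self_consistent(self):
        records = [
            make_record(evalue=ev, subject_length=ln, subject_accession=f"A{i}")
            for i, (ev, ln) in enumerate(
                [(1e-50, 400), (1e-10, 400), (1e-50, 10), (1e-5, 5)]
            )
        ]
        filtered = apply_limits(make_table(records), Limits())
        m = filtered.metadata
        assert m["parsed"] == 4
        assert m["parsed"] == m["kept"] + m["removed_by_evalue"] + m["removed_by_length"]
        assert m["kept"] == 1

    @given(
        records=st.lists(
            st.builds(
                make_record,
                subject_accession=st.text("ABC123", min_size=3, max_size=6),
                evalue=st.floats(min_value=1e-100, max_value=1.0),
                subject_length=st.integers(min_value=1, max_value=800),
            ),
            max_size=20,
        ),
        tight=st.tuples(
            st.floats(min_value=1e-80, max_value=1e-10),
            st.integers(min_value=0, max_value=500),
        ),
    )
    def test_relaxing_cutoffs_is_monotone(self, records, tight):
        table = make_table(records)
        ev, ln = tight
        kept_tight = apply_limits(table, Limits(ev, ln)).records
        kept_loose = apply_limits(table, Limits(ev * 100, max(0, ln - 50))).records
        assert set(map(id, kept_tight)) <= set(map(id, kept_loose))

    @given(
        records=st.lists(
            st.builds(
                make_record,
                evalue=st.floats(min_value=1e-100, max_value=1.0),
                subject_length=st.integers(min_value=1, max_value=800),
            ),
            max_size=20,
        )
    )
    def test_agrees_with_brute_force(self, records):
        table = make_table(records)
        got = apply_limits(table, Limits()).records
        expected = [
            r for r in records if r.evalue <= 1e-30 and r.subject_length >= 50
        ]
        assert got == expected


class TestCrossHitMatrix:
    def test_disjoint_sets_all_zero(self):
        matrix = cross_hit_matrix({
            "p1": {"A1": 1e-40}, "p2": {"B1": 1e-50},
        })
        off_diag = matrix.values[~np.eye(2, dtype=bool)]
        assert (off_diag == 0).all()

    def test_shared_accession_minimum_both_ways(self):
        matrix = cross_hit_matrix({
            "p1": {"SHARED": 1e-60}, "p2": {"SHARED": 1e-45},
        })
        assert matrix.values[0, 1] == matrix.values[1, 0] == 1e-60

    def test_three_proteins_one_shared_pair(self):
        matrix = cross_hit_matrix({
            "p1": {"S": 1e-40}, "p2": {"S": 1e-50}, "p3": {"X": 1e-60},
        })
        assert (matrix.values != 0).sum() == 2
        assert matrix.values[0, 1] == matrix.values[1, 0] == 1e-50

    def test_fewer_than_two_proteins_rejected(self):
        with pytest.raises(ValueError):
            cross_hit_matrix({"p1": {"A": 1e-5}})

    def test_true_zero_evalue_floored(self):
        matrix = cross_hit_matrix({"p1": {"S": 0.0}, "p2": {"S": 1e-45}})
        assert matrix.values[0, 1] == ZERO_EVALUE_FLOOR

    def test_accepts_result_tables(self):
        t1 = make_table([make_record(subject_accession="S", evalue=1e-60)], "p1")
        t2 = make_table([make_record(subject_accession="S", evalue=1e-45)], "p2")
        matrix = cross_hit_matrix({"p1": [t1], "p2": [t2]})
        assert matrix.values[0, 1] == 1e-60

    @given(
        st.dictionaries(
            st.sampled_from(["p1", "p2", "p3", "p4"]),
            st.dictionaries(
                st.sampled_from(["A", "B", "C", "D", "E"]),
                st.floats(min_value=1e-100, max_value=1.0),
                max_size=5,
            ),
            min_size=2,
            max_size=4,
        )
    )
    def test_symmetric_zero_diagonal(self, hits):
        matrix = cross_hit_matrix(hits)
        assert np.allclose(matrix.values, matrix.values.T)
        assert (np.diag(matrix.values) == 0).all()

    def test_csv_output(self, tmp_path):
        matrix = cross_hit_matrix({"p1": {"S": 1e-60}, "p2": {"S": 1e-45}})
        path = tmp_path / "matrix.csv"
        matrix.write_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#")
        assert lines[1].split(",")[1:] == ["p1", "p2"]
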