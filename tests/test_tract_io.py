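import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from admixclock.tract_io import (
    AncestryTract,
    DxySummary,
    PopulationSample,
    TractParseError,
    TractValidationError,
    WindowRecord,
    assign_tracts_to_windows,
    make_window_grid,
    read_tracts,
    read_window_table,
    write_tracts,
    write_window_table,
)


def _write(tmp_path, rows, name="tracts.tsv"):
    path = tmp_path / name
    path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


class TestTractModel:
    def test_length_and_validation(self):
        t = AncestryTract("h1", "chr1", 100, 250, "donor")
        assert t.length == 150
        with pytest.raises(TractValidationError):
            AncestryTract("h1", "chr1", 100, 100, "donor")
        with pytest.raises(TractValidationError):
            AncestryTract("h1", "chr1", 100, 50, "donor")
        with pytest.raises(TractValidationError):
            AncestryTract("h1", "chr1", 0, 10, "martian")

    def test_population_sample_invariants(self):
        tracts = [AncestryTract("h1", "chr1", 0, 100)]
        with pytest.raises(TractValidationError):
            PopulationSample("p", tracts, 1, 1.5, 1000)
        with pytest.raises(TractValidationError):
            # tract lengths exceed the genome on one haplotype
            PopulationSample("p", tracts, 1, 0.5, 50)
        ok = PopulationSample("p", tracts, 2, 0.31, 1000)
        assert ok.admixture_fraction_f == 0.31

    def test_dxy_requires_positive_outgroup_divergence(self):
        with pytest.raises(TractValidationError):
            DxySummary("chr1", 0, 100_000, d_min=0.01, d_out=0.0)


class TestReadTracts:
    def test_adjacent_same_ancestry_intervals_merge(self, tmp_path):
        path = _write(
            tmp_path,
            [("chr1", 0, 50_000, "h1", "donor"),
             ("chr1", 50_000, 80_000, "h1", "donor")],
        )
        tracts = read_tracts(path)
        assert len(tracts) == 1
        assert (tracts[0].start, tracts[0].end, tracts[0].length) == (0, 80_000, 80_000)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        assert read_tracts(_write(tmp_path, [])) == []

    def test_reversed_coordinates_are_a_parse_error_with_line_number(self, tmp_path):
        path = _write(tmp_path, [("chr1", 100, 50, "h1", "donor")])
        with pytest.raises(TractParseError, match="line 1"):
            read_tracts(path)

    def test_wrong_field_count_names_line(self, tmp_path):
        path = _write(tmp_path, [("chr1", 0, 100, "h1", "donor"), ("chr1", 5, 10)])
        with pytest.raises(TractParseError, match="line 2"):
            read_tracts(path)

    def test_overlapping_same_ancestry_intervals_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            [("chr1", 0, 60_000, "h1", "donor"),
             ("chr1", 40_000, 80_000, "h1", "donor")],
        )
        with pytest.raises(TractValidationError, match="overlapping"):
            read_tracts(path)

    @given(
        st.lists(
            st.tuples(st.integers(1, 5_000), st.integers(1, 30_000)),
            min_size=0,
            max_size=20,
        ),
        st.sampled_from(["donor", "recipient"]),
    )
    def test_write_read_round_trip_is_identity(self, tmp_path, gaps_lengths, ancestry):
        pos = 0
        tracts = []
        for gap, length in gaps_lengths:
            start = pos + gap  # gap >= 1 prevents adjacency merging
            tracts.append(AncestryTract("h1", "chr1", start, start + length, ancestry))
            pos = start + length
        path = tmp_path / "rt.tsv"
        write_tracts(tracts, path)
        assert read_tracts(path) == tracts


class TestWindowTable:
    def test_valid_table_round_trips(self, tmp_path):
        windows = [
            WindowRecord("chr1", 0, 100_000, 2.0, 1e-8, rnd_min=0.01),
            WindowRecord("chr1", 100_000, 200_000, 3.0, 2e-8, rnd_min=None),
            WindowRecord("chr2", 0, 100_000, 4.0, 3e-8, rnd_min=0.05),
        ]
        path = tmp_path / "w.tsv"
        write_window_table(windows, path)
        back = read_window_table(path)
        assert len(back) == 3
        assert back[1].rnd_min is None
        assert [(w.chromosome, w.start) for w in back] == [
            ("chr1", 0), ("chr1", 100_000), ("chr2", 0)
        ]

    def test_duplicate_windows_rejected(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text(
            "chromosome\tstart\tend\trho_per_kb\tr_morgans_per_bp\n"
            "chr1\t0\t100000\t1.0\t1e-8\n"
            "chr1\t0\t100000\t2.0\t1e-8\n"
        )
        with pytest.raises(TractValidationError, match="duplicate"):
            read_window_table(path)

    def test_missing_required_column_is_schema_error(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("chromosome\tstart\tend\trho_per_kb\nchr1\t0\t100000\t1.0\n")
        with pytest.raises(TractParseError, match="r_morgans_per_bp"):
            read_window_table(path)

    def test_absent_rnd_column_reads_as_missing(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text(
            "chromosome\tstart\tend\trho_per_kb\tr_morgans_per_bp\n"
            "chr1\t0\t100000\t1.0\t1e-8\n"
        )
        assert read_window_table(path)[0].rnd_min is None


class TestAssignment:
    def test_spanning_tract_assigned_to_every_overlapped_window_at_full_length(self):
        windows = make_window_grid("chr1", 300_000, 1e-8)
        tract = AncestryTract("h1", "chr1", 90_000, 250_000)
        assign_tracts_to_windows([tract], windows)
        assert [len(w.assigned_tracts) for w in windows] == [1, 1, 1]
        for w in windows:
            assert w.assigned_tracts[0].length == 160_000

    def test_contained_tract_assigned_to_exactly_one_window(self):
        windows = make_window_grid("chr1", 300_000, 1e-8)
        assign_tracts_to_windows([AncestryTract("h1", "chr1", 110_000, 150_000)], windows)
        assert [len(w.assigned_tracts) for w in windows] == [0, 1, 0]

    def test_half_open_boundary_excludes_touching_window(self):
        windows = make_window_grid("chr1", 300_000, 1e-8)
        # ends exactly at the second window's start
        assign_tracts_to_windows([AncestryTract("h1", "chr1", 50_000, 100_000)], windows)
        assert [len(w.assigned_tracts) for w in windows] == [1, 0, 0]

    def test_unknown_chromosome_skipped_with_warning(self, caplog):
        windows = make_window_grid("chr1", 200_000, 1e-8)
        with caplog.at_level("WARNING"):
            assign_tracts_to_windows([AncestryTract("h1", "chrX", 0, 1000)], windows)
        assert sum(len(w.assigned_tracts) for w in windows) == 0
        assert "skipped" in caplog.text

    def test_total_assignment_count_matches_brute_force(self, rng):
        windows = make_window_grid("chr1", 2_000_000, 1e-8)
        tracts = []
        for i in range(200):
            start = int(rng.integers(0, 1_950_000))
            end = start + int(rng.integers(1, 400_000))
            tracts.append(AncestryTract(f"h{i}", "chr1", start, end))
        assign_tracts_to_windows(tracts, windows)
        total = sum(len(w.assigned_tracts) for w in windows)
        brute = sum(
            1
            for t in tracts
            for w in windows
            if t.start < w.end and t.end > w.start
        )
        assert total == brute
        # no overlapping tract is dropped
        assigned = {id(t) for w in windows for t in w.assigned_tracts}
        overlapping = {
            id(t)
            for t in tracts
            if any(t.start < w.end and t.end > w.start for w in windows)
        }
        assert assigned == overlapping
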