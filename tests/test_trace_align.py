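"""Progressive MSA, trace projection onto columns, conservation segments."""

import numpy as np
import pytest

from flexscan.disorder import trace_from_scores
from flexscan.seqio import SequenceRecord
from flexscan.trace_align import (AlignedTraceMatrix, MultipleAlignment,
                                  align_sequences, disorder_conservation,
                                  project_traces, write_trace_matrix)


def rec(accession: str, residues: str) -> SequenceRecord:
    return SequenceRecord(accession=accession, residues=residues)


def test_identical_sequences_align_gapless():
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIE"
    aln = align_sequences([rec("a", seq), rec("b", seq), rec("c", seq)])
    assert aln.rows == (seq, seq, seq)


def test_ungapping_rows_reproduces_inputs():
    seqs = [rec("a", "ACDEFGHIKLMNPQRSTVWY"),
            rec("b", "ACDEFGHIKLRSTVWY"),
            rec("c", "ACDEFGMNPQRSTVWY")]
    aln = align_sequences(seqs)
    for i, s in enumerate(seqs):
        assert aln.ungapped(i) == s.residues
    assert len({len(r) for r in aln.rows}) == 1


def test_guide_tree_joins_identical_pair_first():
    """With A == B and C distant, A and B merge first and stay identical."""
    close = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    distant = "GGGPPPWWWCCCHHHNNNDDD"
    aln = align_sequences([rec("a", close), rec("c", distant),
                           rec("b", close)])
    rows = dict(zip(aln.row_accessions, aln.rows))
    assert rows["a"] == rows["b"]


def test_align_requires_two_sequences():
    with pytest.raises(ValueError):
        align_sequences([rec("a", "ACDE")])


def test_project_traces_places_scores_and_zeroes_gaps():
    aln = MultipleAlignment(row_accessions=("a", "b"),
                            rows=("AC-D", "ACDD"))
    traces = [trace_from_scores("a", [0.1, 0.2, 0.3]),
              trace_from_scores("b", [0.4, 0.5, 0.6, 0.7])]
    matrix = project_traces(aln, traces)
    assert matrix.values[0].tolist() == [0.1, 0.2, 0.0, 0.3]
    assert matrix.values[1].tolist() == [0.4, 0.5, 0.6, 0.7]
    assert matrix.gap_mask[0].tolist() == [False, False, True, False]


def test_projection_conserves_row_sums_and_order(family):
    from flexscan.disorder import predict_trace
    seqs = list(family.records[:3])
    aln = align_sequences(seqs)
    traces = [predict_trace(s, "long") for s in seqs]
    matrix = project_traces(aln, traces)
    for r, trace in enumerate(traces):
        non_gap = matrix.values[r][~matrix.gap_mask[r]]
        assert non_gap.tolist() == list(trace.scores)
        assert matrix.values[r].sum() == pytest.approx(sum(trace.scores))
        assert (matrix.values[r][matrix.gap_mask[r]] == 0.0).all()


def test_projection_length_mismatch_names_accession():
    aln = MultipleAlignment(row_accessions=("a", "b"), rows=("ACD", "ACD"))
    traces = [trace_from_scores("a", [0.1, 0.2, 0.3]),
              trace_from_scores("b", [0.1, 0.2])]
    with pytest.raises(ValueError, match="b"):
        project_traces(aln, traces)


def make_matrix(rows: dict[str, list[float]],
                gap_rows: dict[str, list[bool]] | None = None):
    accs = tuple(rows)
    values = np.array([rows[a] for a in accs])
    if gap_rows is None:
        gap_mask = np.zeros(values.shape, dtype=bool)
    else:
        gap_mask = np.array([gap_rows[a] for a in accs])
    return AlignedTraceMatrix(row_accessions=accs, values=values,
                              gap_mask=gap_mask)


def test_segments_are_maximal_runs_in_residue_coordinates():
    matrix = make_matrix({"q": [0.9, 0.9, 0.2, 0.8]})
    _cols, segments = disorder_conservation(matrix, "q", ids_threshold=0.5)
    assert [(s.start, s.end) for s in segments] == [(1, 2), (4, 4)]


def test_segment_coordinates_skip_query_gaps():
    matrix = make_matrix(
        {"q": [0.9, 0.0, 0.9, 0.8]},
        {"q": [False, True, False, False]},
    )
    _cols, segments = disorder_conservation(matrix, "q", ids_threshold=0.5)
    # the gap column is not a query residue: one run covering residues 1-3
    assert [(s.start, s.end) for s in segments] == [(1, 3)]


def test_single_row_matrix_reports_nan_cross_fraction():
    matrix = make_matrix({"q": [0.9, 0.9]})
    _cols, segments = disorder_conservation(matrix, "q")
    assert len(segments) == 1
    assert np.isnan(segments[0].cross_row_fraction)


def test_unconserved_disorder_flagged_for_deletion():
    matrix = make_matrix({"q": [0.9, 0.9, 0.1, 0.9],
                          "h": [0.0, 0.0, 0.0, 0.0]})
    _cols, segments = disorder_conservation(matrix, "q")
    assert segments and all(s.deletion_candidate for s in segments)
    assert all(s.cross_row_fraction == 0.0 for s in segments)


def test_conserved_disorder_not_flagged():
    matrix = make_matrix({"q": [0.9, 0.9], "h": [0.8, 0.7]})
    _cols, segments = disorder_conservation(matrix, "q")
    assert [s.deletion_candidate for s in segments] == [False]
    assert segments[0].cross_row_fraction == 1.0


def test_no_scores_above_threshold_gives_empty_report():
    matrix = make_matrix({"q": [0.1, 0.2, 0.3], "h": [0.1, 0.1, 0.1]})
    _cols, segments = disorder_conservation(matrix, "q")
    assert segments == []


def test_unknown_query_lists_available_rows():
    matrix = make_matrix({"a": [0.1], "b": [0.1]})
    with pytest.raises(ValueError, match="a, b"):
        disorder_conservation(matrix, "zz")


def test_matrix_tsv_export(tmp_path):
    matrix = make_matrix({"a": [0.15, 0.25], "b": [0.35, 0.45]})
    out = tmp_path / "m.tsv"
    write_trace_matrix(matrix, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "accession\t1\t2"
    assert lines[1] == "a\t0.1500\t0.2500"
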