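"""Multiple alignment of homologs and disorder-trace projection.

Sequences are aligned with a built-in progressive algorithm: all pairwise
global alignments (BLOSUM62, affine gaps) give a distance matrix
(1 - fractional identity), a UPGMA guide tree orders the merges, and
profiles are merged by affine-gap profile-profile dynamic programming.

Disorder traces are then projected onto alignment columns: each row's
scores occupy its non-gap columns and every gap cell is set to exactly
0.0. The 0.0 gap convention makes inserted gaps visible in overlaid traces
(a true disorder score of exactly 0.0 is extremely unlikely for a real
residue) but is deliberately overloaded — consumers comparing columns
should treat 0.0 cells as "gap or fully ordered".

:func:`disorder_conservation` reports the maximal runs of query residues
above a disorder threshold together with the fraction of other rows that
are disordered over the same columns; runs that are disordered in the
query but ordered (or absent) in most homologs are flagged as candidates
for deletion from an expression construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .disorder import DisorderTrace
from .search import load_matrix
from .seqio import SequenceRecord

__all__ = [
    "MultipleAlignment",
    "AlignedTraceMatrix",
    "DisorderSegment",
    "align_sequences",
    "project_traces",
    "disorder_conservation",
    "write_aligned_fasta",
    "write_trace_matrix",
]

GAP = "-"


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows; ungapping row i reproduces input sequence i."""

    row_accessions: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.row_accessions) != len(self.rows):
            raise ValueError("one accession per row required")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@dataclass(frozen=True)
class AlignedTraceMatrix:
    """Disorder scores on alignment columns; gap cells are exactly 0.0."""

    row_accessions: tuple[str, ...]
    values: np.ndarray          # shape (n_rows, n_columns)
    gap_mask: np.ndarray        # True where the alignment has a gap

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DisorderSegment:
    """A maximal disordered run of the query, in query residue coordinates.

    ``start``/``end`` are 1-based inclusive positions in the ungapped query.
    ``cross_row_fraction`` is the mean fraction of non-query rows disordered
    over the segment's columns (NaN for a single-row matrix).
    ``deletion_candidate`` flags segments mostly absent/ordered elsewhere.
    """

    start: int
    end: int
    mean_score: float
    cross_row_fraction: float
    deletion_candidate: bool


# ---------------------------------------------------------------------------
# progressive multiple alignment

def _pairwise_global(a: str, b: str, matrix_name: str,
                     gap_open: float, gap_extend: float):
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = load_matrix(matrix_name)
    aligner.mode = "global"
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    best = aligner.align(a, b)[0]
    return str(best[0]), str(best[1])


def _fractional_identity(row_a: str, row_b: str) -> float:
    n_ident = sum(1 for x, y in zip(row_a, row_b)
                  if x == y and x != GAP)
    return n_ident / len(row_a) if row_a else 0.0


def _column_score(col_a: Sequence[str], col_b: Sequence[str], mat) -> float:
    """Mean cross-pair substitution score between two profile columns.

    Gap characters contribute 0, so the score rewards residue-residue
    agreement without double-penalising existing gaps (the affine gap
    penalties handle new gaps).
    """
    total = 0.0
    for x in col_a:
        if x == GAP:
            continue
        for y in col_b:
            if y == GAP:
                continue
            total += mat[x, y]
    return total / (len(col_a) * len(col_b))


def _merge_profiles(prof_a: list[str], prof_b: list[str], mat,
                    gap_open: float, gap_extend: float) -> list[str]:
    """Affine-gap (Gotoh) global profile-profile alignment.

    Profiles are lists of gapped rows. Returns the merged row list
    (rows of ``prof_a`` first). Deterministic tie-break: match preferred
    over gap-in-B over gap-in-A.
    """
    cols_a = ["".join(r[i] for r in prof_a) for i in range(len(prof_a[0]))]
    cols_b = ["".join(r[i] for r in prof_b) for i in range(len(prof_b[0]))]
    n, m = len(cols_a), len(cols_b)
    neg = -np.inf
    # three layers: M match, X gap in profile B (consume A), Y gap in A
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_extend) - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_extend) - (j - 1) * gap_extend
    ptr_M = np.zeros((n + 1, m + 1), dtype=np.int8)   # 0=M,1=X,2=Y
    ptr_X = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_Y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _column_score(cols_a[i - 1], cols_b[j - 1], mat)
            opts = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = opts[k] + s
            ptr_M[i, j] = k
            opts = (M[i - 1, j] - gap_open - gap_extend,
                    X[i - 1, j] - gap_extend,
                    Y[i - 1, j] - gap_open - gap_extend)
            k = int(np.argmax(opts))
            X[i, j] = opts[k]
            ptr_X[i, j] = k
            opts = (M[i, j - 1] - gap_open - gap_extend,
                    X[i, j - 1] - gap_open - gap_extend,
                    Y[i, j - 1] - gap_extend)
            k = int(np.argmax(opts))
            Y[i, j] = opts[k]
            ptr_Y[i, j] = k
    # traceback
    i, j = n, m
    layer = int(np.argmax((M[n, m], X[n, m], Y[n, m])))
    steps: list[int] = []
    while i > 0 or j > 0:
        if i == 0:
            layer = 2
        elif j == 0:
            layer = 1
        steps.append(layer)
        if layer == 0:
            layer = int(ptr_M[i, j])
            i, j = i - 1, j - 1
        elif layer == 1:
            layer = int(ptr_X[i, j])
            i -= 1
        else:
            layer = int(ptr_Y[i, j])
            j -= 1
    steps.reverse()
    gap_col_a = GAP * len(prof_a)
    gap_col_b = GAP * len(prof_b)
    out_a: list[list[str]] = [[] for _ in prof_a]
    out_b: list[list[str]] = [[] for _ in prof_b]
    ia = ib = 0
    for step in steps:
        if step in (0, 1):
            for r, row in enumerate(prof_a):
                out_a[r].append(row[ia])
            ia += 1
        else:
            for r in range(len(prof_a)):
                out_a[r].append(GAP)
        if step in (0, 2):
            for r, row in enumerate(prof_b):
                out_b[r].append(row[ib])
            ib += 1
        else:
            for r in range(len(prof_b)):
                out_b[r].append(GAP)
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def align_sequences(seqs: Sequence[SequenceRecord],
                    gap_open: float = 10.0,
                    gap_extend: float = 0.1,
                    matrix: str = "BLOSUM62") -> MultipleAlignment:
    """Progressive multiple alignment with a UPGMA guide tree.

    Pairwise global alignments give distances (1 - fractional identity);
    UPGMA (average-linkage) clustering orders profile merges. Deterministic
    for a fixed input order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    mat = load_matrix(matrix)
    k = len(seqs)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ra, rb = _pairwise_global(seqs[i].residues, seqs[j].residues,
                                      matrix, gap_open, gap_extend)
            dist[i, j] = dist[j, i] = 1.0 - _fractional_identity(ra, rb)
    merges = linkage(squareform(dist, checks=False), method="average")

    profiles: dict[int, list[str]] = {i: [s.residues] for i, s in enumerate(seqs)}
    members: dict[int, list[int]] = {i: [i] for i in range(k)}
    for step, (a, b, _d, _n) in enumerate(merges):
        a, b = int(a), int(b)
        merged = _merge_profiles(profiles.pop(a), profiles.pop(b), mat,
                                 gap_open, gap_extend)
        profiles[k + step] = merged
        members[k + step] = members.pop(a) + members.pop(b)
    root = k + len(merges) - 1
    rows_by_input = dict(zip(members[root], profiles[root]))
    rows = tuple(rows_by_input[i] for i in range(k))
    aln = MultipleAlignment(
        row_accessions=tuple(s.accession for s in seqs), rows=rows)
    for i, s in enumerate(seqs):
        if aln.ungapped(i) != s.residues:
            raise AssertionError(
                f"alignment row for {s.accession} does not reproduce its input"
            )
    return aln


# ---------------------------------------------------------------------------
# trace projection and conservation

def project_traces(aln: MultipleAlignment,
                   traces: Sequence[DisorderTrace]) -> AlignedTraceMatrix:
    """Place each row's disorder scores at its non-gap columns; gaps -> 0.0."""
    if len(traces) != len(aln.rows):
        raise ValueError("need exactly one trace per alignment row")
    n_rows, n_cols = len(aln.rows), aln.n_columns
    values = np.zeros((n_rows, n_cols))
    gap_mask = np.zeros((n_rows, n_cols), dtype=bool)
    for r, (row, trace) in enumerate(zip(aln.rows, traces)):
        ungapped_len = len(row) - row.count(GAP)
        if len(trace) != ungapped_len:
            raise ValueError(
                f"{aln.row_accessions[r]}: trace length {len(trace)} != "
                f"ungapped row length {ungapped_len}"
            )
        k = 0
        for c, ch in enumerate(row):
            if ch == GAP:
                gap_mask[r, c] = True
            else:
                values[r, c] = trace.scores[k]
                k += 1
    return AlignedTraceMatrix(row_accessions=aln.row_accessions,
                              values=values, gap_mask=gap_mask)


def disorder_conservation(matrix: AlignedTraceMatrix,
                          query_accession: str,
                          ids_threshold: float = 0.5,
                          deletion_fraction: float = 0.5,
                          ) -> tuple[list[dict], list[DisorderSegment]]:
    """Per-column disorder summary and query disorder-segment report.

    Returns ``(columns, segments)``. ``columns`` holds one dict per
    alignment column with the fraction of non-gap rows above threshold and
    the mean score over non-gap rows. ``segments`` are the maximal runs of
    query residues scoring above ``ids_threshold``, each annotated with the
    mean fraction of *other* rows also disordered over those columns; a
    segment whose cross-row fraction is below ``deletion_fraction`` is
    flagged as a deletion candidate for construct design.
    """
    if query_accession not in matrix.row_accessions:
        raise ValueError(
            f"query {query_accession!r} not in matrix; available: "
            f"{', '.join(matrix.row_accessions)}"
        )
    q = matrix.row_accessions.index(query_accession)
    n_rows, n_cols = matrix.values.shape

    columns: list[dict] = []
    for c in range(n_cols):
        present = ~matrix.gap_mask[:, c]
        n_present = int(present.sum())
        vals = matrix.values[present, c]
        columns.append({
            "column": c + 1,
            "fraction_disordered": float((vals > ids_threshold).mean())
                                   if n_present else 0.0,
            "mean_score": float(vals.mean()) if n_present else 0.0,
        })

    others = [r for r in range(n_rows) if r != q]
    segments: list[DisorderSegment] = []
    run_cols: list[int] = []
    residue_index = 0            # 1-based query residue of current column
    run_start_res = run_end_res = 0

    def close_run() -> None:
        if not run_cols:
            return
        scores = matrix.values[q, run_cols]
        if others:
            frac = float(np.mean([
                (matrix.values[r, run_cols] > ids_threshold).mean()
                for r in others
            ]))
        else:
            frac = float("nan")
        deletion = (frac < deletion_fraction) if others else True
        segments.append(DisorderSegment(
            start=run_start_res, end=run_end_res,
            mean_score=float(scores.mean()),
            cross_row_fraction=frac,
            deletion_candidate=deletion,
        ))

    for c in range(n_cols):
        if matrix.gap_mask[q, c]:
            continue
        residue_index += 1
        if matrix.values[q, c] > ids_threshold:
            if not run_cols:
                run_start_res = residue_index
            run_cols.append(c)
            run_end_res = residue_index
        else:
            close_run()
            run_cols = []
    close_run()
    return columns, segments


# ---------------------------------------------------------------------------
# exports

def write_aligned_fasta(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, row in zip(aln.row_accessions, aln.rows):
            fh.write(f">{acc}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i:i + 60] + "\n")


def write_trace_matrix(matrix: AlignedTraceMatrix, path: str | Path) -> None:
    """TSV export: rows = accessions, columns = alignment positions."""
    with open(path, "w") as fh:
        header = "\t".join(["accession"]
                           + [str(i + 1) for i in range(matrix.n_columns)])
        fh.write(header + "\n")
        for acc, row in zip(matrix.row_accessions, matrix.values):
            fh.write(acc + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
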