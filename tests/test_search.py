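"""Local-alignment homology search and its E-value statistics."""

import math
import random

import pytest

from flexscan.search import (SearchParams, alignment_stats, load_matrix,
                             pairwise_local, search)
from flexscan.seqio import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def local_affine_oracle(a: str, b: str, matrix, gap_open: float,
                        gap_extend: float) -> int:
    """Reference Smith-Waterman with affine gaps, written independently.

    Three-state recurrence evaluated by explicit iteration over all cells;
    a gap of length k costs gap_open + k * gap_extend. Returns the best
    local score (0 if nothing positive).
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open - gap_extend)
            best = max(best, M[i][j])
    return int(round(best))


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


def test_local_alignment_matches_reference_dp():
    """Engine raw scores equal the independent affine Smith-Waterman."""
    rng = random.Random(42)
    params = SearchParams()
    matrix = load_matrix(params.matrix)
    for _ in range(60):
        a = random_protein(rng, rng.randint(4, 12))
        b = random_protein(rng, rng.randint(4, 12))
        expected = local_affine_oracle(a, b, matrix, params.gap_open,
                                       params.gap_extend)
        qa = SequenceRecord(accession="qa", residues=a)
        sb = SequenceRecord(accession="sb", residues=b)
        hit = pairwise_local(qa, sb, params, n_database=len(b))
        got = hit.raw_score if hit is not None else 0
        assert got == expected, f"{a} vs {b}: {got} != {expected}"


def test_self_hit_convention(family):
    """A library entry identical to the query gets E-value exactly 0, first."""
    query = family.ancestor
    hits = search(query, list(family.records), SearchParams(evalue_threshold=1e-5))
    assert hits[0].subject_accession == query.accession
    assert hits[0].evalue == 0.0
    assert hits[0].identity_pct == 100.0
    assert all(h.evalue > 0 for h in hits[1:])


def test_self_hit_by_sequence_identity():
    """Identical residues under a different accession still count as self."""
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
    query = SequenceRecord(accession="Q1", residues=seq)
    clone = SequenceRecord(accession="OTHER", residues=seq)
    hits = search(query, [clone], SearchParams())
    assert hits[0].evalue == 0.0


def test_no_local_similarity_gives_no_hit():
    query = SequenceRecord(accession="polyK", residues="K" * 30)
    subject = SequenceRecord(accession="polyD", residues="D" * 30)
    assert search(query, [subject], SearchParams(evalue_threshold=10.0)) == []


def test_empty_library_rejected(family):
    with pytest.raises(ValueError):
        search(family.ancestor, [], SearchParams())


@pytest.mark.parametrize(
    "qa, sa, expected",
    [
        ("ACDE", "ACDE", (100.0, 100.0)),
        ("AC-E", "ACDE", (75.0, 75.0)),   # gap column in the denominator
        ("KR", "RK", (0.0, 100.0)),       # conservative substitutions
    ],
)
def test_alignment_stats(qa, sa, expected):
    assert alignment_stats(qa, sa) == expected


def test_alignment_stats_length_mismatch():
    with pytest.raises(ValueError):
        alignment_stats("ACD", "AC")


def test_evalue_strictly_decreasing_in_score():
    params = SearchParams()
    evalues = [params.ka_K * 100 * 5000 * math.exp(-params.ka_lambda * s)
               for s in range(20, 200, 10)]
    assert all(a > b for a, b in zip(evalues, evalues[1:]))


def test_doubling_library_doubles_evalues(family):
    """E-values scale with total library size n, not per-subject length."""
    query = family.ancestor
    others = [r for r in family.records if r.accession != query.accession]
    params = SearchParams(evalue_threshold=1.0)
    single = search(query, others, params)
    renamed = [SequenceRecord(accession=r.accession + "_b", residues=r.residues,
                              gene_id=r.gene_id, species=r.species)
               for r in others]
    double = search(query, others + renamed, params)
    by_acc = {h.subject_accession: h for h in double}
    for hit in single:
        assert by_acc[hit.subject_accession].evalue == pytest.approx(
            2.0 * hit.evalue, rel=1e-12)


def test_threshold_and_max_hits_monotonicity(family):
    query = family.ancestor
    library = list(family.records)
    loose = search(query, library, SearchParams(evalue_threshold=1e-3))
    tight = search(query, library, SearchParams(evalue_threshold=1e-30))
    assert {h.subject_accession for h in tight} <= {
        h.subject_accession for h in loose}
    capped = search(query, library,
                    SearchParams(evalue_threshold=1e-3, max_hits=2))
    assert [h.subject_accession for h in capped] == [
        h.subject_accession for h in loose[:2]]


def test_hits_sorted_by_evalue_then_accession(family):
    hits = search(family.ancestor, list(family.records),
                  SearchParams(evalue_threshold=1e-3))
    keys = [(h.evalue, h.subject_accession) for h in hits]
    assert keys == sorted(keys)


def test_hit_invariants(family):
    for h in search(family.ancestor, list(family.records),
                    SearchParams(evalue_threshold=1e-3)):
        assert len(h.query_aln) == len(h.subject_aln)
        assert not any(a == b == "-" for a, b in zip(h.query_aln, h.subject_aln))
        assert h.identity_pct <= h.similarity_pct
        assert h.query_start <= h.query_end
        assert h.subject_start <= h.subject_end


def test_external_blast_adapter_agrees_on_ranks(tmp_path, family):
    """blastp (when installed) and the built-in engine return the same hit
    set in the same raw-score order; E-values themselves differ because the
    statistical models differ."""
    import shutil as _shutil

    from flexscan.search import MissingExecutableError, external_blast_adapter
    from flexscan.seqio import write_fasta

    lib_path = tmp_path / "lib.fasta"
    write_fasta(family.records, lib_path)
    params = SearchParams(evalue_threshold=1e-5)
    if _shutil.which("blastp") is None or _shutil.which("makeblastdb") is None:
        with pytest.raises(MissingExecutableError, match="built-in"):
            external_blast_adapter(family.ancestor, lib_path, params)
        return
    external = external_blast_adapter(family.ancestor, lib_path, params)
    builtin = search(family.ancestor, list(family.records), params)
    ext_order = [h.subject_accession for h in
                 sorted(external, key=lambda h: -h.raw_score)]
    builtin_order = [h.subject_accession for h in
                     sorted(builtin, key=lambda h: -h.raw_score)]
    assert ext_order == builtin_order
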