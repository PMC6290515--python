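"""Homology search over a FASTA library with local alignment and E-values.

Each library sequence is aligned to the query with an optimal affine-gap
Smith-Waterman alignment (BLOSUM62 by default, gap of length ``k`` costing
``gap_open + k * gap_extend``). Statistical significance follows the
Karlin-Altschul database-search model,

    E = K * m * n * exp(-lambda * S),

with ``m`` the query length, ``n`` the *total* residue count of the library
(so E-values are comparable across subjects, as in database search) and
``S`` the raw alignment score. The gapped BLOSUM62/11/1 parameters
lambda = 0.267 and K = 0.041 are used by default. When the query itself is
present in the library (same accession or identical sequence) its hit is
reported with E-value exactly 0 and listed first.

An adapter for an external NCBI BLAST+ ``blastp`` executable is provided for
cross-checking; it is optional and never required.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, write_fasta

__all__ = [
    "SearchHit",
    "SearchParams",
    "search",
    "alignment_stats",
    "pairwise_local",
    "external_blast_adapter",
    "MissingExecutableError",
]


class MissingExecutableError(RuntimeError):
    """An optional external tool (blastp) is not on PATH."""


@dataclass(frozen=True)
class SearchParams:
    """Search configuration; defaults mirror a BLOSUM62/11/1 BLASTP setup."""

    evalue_threshold: float = 1e-10
    max_hits: int = 100
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = 0.267
    ka_K: float = 0.041

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")


@dataclass(frozen=True)
class SearchHit:
    """One homology hit with alignment, statistics and 1-based coordinates."""

    subject_accession: str
    evalue: float
    bitscore: float
    raw_score: int
    identity_pct: float
    similarity_pct: float
    query_aln: str
    subject_aln: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int

    def __post_init__(self) -> None:
        if len(self.query_aln) != len(self.subject_aln):
            raise ValueError("aligned strings must have equal length")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@lru_cache(maxsize=4)
def load_matrix(name: str) -> substitution_matrices.Array:
    """Load a substitution matrix, extending it with U (selenocysteine).

    BLOSUM62's alphabet lacks U; pairs involving letters outside the
    matrix's alphabet score 0, tolerating ambiguity without rewarding it.
    """
    base = substitution_matrices.load(name)
    if "U" in base.alphabet:
        return base
    alphabet = base.alphabet + "U"
    ext = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in base.alphabet:
        for b in base.alphabet:
            ext[a, b] = base[a, b]
    return ext


def _make_aligner(params: SearchParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = load_matrix(params.matrix)
    aligner.mode = mode
    # a gap of length k costs gap_open + k*gap_extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def alignment_stats(query_aln: str, subject_aln: str,
                    matrix: str = "BLOSUM62") -> tuple[float, float]:
    """Percent identity and percent similarity of a gapped alignment pair.

    Both denominators are the full alignment length including gap columns.
    Similarity counts columns whose substitution score is positive
    (identities included).
    """
    if len(query_aln) != len(subject_aln):
        raise ValueError("aligned strings must have equal length")
    if not query_aln:
        raise ValueError("empty alignment")
    mat = load_matrix(matrix)
    n_cols = len(query_aln)
    n_ident = 0
    n_sim = 0
    for a, b in zip(query_aln, subject_aln):
        if a == "-" or b == "-":
            continue
        if a == b:
            n_ident += 1
        score = mat[a, b] if (a in mat.alphabet and b in mat.alphabet) else 0.0
        if score > 0:
            n_sim += 1
    return 100.0 * n_ident / n_cols, 100.0 * n_sim / n_cols


def _evalue(raw_score: float, m: int, n: int, params: SearchParams) -> float:
    return params.ka_K * m * n * math.exp(-params.ka_lambda * raw_score)


def _bitscore(raw_score: float, params: SearchParams) -> float:
    return (params.ka_lambda * raw_score - math.log(params.ka_K)) / math.log(2)


def pairwise_local(query: SequenceRecord, subject: SequenceRecord,
                   params: SearchParams, n_database: int) -> SearchHit | None:
    """Optimal local alignment of one subject; None if no positive score."""
    aligner = _make_aligner(params, "local")
    alignments = aligner.align(query.residues, subject.residues)
    try:
        best = alignments[0]
    except IndexError:
        return None
    raw = int(round(best.score))
    if raw <= 0:
        return None
    q_aln = str(best[0])
    s_aln = str(best[1])
    ident, sim = alignment_stats(q_aln, s_aln, params.matrix)
    coords = best.coordinates
    return SearchHit(
        subject_accession=subject.accession,
        evalue=_evalue(raw, len(query), n_database, params),
        bitscore=_bitscore(raw, params),
        raw_score=raw,
        identity_pct=ident,
        similarity_pct=sim,
        query_aln=q_aln,
        subject_aln=s_aln,
        query_start=int(coords[0][0]) + 1,
        query_end=int(coords[0][-1]),
        subject_start=int(coords[1][0]) + 1,
        subject_end=int(coords[1][-1]),
    )


def _is_self_hit(query: SequenceRecord, subject: SequenceRecord) -> bool:
    return (subject.accession == query.accession
            or subject.residues == query.residues)


def search(query: SequenceRecord, library: Sequence[SequenceRecord],
           params: SearchParams | None = None) -> list[SearchHit]:
    """Search a library for homologs of ``query``.

    Returns hits with ``evalue <= evalue_threshold`` sorted by ascending
    E-value (ties by accession), truncated to ``max_hits``. A library entry
    matching the query itself (same accession or identical sequence) is
    assigned E-value exactly 0 — the self-hit convention — and always ranks
    first.
    """
    if params is None:
        params = SearchParams()
    if not library:
        raise ValueError("library is empty")
    n_database = sum(len(rec) for rec in library)

    hits: list[SearchHit] = []
    for subject in library:
        hit = pairwise_local(query, subject, params, n_database)
        if hit is None:
            continue
        if _is_self_hit(query, subject):
            hit = SearchHit(**{**hit.__dict__, "evalue": 0.0})
            hits.append(hit)
        elif hit.evalue <= params.evalue_threshold:
            hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, h.subject_accession))
    return hits[: params.max_hits]


# ---------------------------------------------------------------------------
# optional external BLAST+ adapter


def external_blast_adapter(query: SequenceRecord, library_path: str | Path,
                           params: SearchParams | None = None) -> list[SearchHit]:
    """Run NCBI BLAST+ ``blastp`` against a FASTA library file.

    Optional cross-check path; raises :class:`MissingExecutableError` with a
    pointer to the built-in engine when blastp/makeblastdb are absent.
    Output hits have the same shape as :func:`search` results, one hit per
    subject (best HSP by E-value).
    """
    if params is None:
        params = SearchParams()
    for exe in ("blastp", "makeblastdb"):
        if shutil.which(exe) is None:
            raise MissingExecutableError(
                f"{exe} not found on PATH; use the built-in search() instead"
            )
    from Bio.Blast import NCBIXML  # deferred: only the adapter needs it

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db = tmp / "library.fasta"
        shutil.copy(library_path, db)
        subprocess.run(
            ["makeblastdb", "-in", str(db), "-dbtype", "prot"],
            check=True, capture_output=True,
        )
        query_fa = tmp / "query.fasta"
        write_fasta([query], query_fa)
        out_xml = tmp / "out.xml"
        subprocess.run(
            # composition-based statistics and SEG filtering are disabled so
            # the external engine scores with the plain substitution matrix,
            # comparable with the built-in Smith-Waterman
            ["blastp", "-query", str(query_fa), "-db", str(db),
             "-outfmt", "5", "-out", str(out_xml),
             "-evalue", str(params.evalue_threshold),
             "-max_target_seqs", str(params.max_hits),
             "-comp_based_stats", "0", "-seg", "no"],
            check=True, capture_output=True,
        )
        with open(out_xml) as fh:
            record = NCBIXML.read(fh)

    hits: list[SearchHit] = []
    for alignment in record.alignments:
        hsp = min(alignment.hsps, key=lambda h: h.expect)
        accession = alignment.hit_def.split()[0]
        if "|" in accession:
            parts = accession.split("|")
            accession = parts[1] if len(parts) >= 2 and parts[1] else parts[0]
        ident, sim = alignment_stats(hsp.query, hsp.sbjct, params.matrix)
        hits.append(SearchHit(
            subject_accession=accession,
            evalue=float(hsp.expect),
            bitscore=float(hsp.bits),
            raw_score=int(hsp.score),
            identity_pct=ident,
            similarity_pct=sim,
            query_aln=hsp.query,
            subject_aln=hsp.sbjct,
            query_start=hsp.query_start,
            query_end=hsp.query_end,
            subject_start=hsp.sbjct_start,
            subject_end=hsp.sbjct_end,
        ))
    hits.sort(key=lambda h: (h.evalue, h.subject_accession))
    return hits
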