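"""End-to-end screening runs: search -> disorder -> scoring -> report.

:func:`run_scan` takes a query and a FASTA library, finds homologs, scores
every hit's disorder content (built-in predictor or injected score files),
computes FLEX scores and writes a ranked TSV report. :func:`run_compare`
aligns selected hits, projects their disorder traces onto the alignment and
writes the conservation segment report. Both are deterministic: identical
configuration and inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import polyprotein as pp
from .disorder import DisorderTrace, IdsParams, ids, predict_trace, trace_from_scores
from .scoring import FlexParams, ScoredHit, flex_score, rank_hits
from .search import SearchHit, SearchParams, search
from .seqio import SequenceRecord, read_fasta, read_score_file
from .trace_align import (align_sequences, disorder_conservation,
                          project_traces, write_aligned_fasta,
                          write_trace_matrix)

__all__ = ["RunConfig", "ScanResult", "run_scan", "run_compare",
           "load_config", "REPORT_COLUMNS"]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["identifier", "gene_id", "species", "identity_pct",
                  "similarity_pct", "evalue", "ids_pct", "flex"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one screening run; defaults are the standard setup
    (E-value threshold 1e-10, at most 100 hits, priority coefficient 0.5,
    long-disorder mode, IDS threshold 0.5, sorted by E-value)."""

    query_path: str
    library_path: str
    output_dir: str
    evalue_threshold: float = 1e-10
    max_hits: int = 100
    eta: float = 0.5
    mode: str = "long"
    ids_threshold: float = 0.5
    sort_key: str = "evalue"
    chain_table_path: str | None = None
    score_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for label, path in (("query", self.query_path),
                            ("library", self.library_path)):
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.chain_table_path and not Path(self.chain_table_path).exists():
            raise FileNotFoundError(
                f"chain table not found: {self.chain_table_path}")
        # parameter ranges checked by the dataclasses they feed
        SearchParams(evalue_threshold=self.evalue_threshold,
                     max_hits=self.max_hits)
        FlexParams(eta=self.eta)
        IdsParams(threshold=self.ids_threshold)
        if self.mode not in ("long", "short"):
            raise ValueError(f"unknown disorder mode {self.mode!r}")
        if self.sort_key not in ("evalue", "flex", "ids"):
            raise ValueError(f"unknown sort key {self.sort_key!r}")


@dataclass(frozen=True)
class ScanResult:
    """Everything a scan produced, for downstream comparison runs."""

    query: SequenceRecord
    library: tuple[SequenceRecord, ...]
    scored: tuple[ScoredHit, ...]   # ranked, query row first when present
    table: pd.DataFrame
    report_path: Path


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML config file; keyword overrides win on conflict."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _trace_for(record: SequenceRecord, config: RunConfig) -> DisorderTrace:
    """Per-accession score file when provided, else the built-in predictor."""
    if config.score_dir:
        score_file = Path(config.score_dir) / f"{record.accession}.scores"
        if score_file.exists():
            scores = read_score_file(score_file)
            return trace_from_scores(record.accession, scores, record)
    return predict_trace(record, config.mode)


def _score_hit(hit: SearchHit, subject: SequenceRecord, config: RunConfig,
               chain_anns: dict[str, pp.ChainAnnotation]) -> ScoredHit:
    trace = _trace_for(subject, config)
    ids_params = IdsParams(threshold=config.ids_threshold)
    ann = chain_anns.get(subject.accession)
    if ann is not None:
        _name, start, end = pp.map_hit_to_fragment(hit, ann, len(subject))
        ids_pct = pp.fragment_scores(trace, (start, end), ids_params)
    else:
        ids_pct = ids(trace, ids_params)
    flex = flex_score(ids_pct, hit.evalue, FlexParams(eta=config.eta))
    return ScoredHit(hit=hit, ids_pct=ids_pct, flex=flex, trace=trace)


def _format_row(sh: ScoredHit, record: SequenceRecord) -> dict:
    return {
        "identifier": sh.accession,
        "gene_id": record.gene_id,
        "species": record.species,
        "identity_pct": f"{sh.hit.identity_pct:.1f}",
        "similarity_pct": f"{sh.hit.similarity_pct:.1f}",
        "evalue": "0" if sh.hit.evalue == 0 else f"{sh.hit.evalue:.2E}",
        "ids_pct": f"{sh.ids_pct:.3f}",
        "flex": f"{sh.flex:.4f}",
    }


def run_scan(config: RunConfig) -> ScanResult:
    """Run a full screen and write ``results.tsv`` to the output directory.

    The report has one row per hit (query row included, with E-value 0),
    sorted by ``config.sort_key``; FLEX is printed at 4 decimal places,
    IDS at 3, E-values in scientific notation.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    query = read_fasta(config.query_path)[0]
    library = read_fasta(config.library_path)
    logger.info("scan: query %s (%d aa) vs library of %d sequences",
                query.accession, len(query), len(library))

    params = SearchParams(evalue_threshold=config.evalue_threshold,
                          max_hits=config.max_hits)
    hits = search(query, library, params)
    logger.info("scan: %d hits pass E <= %.3g", len(hits),
                config.evalue_threshold)
    if not hits:
        logger.warning("scan: no hits pass the E-value threshold")

    chain_anns: dict[str, pp.ChainAnnotation] = {}
    if config.chain_table_path:
        chain_anns = {ann.accession: ann
                      for ann in pp.read_chain_table(config.chain_table_path)}

    by_accession = {rec.accession: rec for rec in library}
    scored = [_score_hit(hit, by_accession[hit.subject_accession],
                         config, chain_anns)
              for hit in hits]
    ranked = rank_hits(scored, config.sort_key)

    rows = [_format_row(sh, by_accession[sh.accession]) for sh in ranked]
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report_path = out_dir / "results.tsv"
    table.to_csv(report_path, sep="\t", index=False)
    logger.info("scan: report written to %s", report_path)
    return ScanResult(query=query, library=tuple(library),
                      scored=tuple(ranked), table=table,
                      report_path=report_path)


def run_compare(config: RunConfig, result: ScanResult,
                accessions: list[str]) -> dict[str, Path]:
    """Align selected hits, project disorder traces, report segments.

    ``accessions`` must come from the scan's results; the first one is the
    designated query row of the conservation report. Writes
    ``aligned.fasta``, ``trace_matrix.tsv`` and ``segments.tsv`` and
    returns their paths.
    """
    available = {sh.accession for sh in result.scored}
    unknown = [a for a in accessions if a not in available]
    if unknown:
        raise ValueError(
            f"unknown accession(s) {', '.join(unknown)}; available: "
            f"{', '.join(sorted(available))}"
        )
    by_accession = {rec.accession: rec for rec in result.library}
    traces = {sh.accession: sh.trace for sh in result.scored}
    seqs = [by_accession[a] for a in accessions]

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if len(seqs) == 1:
        raise ValueError("comparison needs at least 2 accessions")
    aln = align_sequences(seqs)
    matrix = project_traces(aln, [traces[a] for a in accessions])
    _cols, segments = disorder_conservation(
        matrix, accessions[0], ids_threshold=config.ids_threshold)

    paths = {
        "alignment": out_dir / "aligned.fasta",
        "matrix": out_dir / "trace_matrix.tsv",
        "segments": out_dir / "segments.tsv",
    }
    write_aligned_fasta(aln, paths["alignment"])
    write_trace_matrix(matrix, paths["matrix"])
    with open(paths["segments"], "w") as fh:
        fh.write("start\tend\tmean_score\tcross_row_fraction\t"
                 "deletion_candidate\n")
        for seg in segments:
            fh.write(f"{seg.start}\t{seg.end}\t{seg.mean_score:.4f}\t"
                     f"{seg.cross_row_fraction:.4f}\t"
                     f"{seg.deletion_candidate}\n")
    logger.info("compare: %d sequences aligned, %d query disorder segments",
                len(seqs), len(segments))
    return paths
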