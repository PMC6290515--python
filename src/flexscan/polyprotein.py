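"""Virtual processing of viral polyprotein hits into mature-peptide chains.

Many viral proteomes are translated as one long polyprotein that proteases
cleave into mature peptides (chains). A homology hit that lands on an
unprocessed polyprotein should be scored on the mature peptide it overlaps,
not on the whole translate. Chain boundaries are supplied as a local
tab-separated table (accession, chain_name, start, end; 1-based inclusive,
mirroring UniProt CHAIN features). The chain with maximal residue overlap
with the hit's subject interval is selected; with no overlapping chain the
whole sequence is used and a warning logged. IDS is then recomputed over
the fragment only; the hit's E-value is kept as computed on the full
subject sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .disorder import DisorderTrace, IdsParams, ids, trace_from_scores
from .search import SearchHit

__all__ = [
    "Chain",
    "ChainAnnotation",
    "ChainTableError",
    "read_chain_table",
    "map_hit_to_fragment",
    "fragment_scores",
]

logger = logging.getLogger(__name__)


class ChainTableError(ValueError):
    """A chain-annotation row is malformed or out of range."""


@dataclass(frozen=True)
class Chain:
    """One mature peptide: name and 1-based inclusive parent coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ChainTableError(
                f"chain {self.name!r}: invalid interval [{self.start}, {self.end}]"
            )

    def overlap(self, start: int, end: int) -> int:
        """Residue overlap with a 1-based inclusive interval."""
        return max(0, min(self.end, end) - max(self.start, start) + 1)


@dataclass(frozen=True)
class ChainAnnotation:
    """All annotated chains of one polyprotein, sorted by start."""

    accession: str
    chains: tuple[Chain, ...]
    has_overlapping_chains: bool = False

    @staticmethod
    def from_chains(accession: str, chains: list[Chain]) -> "ChainAnnotation":
        chains = sorted(chains, key=lambda c: (c.start, c.end))
        overlapping = any(
            a.overlap(b.start, b.end) > 0
            for a, b in zip(chains, chains[1:])
        )
        return ChainAnnotation(accession=accession, chains=tuple(chains),
                               has_overlapping_chains=overlapping)


def read_chain_table(path: str | Path) -> list[ChainAnnotation]:
    """Read a chain TSV (accession, chain_name, start, end) into annotations.

    Rows are grouped by accession and chains sorted by start. Coordinate
    errors name the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    grouped: dict[str, list[Chain]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ChainTableError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            accession, name, start_s, end_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ChainTableError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}, {end_s!r}"
                ) from None
            if start < 1 or end < start:
                raise ChainTableError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}] "
                    f"for {accession}/{name}"
                )
            if accession not in grouped:
                grouped[accession] = []
                order.append(accession)
            grouped[accession].append(Chain(name=name, start=start, end=end))
    return [ChainAnnotation.from_chains(acc, grouped[acc]) for acc in order]


def map_hit_to_fragment(hit: SearchHit,
                        ann: ChainAnnotation,
                        sequence_length: int | None = None,
                        ) -> tuple[str, int, int]:
    """Select the chain the hit belongs to by maximal residue overlap.

    Returns ``(chain_name, start, end)`` in 1-based inclusive parent
    coordinates. With no overlapping chain (or no chains at all) the whole
    sequence is returned under the name ``"whole-sequence"`` with a logged
    warning; ties on overlap go to the chain with the smaller start.
    ``sequence_length`` bounds the fallback interval; when omitted, the
    hit's subject end is used as a lower bound on the parent length.
    """
    best: Chain | None = None
    best_overlap = 0
    for chain in ann.chains:
        ov = chain.overlap(hit.subject_start, hit.subject_end)
        if ov > best_overlap:
            best, best_overlap = chain, ov
    if best is None:
        end = sequence_length if sequence_length else hit.subject_end
        logger.warning(
            "%s: no annotated chain overlaps hit interval [%d, %d]; "
            "using whole sequence", ann.accession,
            hit.subject_start, hit.subject_end,
        )
        return "whole-sequence", 1, end
    return best.name, best.start, best.end


def fragment_scores(trace: DisorderTrace, fragment: tuple[int, int],
                    ids_params: IdsParams | None = None) -> float:
    """IDS over a 1-based inclusive fragment of a trace only."""
    start, end = fragment
    if start < 1 or end > len(trace) or end < start:
        raise ValueError(
            f"fragment [{start}, {end}] outside trace of length {len(trace)}"
        )
    sub = trace_from_scores(f"{trace.accession}[{start}-{end}]",
                            trace.scores[start - 1:end])
    return ids(sub, ids_params)
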