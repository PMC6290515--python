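"""FASTA input/output and UniProt-style header parsing.

Sequence libraries are plain multi-record FASTA files. Definition lines may
use the UniProt convention ``>db|ACCESSION|ENTRYNAME Description OS=Species
GN=Gene`` or be bare tokens; both parse into :class:`SequenceRecord`.
Per-residue disorder scores produced by an external predictor can be read
from simple one-score-per-line text files via :func:`read_score_file`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "FastaFormatError",
    "ScoreFileError",
    "parse_uniprot_header",
    "read_fasta",
    "write_fasta",
    "read_score_file",
    "write_score_file",
]

#: Residue letters accepted on input: the 20 standard amino acids plus the
#: ambiguity codes B (Asx), Z (Glx), X (any) and U (selenocysteine).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU")


class FastaFormatError(ValueError):
    """A FASTA entry violates the format contract (empty sequence, bad letter)."""


class ScoreFileError(ValueError):
    """A per-residue score file is malformed or holds out-of-range values."""


@dataclass(frozen=True)
class SequenceRecord:
    """An amino-acid sequence with UniProt-style identity metadata.

    Attributes
    ----------
    accession:
        Primary identifier, e.g. ``"O00311"``; unique within one library.
    gene_id:
        Gene name from the ``GN=`` header tag, or ``""`` when absent.
    species:
        Organism from the ``OS=`` header tag, or ``""`` when absent.
    description:
        Free-text remainder of the definition line.
    residues:
        Uppercase sequence over the 20 standard letters plus X/B/Z/U.
    """

    accession: str
    residues: str
    gene_id: str = ""
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.accession}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = [(i, c) for i, c in enumerate(self.residues, start=1)
               if c not in VALID_RESIDUES]
        if bad:
            pos, char = bad[0]
            raise FastaFormatError(
                f"{self.accession}: invalid residue {char!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


# "sp|O00311|CDC7_HUMAN" or "tr|A0A000|A0A000_9ZZZZ"
_DB_PREFIX = re.compile(r"^(sp|tr)\|([^|\s]+)\|(\S+)")
# OS runs until the next KEY= tag or end of line; GN is a single token.
_OS_TAG = re.compile(r"\bOS=(.+?)(?=\s+\w{2}=|$)")
_GN_TAG = re.compile(r"\bGN=(\S+)")


def parse_uniprot_header(header: str) -> tuple[str, str, str, str]:
    """Split a FASTA definition line (text after ``>``) into metadata fields.

    Returns ``(accession, gene_id, species, description)``. UniProt
    ``sp|ACC|ENTRY`` / ``tr|ACC|ENTRY`` prefixes and ``OS=`` / ``GN=`` tags
    are recognised; for a bare header the first whitespace-delimited token
    becomes the accession and the other fields are empty.
    """
    header = header.strip()
    if not header:
        raise FastaFormatError("empty FASTA header")

    m = _DB_PREFIX.match(header)
    if m:
        accession = m.group(2)
        rest = header[m.end():].strip()
    else:
        parts = header.split(None, 1)
        accession = parts[0]
        rest = parts[1].strip() if len(parts) > 1 else ""

    species = ""
    gene_id = ""
    os_m = _OS_TAG.search(rest)
    if os_m:
        species = os_m.group(1).strip()
    gn_m = _GN_TAG.search(rest)
    if gn_m:
        gene_id = gn_m.group(1)

    # description = annotation text before the first KEY= tag
    tag_m = re.search(r"\s*\b\w{2}=", rest)
    description = rest[: tag_m.start()].strip() if tag_m else rest
    return accession, gene_id, species, description


def _record_from_seqio(rec: SeqRecord) -> SequenceRecord:
    header = rec.description if rec.description else rec.id
    accession, gene_id, species, description = parse_uniprot_header(header)
    raw = str(rec.seq)
    residues = re.sub(r"[\s\d]", "", raw).upper()
    if not residues:
        raise FastaFormatError(f"entry {header!r}: empty sequence")
    return SequenceRecord(
        accession=accession,
        residues=residues,
        gene_id=gene_id,
        species=species,
        description=description,
    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA library into :class:`SequenceRecord` objects, in file order.

    Whitespace and digits inside sequences are stripped and letters
    uppercased. Raises :class:`FileNotFoundError` for a missing file and
    :class:`FastaFormatError` for empty sequences or invalid residue letters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records = [_record_from_seqio(rec) for rec in SeqIO.parse(str(path), "fasta")]
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise FastaFormatError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    return records


def _format_header(rec: SequenceRecord) -> str:
    parts = [rec.accession]
    if rec.description:
        parts.append(rec.description)
    if rec.species:
        parts.append(f"OS={rec.species}")
    if rec.gene_id:
        parts.append(f"GN={rec.gene_id}")
    return " ".join(parts)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records to FASTA; metadata re-emitted as OS=/GN= tags."""
    seqio_records = [
        SeqRecord(Seq(rec.residues), id=rec.accession,
                  description=_format_header(rec)[len(rec.accession):].strip())
        for rec in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqio_records)


def read_score_file(path: str | Path) -> list[float]:
    """Read per-residue disorder scores, one residue per line.

    Accepts either a single score per line or an ``index score`` pair
    (the index column is ignored; residue order is file order). All scores
    must lie in [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) > 2:
                raise ScoreFileError(
                    f"{path}:{lineno}: expected 'score' or 'index score', "
                    f"got {len(tokens)} fields"
                )
            token = tokens[-1]
            try:
                value = float(token)
            except ValueError:
                raise ScoreFileError(
                    f"{path}:{lineno}: non-numeric score {token!r}"
                ) from None
            if not 0.0 <= value <= 1.0:
                raise ScoreFileError(
                    f"{path}:{lineno}: score {value} outside [0, 1]"
                )
            scores.append(value)
    if not scores:
        raise ScoreFileError(f"{path}: no scores found")
    return scores


def write_score_file(scores: Iterable[float], path: str | Path) -> None:
    """Write a two-column (index, score) per-residue score file."""
    with open(path, "w") as fh:
        for i, s in enumerate(scores, start=1):
            fh.write(f"{i}\t{s:.6f}\n")
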