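"""Deterministic synthetic homolog families and disorder-score profiles.

Generates test inputs for every pipeline stage without any downloads:

* an ancestor sequence built from block-wise composition pools — disordered
  blocks draw from the polar/charged pool {E, K, S, P, Q, G}, ordered blocks
  from the hydrophobic pool {L, I, V, F, W, Y, A, M};
* descendants derived by seeded point substitutions (within the block's
  pool, preserving the order/disorder architecture) and indels;
* per-residue disorder-score profiles emulating an external predictor's
  output: scores centered at 0.8 inside disordered blocks and 0.2 inside
  ordered blocks, with uniform noise of configurable half-width.

Because the true block structure is known, ground-truth IDS values are exact
block arithmetic, enabling exact-expectation tests. A single integer seed
drives all randomness; identical seeds give byte-identical output. No
attempt is made to simulate realistic evolution (no substitution-matrix
mutation model, no rate heterogeneity).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import SequenceRecord, write_fasta, write_score_file

__all__ = [
    "DisorderBlock",
    "FixtureSpec",
    "Family",
    "make_family",
    "make_score_profile",
    "write_family",
    "DISORDERED_POOL",
    "ORDERED_POOL",
]

DISORDERED_POOL = "EKSPQG"
ORDERED_POOL = "LIVFWYAM"


@dataclass(frozen=True)
class DisorderBlock:
    """One architectural block: 1-based inclusive bounds and its kind."""

    start: int
    end: int
    kind: str  # "ordered" | "disordered"

    def __post_init__(self) -> None:
        if self.kind not in ("ordered", "disordered"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid block [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic homolog family.

    ``substitution_rate`` and ``indel_rate`` are per-residue per-lineage
    probabilities; ``disorder_blocks`` must tile within ``ancestor_length``
    without overlap (uncovered stretches default to ordered composition).
    ``noise_width`` is the half-width of the uniform noise added to the
    0.8/0.2 block centers of score profiles.
    """

    seed: int = 0
    family_size: int = 6
    ancestor_length: int = 400
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    disorder_blocks: tuple[DisorderBlock, ...] = ()
    noise_width: float = 0.1

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be >= 1")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if not 0.0 <= self.noise_width <= 0.5:
            raise ValueError("noise_width must be in [0, 0.5]")
        blocks = sorted(self.disorder_blocks, key=lambda b: b.start)
        prev_end = 0
        for b in blocks:
            if b.start <= prev_end:
                raise ValueError("disorder_blocks overlap")
            if b.end > self.ancestor_length:
                raise ValueError("disorder_blocks exceed ancestor_length")
            prev_end = b.end
        object.__setattr__(self, "disorder_blocks", tuple(blocks))


@dataclass(frozen=True)
class Family:
    """A generated family: records plus per-member ground truth."""

    records: tuple[SequenceRecord, ...]
    #: accession -> list of (start, end, kind) blocks on that member's sequence
    truth: dict[str, tuple[DisorderBlock, ...]]
    #: accession -> ground-truth IDS percent (disordered residue fraction x 100)
    true_ids: dict[str, float]

    @property
    def ancestor(self) -> SequenceRecord:
        return self.records[0]


def _block_kinds(spec: FixtureSpec) -> np.ndarray:
    """Per-residue kind array for the ancestor: True where disordered."""
    disordered = np.zeros(spec.ancestor_length, dtype=bool)
    for b in spec.disorder_blocks:
        if b.kind == "disordered":
            disordered[b.start - 1:b.end] = True
    return disordered


def _kinds_to_blocks(disordered: np.ndarray) -> tuple[DisorderBlock, ...]:
    blocks: list[DisorderBlock] = []
    start = 0
    for i in range(1, len(disordered) + 1):
        if i == len(disordered) or disordered[i] != disordered[start]:
            kind = "disordered" if disordered[start] else "ordered"
            blocks.append(DisorderBlock(start=start + 1, end=i, kind=kind))
            start = i
    return tuple(blocks)


def _draw_sequence(rng: np.random.Generator, disordered: np.ndarray) -> str:
    chars = []
    for is_dis in disordered:
        pool = DISORDERED_POOL if is_dis else ORDERED_POOL
        chars.append(pool[rng.integers(len(pool))])
    return "".join(chars)


def _mutate(rng: np.random.Generator, residues: str,
            disordered: np.ndarray, sub_rate: float,
            indel_rate: float) -> tuple[str, np.ndarray]:
    """Point substitutions within the residue's pool, then indels.

    Deletions remove single residues; insertions add a single residue of
    the local kind. The returned kind array tracks the edited sequence so
    ground truth stays exact.
    """
    chars = list(residues)
    kinds = list(disordered)
    if sub_rate > 0:
        for i in range(len(chars)):
            if rng.random() < sub_rate:
                pool = DISORDERED_POOL if kinds[i] else ORDERED_POOL
                choices = [c for c in pool if c != chars[i]]
                chars[i] = choices[rng.integers(len(choices))]
    if indel_rate > 0:
        out_chars: list[str] = []
        out_kinds: list[bool] = []
        for i in range(len(chars)):
            if rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                pool = DISORDERED_POOL if kinds[i] else ORDERED_POOL
                out_chars.append(pool[rng.integers(len(pool))])
                out_kinds.append(kinds[i])
            out_chars.append(chars[i])
            out_kinds.append(kinds[i])
        chars, kinds = out_chars, out_kinds
    if not chars:  # pathological: everything deleted; keep one residue
        chars, kinds = [residues[0]], [bool(disordered[0])]
    return "".join(chars), np.array(kinds, dtype=bool)


def make_family(spec: FixtureSpec) -> Family:
    """Generate a homolog family with known order/disorder architecture.

    Member 0 (accession ``FAM{seed}A``) is the ancestor; members 1..k-1 are
    independent descendants of it. Ground truth records each member's block
    structure after its own edits.
    """
    rng = np.random.default_rng(spec.seed)
    anc_kinds = _block_kinds(spec)
    ancestor_seq = _draw_sequence(rng, anc_kinds)

    records: list[SequenceRecord] = []
    truth: dict[str, tuple[DisorderBlock, ...]] = {}
    true_ids: dict[str, float] = {}

    def add(accession: str, seq: str, kinds: np.ndarray, idx: int) -> None:
        records.append(SequenceRecord(
            accession=accession, residues=seq,
            gene_id=f"fam{spec.seed}",
            species=f"Synthetic taxon {idx}",
            description="synthetic homolog",
        ))
        truth[accession] = _kinds_to_blocks(kinds)
        true_ids[accession] = 100.0 * float(kinds.mean())

    add(f"FAM{spec.seed}A", ancestor_seq, anc_kinds, 0)
    for i in range(1, spec.family_size):
        seq, kinds = _mutate(rng, ancestor_seq, anc_kinds,
                             spec.substitution_rate, spec.indel_rate)
        add(f"FAM{spec.seed}D{i}", seq, kinds, i)
    return Family(records=tuple(records), truth=truth, true_ids=true_ids)


def make_score_profile(spec: FixtureSpec, family: Family,
                       accession: str) -> list[float]:
    """Emulated per-residue predictor output for one family member.

    Disordered residues score 0.8 +/- noise_width, ordered residues
    0.2 +/- noise_width (uniform, clamped to [0, 1]). The noise stream is
    seeded by ``(spec.seed, accession)`` so profiles are reproducible and
    member-independent.
    """
    if accession not in family.truth:
        raise KeyError(f"unknown accession {accession!r}; family has: "
                       f"{', '.join(family.truth)}")
    sub_seed = zlib.crc32(accession.encode()) % (2**31)
    rng = np.random.default_rng([spec.seed, sub_seed])
    scores: list[float] = []
    for block in family.truth[accession]:
        center = 0.8 if block.kind == "disordered" else 0.2
        noise = rng.uniform(-spec.noise_width, spec.noise_width, len(block))
        scores.extend(float(np.clip(center + x, 0.0, 1.0)) for x in noise)
    return scores


def write_family(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write a family as FASTA + per-member score files + ground-truth TSV.

    Returns the FASTA path. Score files are ``<accession>.scores`` beside
    it; ground truth goes to ``truth.tsv`` (accession, start, end, kind,
    true_ids_pct).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    family = make_family(spec)
    fasta = out_dir / "family.fasta"
    write_fasta(family.records, fasta)
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("accession\tstart\tend\tkind\ttrue_ids_pct\n")
        for rec in family.records:
            for b in family.truth[rec.accession]:
                fh.write(f"{rec.accession}\t{b.start}\t{b.end}\t{b.kind}\t"
                         f"{family.true_ids[rec.accession]:.3f}\n")
    for rec in family.records:
        scores = make_score_profile(spec, family, rec.accession)
        write_score_file(scores, out_dir / f"{rec.accession}.scores")
    return fasta
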