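"""Per-residue disorder traces and the IDS disorder-content statistic.

The disorder predictor is pluggable. The built-in default is a windowed
composition heuristic: over a centered window (101 residues in ``long``
mode, 25 in ``short``, truncated at the termini) the score is

    clamp01( A  -  B * mean_hydropathy  +  C * |mean_net_charge| )

with Kyte-Doolittle hydropathy and net charge (K, R = +1; D, E = -1).
Constants A = 0.45, B = 0.12, C = 0.5 are calibrated so that low-complexity
polar/charged stretches (poly-E/K/S/P) score above 0.5 while hydrophobic
globular cores score below it. This heuristic captures the composition
signal that dedicated energy-based predictors such as IUPred exploit, but
makes no claim of accuracy parity with them; genuine predictor output can
be injected instead via :func:`trace_from_scores` and
:func:`flexscan.seqio.read_score_file`.

The intrinsic disorder score (IDS) of a trace is the percentage of residues
whose score strictly exceeds a threshold (default 0.5):

    IDS = 100 * #{r : s_r > threshold} / l
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "DisorderTrace",
    "IdsParams",
    "predict_trace",
    "trace_from_scores",
    "ids",
    "WINDOW_SIZES",
    "HYDROPATHY",
]

#: Kyte-Doolittle hydropathy index; ambiguity codes get neutral/average values.
HYDROPATHY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
    "B": -3.5, "Z": -3.5, "X": 0.0, "U": 2.5,
}

_CHARGE: dict[str, float] = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

#: Centered-window sizes for the two prediction contexts.
WINDOW_SIZES: dict[str, int] = {"long": 101, "short": 25}

# heuristic calibration constants (see module docstring)
_A, _B, _C = 0.45, 0.12, 0.5


@dataclass(frozen=True)
class DisorderTrace:
    """Ordered per-residue disorder scores in [0, 1] for one sequence."""

    accession: str
    scores: tuple[float, ...]
    mode: str = "external"

    def __post_init__(self) -> None:
        if len(self.scores) == 0:
            raise ValueError(f"{self.accession}: empty disorder trace")
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        for i, s in enumerate(self.scores, start=1):
            if not 0.0 <= s <= 1.0:
                raise ValueError(
                    f"{self.accession}: score {s} at residue {i} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class IdsParams:
    """IDS computation parameters: the per-residue disorder cut."""

    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


def predict_trace(seq: SequenceRecord, mode: str = "long") -> DisorderTrace:
    """Built-in composition-heuristic disorder trace (deterministic).

    ``mode`` selects the window: ``long`` (101 residues) for extended
    disordered regions, ``short`` (25) for short linker-scale disorder.
    """
    if mode not in WINDOW_SIZES:
        raise ValueError(f"unknown mode {mode!r}; expected one of "
                         f"{sorted(WINDOW_SIZES)}")
    window = WINDOW_SIZES[mode]
    half = window // 2
    n = len(seq)
    hydro = np.array([HYDROPATHY[c] for c in seq.residues])
    charge = np.array([_CHARGE.get(c, 0.0) for c in seq.residues])
    # prefix sums for O(n) windowed means with truncation at the termini
    cum_h = np.concatenate([[0.0], np.cumsum(hydro)])
    cum_c = np.concatenate([[0.0], np.cumsum(charge)])
    scores = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        width = hi - lo
        mean_h = (cum_h[hi] - cum_h[lo]) / width
        mean_c = (cum_c[hi] - cum_c[lo]) / width
        scores[i] = _A - _B * mean_h + _C * abs(mean_c)
    np.clip(scores, 0.0, 1.0, out=scores)
    return DisorderTrace(accession=seq.accession, scores=tuple(scores),
                         mode=mode)


def trace_from_scores(accession: str, scores: Sequence[float],
                      sequence: SequenceRecord | None = None) -> DisorderTrace:
    """Wrap externally computed per-residue scores as a trace.

    If ``sequence`` is given, the score count must match its length.
    """
    if sequence is not None and len(scores) != len(sequence):
        raise ValueError(
            f"{accession}: {len(scores)} scores for a "
            f"{len(sequence)}-residue sequence"
        )
    return DisorderTrace(accession=accession, scores=tuple(scores),
                         mode="external")


def ids(trace: DisorderTrace, params: IdsParams | None = None) -> float:
    """Intrinsic disorder score: percent of residues strictly above threshold.

    A residue scoring exactly at the threshold counts as ordered (the
    inequality is strict). Range [0, 100].
    """
    if params is None:
        params = IdsParams()
    l = len(trace)
    n_disordered = sum(1 for s in trace.scores if s > params.threshold)
    return 100.0 * n_disordered / l
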