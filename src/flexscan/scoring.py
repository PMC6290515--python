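"""The E-value hyperbolic transform, the hybrid FLEX score and hit ranking.

The FLEX score combines homology strength and intrinsic structural order
into one number in [0, 1]:

    FLEX = (1 - eta) * t(E) + eta * (1 - IDS/100)

where ``t(E) = 1 - 0.99^((-log10 E)^2)`` is a sigmoidal transform of the
E-value and ``eta`` (the priority coefficient, in [0, 1]) shifts the weight
between the homology component (eta -> 0) and structural order (eta -> 1).
IDS enters as a fraction so that FLEX stays in [0, 1]. The transform
converges the extreme low-end E-value range while resolving the middle:
it is near-linear in -log10(E) between E = 1e-3 and 1e-14 and its tails
approach 0 (E -> 1) and 1 (E -> 0). E = 0, the self-hit convention, maps to
t = 1 (the limit).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .disorder import DisorderTrace
from .search import SearchHit

__all__ = [
    "FlexParams",
    "ScoredHit",
    "evalue_transform",
    "flex_score",
    "rank_hits",
    "screen_summary",
    "bin_improvements",
    "TRANSFORM_BASE",
]

#: Fixed base of the hyperbolic E-value transform.
TRANSFORM_BASE = 0.99


@dataclass(frozen=True)
class FlexParams:
    """FLEX weighting: ``eta`` is the priority coefficient in [0, 1]."""

    eta: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")


@dataclass(frozen=True)
class ScoredHit:
    """A search hit joined with its disorder trace, IDS (percent) and FLEX."""

    hit: SearchHit
    ids_pct: float
    flex: float
    trace: DisorderTrace

    @property
    def accession(self) -> str:
        return self.hit.subject_accession


def evalue_transform(evalue: float) -> float:
    """Hyperbolic transform of an E-value onto [0, 1].

    t(E) = 1 - 0.99^((-log10 E)^2) for E > 0; t(0) = 1 by the limiting
    convention (self hits). For E >= 1 the squared exponent is still
    non-negative, so t stays in [0, 1] with no clamping; note the square
    makes t rise again for E > 1, which the E-value threshold (always
    well below 1) keeps out of scope.
    """
    if evalue < 0:
        raise ValueError("evalue must be >= 0")
    if evalue == 0:
        return 1.0
    exponent = math.log10(evalue) ** 2
    return 1.0 - TRANSFORM_BASE ** exponent


def flex_score(ids_pct: float, evalue: float,
               params: FlexParams | None = None) -> float:
    """FLEX = (1 - eta) * t(E) + eta * (1 - IDS/100); result in [0, 1]."""
    if params is None:
        params = FlexParams()
    if not 0.0 <= ids_pct <= 100.0:
        raise ValueError("ids_pct must be in [0, 100]")
    order_term = 1.0 - ids_pct / 100.0
    return (1.0 - params.eta) * evalue_transform(evalue) + params.eta * order_term


_SORT_KEYS = {
    # key -> (value extractor, descending?)
    "evalue": (lambda sh: sh.hit.evalue, False),
    "flex": (lambda sh: sh.flex, True),
    "ids": (lambda sh: sh.ids_pct, False),
}


def rank_hits(hits: Sequence[ScoredHit], sort_key: str = "evalue") -> list[ScoredHit]:
    """Stable sort of scored hits: evalue ascending, flex descending or ids
    ascending; ties broken by accession."""
    if sort_key not in _SORT_KEYS:
        raise ValueError(f"unknown sort key {sort_key!r}; expected one of "
                         f"{sorted(_SORT_KEYS)}")
    extract, descending = _SORT_KEYS[sort_key]
    sign = -1.0 if descending else 1.0
    return sorted(hits, key=lambda sh: (sign * extract(sh), sh.accession))


def screen_summary(query: ScoredHit,
                   hits: Sequence[ScoredHit]) -> tuple[int, list[float]]:
    """Count superior homologs and their IDS improvements over the query.

    A hit is superior when its FLEX score strictly exceeds the query's
    (both scored under the same FlexParams). The improvement for each
    superior hit is ``query IDS - hit IDS`` in percentage points (positive
    when the hit is more ordered).
    """
    superior = [sh for sh in hits
                if sh.flex > query.flex and sh.accession != query.accession]
    improvements = [query.ids_pct - sh.ids_pct for sh in superior]
    return len(superior), improvements


def bin_improvements(improvements: Sequence[float],
                     width: float = 5.0) -> dict[float, int]:
    """Bucket IDS improvements into ``width``-point bins (default 5).

    Bin key is the lower edge: an improvement of 17.3 falls in bin 15.0.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    counts = Counter(math.floor(x / width) * width for x in improvements)
    return dict(sorted(counts.items()))
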