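"""Exact reference computations: full Levenshtein DP with traceback,
the suffix-vs-text-prefix distance used by the bit-semantics tests, and
an affine-gap CIGAR scorer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import InputError
from .windowing import CigarOp, canonicalize_cigar, parse_cigar


@dataclass(frozen=True)
class ScoringParams:
    """Single-affine gap model: ``match*(= bases) - mismatch*(X bases)
    - sum over maximal I/D runs of (open + extend*len)``.

    The defaults approximate minimap2's default model with one gap class.
    """

    match_score: int = 2
    mismatch_penalty: int = 4
    gap_open_penalty: int = 4
    gap_extend_penalty: int = 2

    def __post_init__(self) -> None:
        if min(self.match_score, self.mismatch_penalty,
               self.gap_open_penalty, self.gap_extend_penalty) < 0:
            raise InputError("scoring parameters must be non-negative")


def levenshtein_matrix(a: str, b: str) -> np.ndarray:
    """Full (len(a)+1) x (len(b)+1) unit-cost edit-distance table,
    filled row-wise with vectorized running-minimum updates."""
    n, m = len(a), len(b)
    dist = np.empty((n + 1, m + 1), dtype=np.int32)
    dist[0] = np.arange(m + 1, dtype=np.int32)
    if m == 0:
        dist[:, 0] = np.arange(n + 1, dtype=np.int32)
        return dist
    bs = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    col = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        cost = (bs != ord(a[i - 1])).astype(np.int32)
        best = np.minimum(dist[i - 1, 1:] + 1, dist[i - 1, :-1] + cost)
        # fold in the left-to-right dependency: dist[i, j] is the minimum
        # over k <= j of base[k] + (j - k)
        base = np.concatenate(([i], best)).astype(np.int32)
        dist[i] = np.minimum.accumulate(base - col) + col
    return dist


def levenshtein_distance(a: str, b: str) -> int:
    return int(levenshtein_matrix(a, b)[len(a), len(b)])


def levenshtein_align(a: str, b: str) -> tuple[int, list[CigarOp]]:
    """Exact edit distance and one attaining CIGAR.

    ``a`` plays the text/reference role, ``b`` the pattern/read role
    (D consumes ``a``, I consumes ``b``).  Ties are broken by preferring
    the diagonal (=/X), then D, then I, so output is reproducible.
    """
    dist = levenshtein_matrix(a, b)
    i, j = len(a), len(b)
    letters = []
    while i > 0 or j > 0:
        here = dist[i, j]
        if i > 0 and j > 0:
            cost = 0 if a[i - 1] == b[j - 1] else 1
            if here == dist[i - 1, j - 1] + cost:
                letters.append("=" if cost == 0 else "X")
                i, j = i - 1, j - 1
                continue
        if i > 0 and here == dist[i - 1, j] + 1:
            letters.append("D")
            i -= 1
            continue
        letters.append("I")
        j -= 1
    letters.reverse()
    return int(dist[len(a), len(b)]), canonicalize_cigar(letters)


@lru_cache(maxsize=1 << 18)
def prefix_min_distance(pattern_suffix: str, text_suffix: str) -> int:
    """min over t of lev(pattern_suffix, text_suffix[:t]).

    This is the quantity a 0 bit in the DP table certifies: the pattern
    suffix can be matched against *some* prefix of the text suffix.
    """
    dist = levenshtein_matrix(pattern_suffix, text_suffix)
    return int(dist[len(pattern_suffix)].min())


def _as_cigar(cigar) -> list[CigarOp]:
    if isinstance(cigar, str):
        return parse_cigar(cigar)
    return list(cigar)


def count_edits(cigar) -> int:
    """Total X + I + D characters of a CIGAR (string or op list)."""
    return sum(c.length for c in _as_cigar(cigar) if c.op in "XID")


def affine_score(cigar, params: ScoringParams = ScoringParams()) -> int:
    """Score a CIGAR under the single-affine gap model.

    Requires extended ops; M is rejected because match/mismatch cannot
    be resolved from it.
    """
    score = 0
    for c in _as_cigar(cigar):
        if c.op == "M":
            raise InputError("affine scoring requires =/X-resolved CIGARs")
        if c.op == "=":
            score += params.match_score * c.length
        elif c.op == "X":
            score -= params.mismatch_penalty * c.length
        else:  # maximal I or D run
            score -= params.gap_open_penalty + params.gap_extend_penalty * c.length
    return score
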