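"""Greedy windowed alignment driver and CIGAR plumbing.

Windows of size ``W`` slide over both sequences; each window is filled
with the bitvector DP and traced back, committing only its first
``W - O`` characters (the overlap is retried in the next window).  The
per-window edit fragments are stitched into one extended-CIGAR string
(``=``, ``X``, ``I``, ``D``; ``I`` consumes the pattern/read, ``D`` the
text/reference, SAM convention) and a total edit count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core import (
    MODE_ENTRIES,
    PatternMasks,
    WindowParams,
    build_pattern_masks,
    fill_table,
    normalize_sequence,
)
from .errors import InputError, InternalError
from .traceback import traceback_window

_CIGAR_TOKEN = re.compile(r"(\d+)([=XIDM])")
_VALID_OPS = frozenset("=XIDM")


@dataclass(frozen=True)
class CigarOp:
    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in _VALID_OPS:
            raise InputError(f"unknown CIGAR op {self.op!r}")
        if self.length < 1:
            raise InputError(f"non-positive CIGAR run length {self.length}")


def canonicalize_cigar(ops) -> list[CigarOp]:
    """Run-length-encode a sequence of op letters and/or CigarOps,
    merging adjacent equal operations."""
    out: list[CigarOp] = []
    for item in ops:
        if isinstance(item, CigarOp):
            op, length = item.op, item.length
        else:
            op, length = item, 1
            if op not in _VALID_OPS:
                raise InputError(f"unknown CIGAR op {op!r}")
        if out and out[-1].op == op:
            out[-1] = CigarOp(op, out[-1].length + length)
        else:
            out.append(CigarOp(op, length))
    return out


def cigar_to_string(cigar: list[CigarOp], collapse_m: bool = False) -> str:
    """Render to the SAM text dialect; ``collapse_m`` folds {=, X} into M."""
    if collapse_m:
        cigar = canonicalize_cigar(
            CigarOp("M" if c.op in "=X" else c.op, c.length) for c in cigar)
    return "".join(f"{c.length}{c.op}" for c in cigar)


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse a SAM-dialect CIGAR string into ops."""
    ops = []
    pos = 0
    for match in _CIGAR_TOKEN.finditer(text):
        if match.start() != pos:
            raise InputError(f"malformed CIGAR near offset {pos}: {text!r}")
        ops.append(CigarOp(match.group(2), int(match.group(1))))
        pos = match.end()
    if pos != len(text):
        raise InputError(f"malformed CIGAR near offset {pos}: {text!r}")
    return canonicalize_cigar(ops)


def cigar_consumed(cigar: list[CigarOp]) -> tuple[int, int]:
    """(text, pattern) characters consumed by a CIGAR."""
    text = sum(c.length for c in cigar if c.op in "=XDM")
    pattern = sum(c.length for c in cigar if c.op in "=XIM")
    return text, pattern


@dataclass(frozen=True)
class Alignment:
    """A stitched pairwise alignment."""

    cigar: list[CigarOp]
    edits: int
    text_len: int
    pattern_len: int
    windows_used: int

    def cigar_string(self, collapse_m: bool = False) -> str:
        return cigar_to_string(self.cigar, collapse_m=collapse_m)


@dataclass
class AlignStats:
    """Aggregated store-traffic counters across all windows of one pair."""

    bits_written: int = 0
    bits_read: int = 0
    rows_computed: int = 0
    cells_stored: int = 0


def align(text: str, pattern: str, params: WindowParams,
          stats: AlignStats | None = None) -> Alignment:
    """Align ``pattern`` (read) against ``text`` (reference segment).

    Coordinates are 0-based half-open.  Window advance uses the
    consumed lengths reported by each traceback, so the two sequences
    may advance unevenly in the presence of indels.  If one sequence is
    exhausted while the other still has characters, the remainder is
    emitted as a single I or D run.
    """
    text = normalize_sequence(text)
    pattern = normalize_sequence(pattern)
    n, m = len(text), len(pattern)
    W = params.W
    letters: list[str] = []
    a = b = 0
    windows = 0
    while a < n or b < m:
        rem_t, rem_p = n - a, m - b
        if rem_p == 0:
            letters.append("D" * rem_t)
            a = n
            break
        if rem_t == 0:
            letters.append("I" * rem_p)
            b = m
            break
        wtext = text[a:a + min(W, rem_t)]
        wpattern = pattern[b:b + min(W, rem_p)]
        terminal = rem_t <= W and rem_p <= W
        # trimming is only safe for truncated tracebacks
        mode = MODE_ENTRIES if (terminal and params.dent) else None
        masks = build_pattern_masks(wpattern)
        store, d_opt, _rows = fill_table(wtext, wpattern, params,
                                         masks=masks, mode=mode)
        result = traceback_window(store, d_opt, params, masks, wtext,
                                  terminal=terminal)
        if stats is not None:
            stats.bits_written += store.bits_written
            stats.bits_read += store.bits_read
            stats.rows_computed += store.rows_computed
            stats.cells_stored += store.cell_writes
        windows += 1
        if result.text_consumed == 0 and result.pattern_consumed == 0:
            raise InternalError("window made no progress")
        a += result.text_consumed
        b += result.pattern_consumed
        letters.append(result.ops)
        if terminal:
            break
    cigar = canonicalize_cigar("".join(letters))
    ct, cp = cigar_consumed(cigar)
    if ct != n or cp != m:
        raise InternalError(
            f"CIGAR consumption mismatch: ({ct},{cp}) vs ({n},{m})")
    edits = sum(c.length for c in cigar if c.op in "XID")
    return Alignment(cigar=cigar, edits=edits, text_len=n, pattern_len=m,
                     windows_used=windows)
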