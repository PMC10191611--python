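"""Traceback: walk the path of 0 bits from the edit-distance witness
toward the window's north-east corner, emitting =/X/I/D edits.

The walk starts at ``(d = d_opt, i = 0, j = 0)`` and crosses one edge per
step.  Edges are either read back from an edges-mode store or regenerated
on demand from stored entries (SENE); both paths yield identical edge
sets on every cell.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    Bitvector,
    DPStore,
    EdgeSet,
    MODE_EDGES,
    PatternMasks,
    WindowParams,
    boundary_vector,
    dc_cell,
)
from .errors import InternalError

#: Fixed edge priority; deterministic and documented.  Matches are free,
#: and among cost-1 edges the substitution keeps the walk on the diagonal.
EDGE_PRIORITY = "MSDI"

_OP_OF_EDGE = {"M": "=", "S": "X", "D": "D", "I": "I"}


@dataclass(frozen=True)
class WindowResult:
    """Edits emitted by one window's traceback."""

    ops: str  # letters from {=, X, I, D}, in text order
    text_consumed: int
    pattern_consumed: int
    d_start: int
    padded_tail: int = 0


def _entry_at(store: DPStore, d: int, i: int) -> Bitvector:
    """Entry value at (d, i): read from the store, or the boundary vector
    for the rightmost column when it lies outside the stored region."""
    if i == store.n and (store.mode == MODE_EDGES or i > store.max_col):
        return boundary_vector(d, store.m)
    return Bitvector(store.read_entry(d, i), store.m)


def regenerate_edges(store: DPStore, d: int, i: int, masks: PatternMasks,
                     params: WindowParams, text: str) -> EdgeSet:
    """Edge set of cell (d, i), from stored payloads.

    In edges mode the stored I/D/M are read and S is derived by shifting
    D.  In entries modes the neighbors' entries are read back and the
    cell update is re-applied (the boundary column is recomputed rather
    than read when the store discarded it).
    """
    m = store.m
    ones = Bitvector((1 << m) - 1, m)
    if store.mode == MODE_EDGES:
        i_e, d_e, m_e = store.read_edges(d, i)
        if i == store.n:
            # boundary column: only the insertion chain is legal
            bv = Bitvector(i_e, m)
            return EdgeSet(I=bv, D=ones, S=ones, M=ones, entry=bv)
        if d == 0:
            # match-only row: no north row exists
            bv = Bitvector(m_e, m)
            return EdgeSet(I=ones, D=ones, S=ones, M=bv, entry=bv)
        return EdgeSet(
            I=Bitvector(i_e, m),
            D=Bitvector(d_e, m),
            S=Bitvector(d_e, m).shl(),
            M=Bitvector(m_e, m),
            entry=Bitvector(i_e & d_e & ((d_e << 1) & ones.value) & m_e, m),
        )
    if i == store.n:
        # boundary column: only the insertion chain is legal (the d=0
        # corner is all ones and select_edge will reject it)
        entry = boundary_vector(d, m)
        return EdgeSet(I=entry, D=ones, S=ones, M=ones, entry=entry)
    mask = masks.bv(text[i])
    if d == 0:
        east = _entry_at(store, 0, i + 1)
        m_edge = Bitvector((east.shl().value) | mask.value, m)
        return EdgeSet(I=ones, D=ones, S=ones, M=m_edge, entry=m_edge)
    north = _entry_at(store, d - 1, i)
    northeast = _entry_at(store, d - 1, i + 1)
    east = _entry_at(store, d, i + 1)
    return dc_cell(north, northeast, east, mask)


def select_edge(edges: EdgeSet, j: int) -> str:
    """First of M, S, D, I whose bitvector has bit ``j`` equal to 0."""
    for name in EDGE_PRIORITY:
        if getattr(edges, name).bit(j) == 0:
            return name
    raise InternalError(
        f"no zero bit at j={j} in any edge; entry bit is "
        f"{edges.entry.bit(j)} (violates the AND identity)")


def traceback_window(store: DPStore, d_opt: int, params: WindowParams,
                     masks: PatternMasks, text: str,
                     terminal: bool) -> WindowResult:
    """Walk from ``(d_opt, 0, 0)`` and emit edits.

    Non-terminal windows stop as soon as ``i`` or ``j`` reaches ``W - O``
    (or a sequence runs out), which keeps every visited cell inside the
    trimmed store region.  Terminal windows walk to ``i = n, j = m``;
    when the pattern is exhausted first the remaining text is appended as
    a tail of deletions.
    """
    n, m = store.n, store.m
    limit = params.W - params.O
    d, i, j = d_opt, 0, 0
    ops: list[str] = []
    padded = 0
    while True:
        if terminal:
            if j == m:
                if i < n:
                    padded = n - i
                    ops.append("D" * padded)
                    i = n
                break
        elif i >= limit or j >= limit or i >= n or j >= m:
            break
        edges = regenerate_edges(store, d, i, masks, params, text)
        if __debug__ and edges.entry.bit(j) != 0:
            raise InternalError(f"zero-path invariant violated at ({d},{i},{j})")
        edge = select_edge(edges, j)
        ops.append(_OP_OF_EDGE[edge])
        if edge == "M":
            i, j = i + 1, j + 1
        elif edge == "S":
            d, i, j = d - 1, i + 1, j + 1
        elif edge == "D":
            d, i = d - 1, i + 1
        else:  # I
            d, j = d - 1, j + 1
        if d < 0:
            raise InternalError("row index went negative during traceback")
    return WindowResult(
        ops="".join(ops),
        text_consumed=i,
        pattern_consumed=j,
        d_start=d_opt,
        padded_tail=padded,
    )
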