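"""Bitvector edit-distance dynamic programming (table fill).

The DP table ``R`` has rows ``d = 0..k`` (edit budget) and columns
``i = 0..n`` (text position).  Each cell is an ``m``-bit bitvector whose
bit ``j`` (``j = 0`` is the *most significant* bit) is 0 exactly when the
pattern suffix starting at ``j`` can be matched against some prefix of the
text suffix starting at ``i`` with at most ``d`` edits::

    bit j of R[d][i] == 0  <=>  min_t lev(pattern[j:], text[i:i+t]) <= d

Bitvectors are plain Python integers of declared width; the paper-style
bit index ``j`` maps to integer bit position ``width - 1 - j``, so a
bitstring written left-to-right reads as the binary numeral of the value
(``"0110" -> 6``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import ConfigurationError, InternalError, OutOfRegionError

_COMPLEMENTABLE = "ACGT"


class Bitvector(NamedTuple):
    """An ``m``-bit value; bit ``j=0`` is the most significant bit."""

    value: int
    width: int

    def bit(self, j: int) -> int:
        """Return bit ``j`` (0 = most significant)."""
        if not 0 <= j < self.width:
            raise IndexError(f"bit {j} out of range for width {self.width}")
        return (self.value >> (self.width - 1 - j)) & 1

    def shl(self) -> "Bitvector":
        """Left shift by one, truncated to width; a 0 enters at j = width-1."""
        return Bitvector((self.value << 1) & ((1 << self.width) - 1), self.width)

    def __str__(self) -> str:
        return format(self.value, f"0{self.width}b") if self.width else ""


def _ones(m: int) -> int:
    return (1 << m) - 1


@dataclass(frozen=True)
class PatternMasks:
    """Per-character match masks: bit ``j`` is 0 iff ``pattern[j] == X``.

    Characters outside the alphabet never match (all-ones column), so an
    ambiguous base always costs a substitution.
    """

    width: int
    masks: dict  # char -> int

    def mask_of(self, char: str) -> int:
        return self.masks.get(char, _ones(self.width))

    def bv(self, char: str) -> Bitvector:
        return Bitvector(self.mask_of(char), self.width)


def normalize_sequence(seq: str) -> str:
    """Upper-case and map U to T."""
    return seq.upper().replace("U", "T")


def build_pattern_masks(pattern: str, alphabet: str = _COMPLEMENTABLE) -> PatternMasks:
    """Preprocess ``pattern`` into one match mask per alphabet character."""
    m = len(pattern)
    ones = _ones(m)
    masks = {}
    for char in alphabet:
        v = ones
        for j, p in enumerate(pattern):
            if p == char:
                v &= ~(1 << (m - 1 - j))
        masks[char] = v & ones
    return PatternMasks(width=m, masks=masks)


def boundary_vector(d: int, m: int) -> Bitvector:
    """Rightmost-column entry for row ``d``: the ``d`` least significant
    bits are 0 (bit ``j`` is 0 iff ``m - j <= d``)."""
    if d < 0:
        raise ConfigurationError(f"negative edit count d={d}")
    if d >= m:
        return Bitvector(0, m)
    return Bitvector(_ones(m) & ~_ones(d), m)


#: Storage modes for the traceback store.
MODE_EDGES = "edges"  # I, D, M stored per cell (S = D << 1 on read)
MODE_ENTRIES = "entries"  # single ANDed entry per cell
MODE_ENTRIES_DENT = "entries-dent"  # entries, trimmed to the traceback region

_PRESETS = {"long": (64, 33), "short": (32, 17)}


@dataclass(frozen=True)
class WindowParams:
    """Validated configuration of one aligner instance.

    ``W`` is the window size, ``O`` the overlap; the per-window edit
    budget ``k`` is fixed to ``W``.  The three switchable frugality
    improvements are ``sene`` (store entries, not edges), ``dent``
    (trim the store to the traceback-reachable region; requires
    ``sene``) and ``et`` (early termination of the row fill).
    """

    W: int = 64
    O: int = 33
    sene: bool = True
    dent: bool = True
    et: bool = True

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ConfigurationError(f"W must be >= 1, got {self.W}")
        if not 0 <= self.O < self.W:
            raise ConfigurationError(
                f"overlap must satisfy 0 <= O < W, got O={self.O}, W={self.W}"
            )
        if self.dent and not self.sene:
            raise ConfigurationError("dent requires sene (it trims the entries table)")

    @property
    def k(self) -> int:
        return self.W

    @property
    def store_mode(self) -> str:
        if not self.sene:
            return MODE_EDGES
        return MODE_ENTRIES_DENT if self.dent else MODE_ENTRIES

    @classmethod
    def preset(cls, name: str, **flags) -> "WindowParams":
        try:
            w, o = _PRESETS[name]
        except KeyError:
            raise ConfigurationError(f"unknown preset {name!r}") from None
        return cls(W=w, O=o, **flags)


@dataclass(frozen=True)
class EdgeSet:
    """The four incoming edges of one DP cell plus their AND."""

    I: Bitvector
    D: Bitvector
    S: Bitvector
    M: Bitvector
    entry: Bitvector


def dc_cell(north: Bitvector, northeast: Bitvector, east: Bitvector,
            mask: Bitvector) -> EdgeSet:
    """One interior-cell update.

    ``north = R[d-1][i]`` (insertion), ``northeast = R[d-1][i+1]``
    (deletion; substitution is its shift), ``east = R[d][i+1]`` (match).
    """
    m = north.width
    if not (northeast.width == east.width == mask.width == m):
        raise ConfigurationError(
            "width mismatch in dc_cell: "
            f"{north.width}/{northeast.width}/{east.width}/{mask.width}"
        )
    ones = _ones(m)
    i_edge = (north.value << 1) & ones
    d_edge = northeast.value
    s_edge = (d_edge << 1) & ones
    m_edge = ((east.value << 1) & ones) | mask.value
    entry = i_edge & d_edge & s_edge & m_edge
    return EdgeSet(
        I=Bitvector(i_edge, m),
        D=Bitvector(d_edge, m),
        S=Bitvector(s_edge, m),
        M=Bitvector(m_edge, m),
        entry=Bitvector(entry, m),
    )


class DPStore:
    """Traceback store for one window's DP table.

    Holds the per-cell payloads that survive the fill, in one of three
    modes, and counts the bits that cross the store boundary.  Values the
    fill keeps in its working rows ("forefront in registers") are not
    counted.  In ``entries-dent`` mode only columns ``i <= W-O`` and the
    top ``W-O+1`` bits of each entry are stored; everything else is
    discarded at write time.
    """

    def __init__(self, n: int, m: int, params: WindowParams, mode: str | None = None):
        self.n = n
        self.m = m
        self.k = params.k
        self.W = params.W
        self.O = params.O
        self.mode = mode if mode is not None else params.store_mode
        if self.mode not in (MODE_EDGES, MODE_ENTRIES, MODE_ENTRIES_DENT):
            raise ConfigurationError(f"unknown store mode {self.mode!r}")
        self.bits_written = 0
        self.bits_read = 0
        self.rows_computed = 0
        self.cell_writes = 0
        if self.mode == MODE_ENTRIES_DENT:
            self.max_col = min(n, self.W - self.O)
            self.kept_bits = min(m, self.W - self.O + 1)
            # keep the top kept_bits of each m-bit entry
            self.trim_mask = _ones(m) & ~_ones(m - self.kept_bits)
        else:
            self.max_col = n
            self.kept_bits = m
            self.trim_mask = _ones(m)
        ncells = (self.k + 1) * (self.max_col + 1)
        if self.mode == MODE_EDGES:
            self._edges_i = [None] * ncells
            self._edges_d = [None] * ncells
            self._edges_m = [None] * ncells
        else:
            self._entries = [None] * ncells

    # -- geometry -----------------------------------------------------

    def _index(self, d: int, i: int) -> int:
        if not 0 <= d <= self.k:
            raise OutOfRegionError(f"row {d} outside [0, {self.k}]")
        if not 0 <= i <= self.max_col:
            raise OutOfRegionError(f"column {i} outside stored region [0, {self.max_col}]")
        return d * (self.max_col + 1) + i

    @property
    def stored_cells(self) -> int:
        """Number of cell locations the store provides (full table capacity)."""
        return (self.k + 1) * (self.max_col + 1)

    @property
    def capacity_bits(self) -> int:
        """Total store capacity in bits, all rows, per the mode's payload."""
        per_cell = 3 * self.kept_bits if self.mode == MODE_EDGES else self.kept_bits
        return self.stored_cells * per_cell

    @property
    def stored_bytes(self) -> float:
        return self.capacity_bits / 8

    # -- writes (fill side) -------------------------------------------

    def write_entry_row(self, d: int, row: list) -> None:
        """Store one computed row of entry values (entries / dent modes)."""
        base = self._index(d, 0)
        trim = self.trim_mask
        kept = self.kept_bits
        entries = self._entries
        for i in range(self.max_col + 1):
            idx = base + i
            if entries[idx] is not None:
                raise InternalError(f"cell ({d},{i}) written twice")
            entries[idx] = row[i] & trim
        self.cell_writes += self.max_col + 1
        self.bits_written += (self.max_col + 1) * kept
        self.rows_computed = max(self.rows_computed, d + 1)

    def write_edge_row(self, d: int, i_row: list, d_row: list, m_row: list) -> None:
        """Store one computed row of (I, D, M) triples (edges mode)."""
        base = self._index(d, 0)
        for i in range(self.max_col + 1):
            idx = base + i
            if self._edges_m[idx] is not None:
                raise InternalError(f"cell ({d},{i}) written twice")
            self._edges_i[idx] = i_row[i]
            self._edges_d[idx] = d_row[i]
            self._edges_m[idx] = m_row[i]
        self.cell_writes += self.max_col + 1
        self.bits_written += (self.max_col + 1) * 3 * self.m
        self.rows_computed = max(self.rows_computed, d + 1)

    # -- reads (traceback side) ---------------------------------------

    def read_entry(self, d: int, i: int) -> int:
        if self.mode == MODE_EDGES:
            raise InternalError("read_entry on an edges-mode store")
        if d >= self.rows_computed:
            raise OutOfRegionError(f"row {d} was never computed")
        value = self._entries[self._index(d, i)]
        self.bits_read += self.kept_bits
        return value

    def read_edges(self, d: int, i: int) -> tuple:
        if self.mode != MODE_EDGES:
            raise InternalError("read_edges on an entries-mode store")
        if d >= self.rows_computed:
            raise OutOfRegionError(f"row {d} was never computed")
        idx = self._index(d, i)
        self.bits_read += 3 * self.m
        return self._edges_i[idx], self._edges_d[idx], self._edges_m[idx]


def fill_table(text: str, pattern: str, params: WindowParams,
               masks: PatternMasks | None = None,
               mode: str | None = None):
    """Row-wise bitvector DP fill for one window.

    Returns ``(store, d_opt, rows_computed)`` where ``d_opt`` is the
    smallest row whose leftmost entry has bit 0 equal to 0, i.e. the
    minimum over ``t`` of ``lev(pattern, text[:t])``.  With ``params.et``
    no row beyond ``d_opt`` is computed; otherwise all ``k+1`` rows are.

    ``mode`` overrides the store mode derived from the flags (the window
    driver disables trimming for terminal windows this way).
    """
    n, m = len(text), len(pattern)
    if n > params.W or m > params.W:
        raise ConfigurationError(
            f"window sequences exceed W={params.W}: n={n}, m={m}")
    if masks is None:
        masks = build_pattern_masks(pattern)
    elif masks.width != m:
        raise ConfigurationError("pattern mask width does not match pattern")
    store = DPStore(n, m, params, mode=mode)
    k = params.k
    ones = _ones(m)
    msb = 1 << (m - 1) if m else 0
    mask_row = [masks.mask_of(c) for c in text]
    edges_mode = store.mode == MODE_EDGES

    d_opt = None
    prev = None
    for d in range(k + 1):
        cur = [0] * (n + 1)
        if d == 0:
            cur[n] = ones
            for i in range(n - 1, -1, -1):
                cur[i] = ((cur[i + 1] << 1) & ones) | mask_row[i]
            if edges_mode:
                # row 0 has no north row: I and D edges are all-ones
                store.write_edge_row(0, [ones] * (n + 1), [ones] * (n + 1), cur)
            else:
                store.write_entry_row(0, cur)
        else:
            cur[n] = boundary_vector(d, m).value
            if edges_mode:
                i_row = [0] * (n + 1)
                d_row = [0] * (n + 1)
                m_row = [0] * (n + 1)
                # boundary column: only the insertion chain is legal
                i_row[n], d_row[n], m_row[n] = cur[n], ones, ones
                for i in range(n - 1, -1, -1):
                    i_e = (prev[i] << 1) & ones
                    d_e = prev[i + 1]
                    s_e = (d_e << 1) & ones
                    m_e = ((cur[i + 1] << 1) & ones) | mask_row[i]
                    cur[i] = i_e & d_e & s_e & m_e
                    i_row[i], d_row[i], m_row[i] = i_e, d_e, m_e
                store.write_edge_row(d, i_row, d_row, m_row)
            else:
                for i in range(n - 1, -1, -1):
                    d_e = prev[i + 1]
                    cur[i] = (
                        ((prev[i] << 1) & ones)
                        & d_e
                        & ((d_e << 1) & ones)
                        & (((cur[i + 1] << 1) & ones) | mask_row[i])
                    )
                store.write_entry_row(d, cur)
        if d_opt is None and (m == 0 or not cur[0] & msb):
            d_opt = d
            if params.et:
                break
        prev = cur
    if d_opt is None:
        raise InternalError(
            f"no row with a leading 0 found within k={k} rows (n={n}, m={m})")
    return store, d_opt, store.rows_computed
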