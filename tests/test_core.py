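import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frugalign import (
    Bitvector,
    ConfigurationError,
    InternalError,
    MODE_EDGES,
    MODE_ENTRIES,
    MODE_ENTRIES_DENT,
    WindowParams,
    boundary_vector,
    build_pattern_masks,
    dc_cell,
    fill_table,
)

from conftest import random_seq

dna = st.text(alphabet="ACGT", max_size=12)


class TestPatternMasks:
    def test_acga_example(self):
        pm = build_pattern_masks("ACGA")
        assert pm.masks["A"] == 0b0110
        assert pm.masks["C"] == 0b1011
        assert pm.masks["G"] == 0b1101
        assert pm.masks["T"] == 0b1111

    def test_uniform_pattern(self):
        pm = build_pattern_masks("AAAA")
        assert pm.masks["A"] == 0b0000
        assert pm.masks["C"] == pm.masks["G"] == pm.masks["T"] == 0b1111

    def test_ambiguous_base_never_matches(self):
        pm = build_pattern_masks("ACGN")
        for char in "ACGT":
            assert pm.masks[char] & 1  # bit j=3 (LSB) is 1 in all masks
        assert pm.mask_of("N") == 0b1111  # catch-all

    def test_empty_pattern(self):
        pm = build_pattern_masks("")
        assert pm.width == 0
        assert all(v == 0 for v in pm.masks.values())

    @given(dna)
    def test_each_position_matches_exactly_one_character(self, pattern):
        # exactly one of the four masks holds a 0 at every position, so
        # their AND is all zeros and the OR of complements is all ones
        pm = build_pattern_masks(pattern)
        m = len(pattern)
        acc = 0
        for char in "ACGT":
            acc |= ~pm.masks[char] & ((1 << m) - 1)
        combined = pm.masks["A"] & pm.masks["C"] & pm.masks["G"] & pm.masks["T"]
        assert combined == 0
        assert acc == (1 << m) - 1


class TestBoundaryVector:
    @pytest.mark.parametrize("d,m,expected", [
        (0, 4, 0b1111),
        (2, 4, 0b1100),
        (4, 4, 0b0000),
        (7, 4, 0b0000),
        (0, 0, 0),
    ])
    def test_examples(self, d, m, expected):
        bv = boundary_vector(d, m)
        assert bv.value == expected
        assert bv.width == m

    @given(st.integers(0, 10), st.integers(0, 10))
    def test_bit_rule(self, d, m):
        bv = boundary_vector(d, m)
        for j in range(m):
            assert bv.bit(j) == (0 if m - j <= d else 1)


class TestDcCell:
    def test_fig_instance_cell(self):
        # text ACGT, pattern ACGA, cell d=1, i=2
        edges = dc_cell(Bitvector(0b1111, 4), Bitvector(0b1111, 4),
                        Bitvector(0b1110, 4), Bitvector(0b1101, 4))
        assert edges.I.value == 0b1110
        assert edges.D.value == 0b1111
        assert edges.S.value == 0b1110
        assert edges.M.value == 0b1101
        assert edges.entry.value == 0b1100
        assert edges.entry.bit(2) == 0

    def test_all_ones_inputs(self):
        ones = Bitvector(0b1111, 4)
        edges = dc_cell(ones, ones, ones, ones)
        assert edges.entry.value == 0b1110  # shifted-in 0s of I and S survive

    def test_width_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            dc_cell(Bitvector(0, 4), Bitvector(0, 3),
                    Bitvector(0, 4), Bitvector(0, 4))

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 15))
    def test_and_identity(self, a, b, c, d):
        edges = dc_cell(Bitvector(a, 4), Bitvector(b, 4),
                        Bitvector(c, 4), Bitvector(d, 4))
        combined = (edges.I.value & edges.D.value
                    & edges.S.value & edges.M.value)
        assert edges.entry.value == combined
        assert edges.S.value == edges.D.shl().value


class TestWindowParams:
    def test_defaults_are_long_preset(self):
        p = WindowParams()
        assert (p.W, p.O) == (64, 33)
        assert p.k == 64

    def test_presets(self):
        assert (WindowParams.preset("long").W, WindowParams.preset("long").O) == (64, 33)
        assert (WindowParams.preset("short").W, WindowParams.preset("short").O) == (32, 17)

    @pytest.mark.parametrize("kwargs", [
        {"W": 0},
        {"W": 4, "O": 4},
        {"W": 4, "O": -1},
        {"sene": False, "dent": True},
    ])
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ConfigurationError):
            WindowParams(**kwargs)

    def test_store_mode_derivation(self):
        assert WindowParams(sene=False, dent=False).store_mode == MODE_EDGES
        assert WindowParams(sene=True, dent=False).store_mode == MODE_ENTRIES
        assert WindowParams(sene=True, dent=True).store_mode == MODE_ENTRIES_DENT


class TestFillTable:
    def test_worked_example_et_on(self):
        params = WindowParams(W=4, O=0, dent=False, et=True)
        store, d_opt, rows = fill_table("ACGT", "ACGA", params)
        assert d_opt == 1
        assert rows == 2
        assert store.read_entry(1, 2) == 0b1100
        assert store.read_entry(1, 0) == 0b0100

    def test_identical_strings(self):
        params = WindowParams(W=8, O=0, dent=False, et=True)
        _store, d_opt, rows = fill_table("ACGT", "ACGT", params)
        assert d_opt == 0
        assert rows == 1

    def test_et_off_fills_all_rows(self):
        params = WindowParams(W=4, O=0, dent=False, et=False)
        _store, d_opt, rows = fill_table("ACGT", "ACGA", params)
        assert d_opt == 1
        assert rows == 5

    def test_window_overflow_rejected(self):
        with pytest.raises(ConfigurationError):
            fill_table("A" * 5, "A" * 3, WindowParams(W=4, O=0, dent=False))

    def test_empty_inputs(self):
        params = WindowParams(W=4, O=0, dent=False)
        _s, d_opt, _r = fill_table("", "", params)
        assert d_opt == 0
        _s, d_opt, _r = fill_table("ACG", "", params)
        assert d_opt == 0  # empty pattern matches the empty text prefix
        _s, d_opt, _r = fill_table("", "ACG", params)
        assert d_opt == 3  # pattern must be inserted entirely

    @given(dna, dna, st.booleans())
    @settings(max_examples=60, deadline=None)
    def test_et_equivalence(self, text, pattern, sene):
        base = dict(W=12, O=0, sene=sene, dent=False)
        s_on, d_on, r_on = fill_table(text, pattern, WindowParams(et=True, **base))
        s_off, d_off, r_off = fill_table(text, pattern, WindowParams(et=False, **base))
        assert d_on == d_off
        assert r_on == d_on + 1
        assert r_off == 13
        for d in range(d_on + 1):  # shared rows are identical
            for i in range(len(text) + 1):
                if sene:
                    assert s_on.read_entry(d, i) == s_off.read_entry(d, i)
                else:
                    assert s_on.read_edges(d, i) == s_off.read_edges(d, i)

    @given(dna, dna)
    @settings(max_examples=60, deadline=None)
    def test_mode_equivalence(self, text, pattern):
        # entries reconstructed from stored edges equal stored entries
        params_e = WindowParams(W=12, O=5, sene=False, dent=False, et=False)
        params_n = WindowParams(W=12, O=5, sene=True, dent=False, et=False)
        params_d = WindowParams(W=12, O=5, sene=True, dent=True, et=False)
        s_edges, d1, _ = fill_table(text, pattern, params_e)
        s_entries, d2, _ = fill_table(text, pattern, params_n)
        s_dent, d3, _ = fill_table(text, pattern, params_d)
        assert d1 == d2 == d3
        m = len(pattern)
        ones = (1 << m) - 1
        for d in range(s_edges.k + 1):
            for i in range(len(text) + 1):
                i_e, d_e, m_e = s_edges.read_edges(d, i)
                if d == 0 or i == len(text):
                    entry = s_entries.read_entry(d, i)  # boundary payloads
                else:
                    entry = i_e & d_e & ((d_e << 1) & ones) & m_e
                assert entry == s_entries.read_entry(d, i)
                if i <= s_dent.max_col:
                    assert entry & s_dent.trim_mask == s_dent.read_entry(d, i)

    @given(dna, dna, st.sampled_from([MODE_EDGES, MODE_ENTRIES, MODE_ENTRIES_DENT]))
    @settings(max_examples=60, deadline=None)
    def test_write_once(self, text, pattern, mode):
        params = WindowParams(W=12, O=5, et=False)
        store, _d, rows = fill_table(text, pattern, params, mode=mode)
        assert store.cell_writes == rows * (store.max_col + 1)
        per_cell = 3 * store.m if mode == MODE_EDGES else store.kept_bits
        assert store.bits_written == store.cell_writes * per_cell

    def test_counters_monotone(self, rng):
        params = WindowParams(W=16, O=9, et=False)
        text, pattern = random_seq(rng, 16), random_seq(rng, 16)
        store, d_opt, _ = fill_table(text, pattern, params)
        written_after_fill = store.bits_written
        assert store.bits_read == 0
        store.read_entry(0, 0)
        assert store.bits_read == store.kept_bits
        assert store.bits_written == written_after_fill


class TestDiagonalSemantics:
    def test_d_opt_is_min_prefix_distance(self, rng):
        # d_opt equals min over t of lev(pattern, text[:t])
        from frugalign.oracle import prefix_min_distance
        params = WindowParams(W=16, O=0, dent=False)
        for _ in range(40):
            n = int(rng.integers(0, 17))
            m = int(rng.integers(0, 17))
            text, pattern = random_seq(rng, n), random_seq(rng, m)
            _s, d_opt, _r = fill_table(text, pattern, params)
            assert d_opt == prefix_min_distance(pattern, text)
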