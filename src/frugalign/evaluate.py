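"""Experiment harness: early-termination skip fraction, store footprint
and write-traffic ratios between storage modes, accuracy quantiles
against the exact oracle, and the correctly-aligned-bases metric.

All reported ratios are derived from live store counters, never from
closed forms (the closed forms appear only in tests, as oracles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MODE_EDGES,
    MODE_ENTRIES,
    MODE_ENTRIES_DENT,
    WindowParams,
    build_pattern_masks,
    fill_table,
)
from .errors import ConfigurationError, InputError
from .oracle import ScoringParams, affine_score, levenshtein_align
from .pairs import PairRecord, SyntheticPairSpec, generate_pairs
from .traceback import traceback_window
from .windowing import Alignment, CigarOp, align, cigar_consumed

QUANTILES = (0.5, 0.1, 0.01, 0.001)


@dataclass(frozen=True)
class ModeTraffic:
    stored_bytes: float
    bits_written: int
    bits_read: int


@dataclass(frozen=True)
class TrafficReport:
    """Store footprint and traffic of the three modes on one window."""

    W: int
    O: int
    modes: dict  # mode name -> ModeTraffic

    def stored_bytes_ratio(self, numerator: str, denominator: str) -> float:
        return self.modes[numerator].stored_bytes / self.modes[denominator].stored_bytes

    def write_ratio(self, numerator: str, denominator: str) -> float:
        return self.modes[numerator].bits_written / self.modes[denominator].bits_written


def _random_pair(rng: np.random.Generator, length: int) -> tuple[str, str]:
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    text = letters[rng.integers(0, 4, size=length)].tobytes().decode()
    pattern = letters[rng.integers(0, 4, size=length)].tobytes().decode()
    return text, pattern


def skip_fraction_experiment(n_pairs: int, W: int = 64, seed: int = 0) -> float:
    """Mean fraction of DP rows never computed thanks to early
    termination, over uniform random pairs both of length ``W``."""
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    params = WindowParams(W=W, O=0, sene=True, dent=False, et=True)
    rng = np.random.default_rng(seed)
    k = params.k
    total = 0.0
    for _ in range(n_pairs):
        text, pattern = _random_pair(rng, W)
        _store, d_opt, _rows = fill_table(text, pattern, params)
        total += (k - d_opt) / (k + 1)
    return total / n_pairs


def footprint_report(W: int, O: int, seed: int = 0) -> TrafficReport:
    """Fill one representative full window (no early termination) in each
    storage mode and read the counters; also run a truncated traceback to
    populate the read counters."""
    params_by_mode = {
        MODE_EDGES: WindowParams(W=W, O=O, sene=False, dent=False, et=False),
        MODE_ENTRIES: WindowParams(W=W, O=O, sene=True, dent=False, et=False),
        MODE_ENTRIES_DENT: WindowParams(W=W, O=O, sene=True, dent=True, et=False),
    }
    rng = np.random.default_rng(seed)
    text, pattern = _random_pair(rng, W)
    masks = build_pattern_masks(pattern)
    modes = {}
    for mode, params in params_by_mode.items():
        store, d_opt, _rows = fill_table(text, pattern, params, masks=masks)
        traceback_window(store, d_opt, params, masks, text, terminal=False)
        modes[mode] = ModeTraffic(
            stored_bytes=store.stored_bytes,
            bits_written=store.bits_written,
            bits_read=store.bits_read,
        )
    return TrafficReport(W=W, O=O, modes=modes)


def accuracy_quantiles(pairs, grid, scoring: ScoringParams = ScoringParams(),
                       reference_align=None) -> pd.DataFrame:
    """Affine-score delta quantiles (heuristic minus oracle) per (W, O).

    ``pairs`` is a list of PairRecords, ``grid`` an iterable of (W, O).
    ``reference_align`` defaults to the exact Levenshtein aligner; the
    self-consistency tests substitute the heuristic itself.
    """
    grid = list(grid)
    for w, o in grid:
        if not 0 <= o < w:
            raise ConfigurationError(f"invalid grid point W={w}, O={o}")
    pairs = list(pairs)
    oracle_scores = []
    for record in pairs:
        if reference_align is None:
            _dist, cigar = levenshtein_align(record.text, record.pattern)
            oracle_scores.append(affine_score(cigar, scoring))
        else:
            oracle_scores.append(None)  # filled per grid point
    rows = []
    for w, o in grid:
        params = WindowParams(W=w, O=o)
        deltas = []
        for record, oracle_score in zip(pairs, oracle_scores):
            aln = align(record.text, record.pattern, params)
            score = affine_score(aln.cigar, scoring)
            if oracle_score is None:
                ref = reference_align(record.text, record.pattern, params)
                oracle_score = affine_score(ref.cigar, scoring)
            deltas.append(score - oracle_score)
        deltas = np.asarray(deltas, dtype=float)
        row = {"W": w, "O": o}
        for q in QUANTILES:
            row[f"q{q}"] = float(np.quantile(deltas, q))
        rows.append(row)
    return pd.DataFrame(rows)


def _read_base_placements(cigar: list[CigarOp], n_pattern: int) -> list:
    """Text offset assigned to each pattern base; None for insertions."""
    placements = []
    ti = 0
    for op in cigar:
        if op.op in "=XM":
            placements.extend(range(ti, ti + op.length))
            ti += op.length
        elif op.op == "I":
            placements.extend([None] * op.length)
        else:  # D
            ti += op.length
    if len(placements) != n_pattern:
        raise InputError(
            f"CIGAR consumes {len(placements)} pattern bases, expected {n_pattern}")
    return placements


def correct_base_fraction(predicted: Alignment | list[CigarOp],
                          truth_cigar: list[CigarOp],
                          pair: PairRecord) -> float:
    """Fraction of read bases placed at the same text offset as in the
    ground truth (insertions must be insertions in both)."""
    pred_cigar = predicted.cigar if isinstance(predicted, Alignment) else predicted
    n_pattern = len(pair.pattern)
    for cigar in (pred_cigar, truth_cigar):
        ct, cp = cigar_consumed(cigar)
        if ct != len(pair.text) or cp != n_pattern:
            raise InputError(
                f"CIGAR consumes ({ct},{cp}); pair is "
                f"({len(pair.text)},{n_pattern})")
    if n_pattern == 0:
        return 1.0
    pred = _read_base_placements(pred_cigar, n_pattern)
    truth = _read_base_placements(truth_cigar, n_pattern)
    correct = sum(1 for p, t in zip(pred, truth) if p == t)
    return correct / n_pattern


def synthetic_accuracy_run(n_pairs: int, length: int, error_rate: float,
                           grid, seed: int = 0,
                           scoring: ScoringParams = ScoringParams()) -> pd.DataFrame:
    """Convenience wrapper: generate pairs, run the quantile sweep."""
    spec = SyntheticPairSpec(n_pairs=n_pairs, ref_length=length,
                             error_rate=error_rate, seed=seed)
    return accuracy_quantiles(list(generate_pairs(spec)), grid, scoring=scoring)
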