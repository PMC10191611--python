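"""Pair records: synthetic ground-truthed generation, readers, writers.

The synthetic generator emulates read-vs-reference candidate pairs: a
uniform random reference over {A,C,G,T} and a derived read produced by
an i.i.d. per-position error process (substitution/insertion/deletion
mix), with the applied edit script retained as a ground-truth CIGAR.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .core import normalize_sequence
from .errors import ConfigurationError, InputError
from .windowing import (
    Alignment,
    CigarOp,
    canonicalize_cigar,
    cigar_consumed,
    cigar_to_string,
    parse_cigar,
)

DEFAULT_ALPHABET = "ACGT"


@dataclass(frozen=True)
class PairRecord:
    id: str
    text: str
    pattern: str
    truth_cigar: list[CigarOp] | None = None


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Parameters of the ground-truthed pair generator."""

    n_pairs: int = 1
    ref_length: int = 10_000
    error_rate: float = 0.05
    mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # (sub, ins, del)
    seed: int = 0
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ConfigurationError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if len(self.mix) != 3 or min(self.mix) < 0:
            raise ConfigurationError("mix must be three non-negative proportions")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ConfigurationError(f"mix must sum to 1, got {sum(self.mix)}")
        if self.n_pairs < 0 or self.ref_length < 0:
            raise ConfigurationError("n_pairs and ref_length must be non-negative")


def generate_pairs(spec: SyntheticPairSpec) -> Iterator[PairRecord]:
    """Yield seeded, reproducible ground-truthed pairs.

    Each reference position is independently hit by an error with
    probability ``error_rate``; the error type is drawn from ``mix``.
    An insertion places a uniform random base before the position (the
    position itself still matches), a substitution replaces the base by
    a uniform draw from the other three, a deletion drops it.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.frombuffer(spec.alphabet.encode("ascii"), dtype=np.uint8)
    n_letters = len(letters)
    for idx in range(spec.n_pairs):
        ref_codes = rng.integers(0, n_letters, size=spec.ref_length)
        text = letters[ref_codes].tobytes().decode("ascii")
        hit = rng.random(spec.ref_length) < spec.error_rate
        kinds = rng.choice(3, size=spec.ref_length, p=spec.mix)
        read_parts: list[str] = []
        ops: list[str] = []
        for pos in range(spec.ref_length):
            base = text[pos]
            if not hit[pos]:
                read_parts.append(base)
                ops.append("=")
                continue
            kind = kinds[pos]
            if kind == 0:  # substitution: one of the other three bases
                choices = spec.alphabet.replace(base, "")
                read_parts.append(choices[rng.integers(0, len(choices))])
                ops.append("X")
            elif kind == 1:  # insertion before this position
                read_parts.append(spec.alphabet[rng.integers(0, n_letters)])
                read_parts.append(base)
                ops.append("I")
                ops.append("=")
            else:  # deletion
                ops.append("D")
        yield PairRecord(
            id=f"pair{idx}",
            text=text,
            pattern="".join(read_parts),
            truth_cigar=canonicalize_cigar(ops),
        )


# ---------------------------------------------------------------------
# readers / writers

TSV_HEADER = ["id", "text_len", "pattern_len", "edits", "cigar"]


def _load_tsv(path: Path) -> Iterator[PairRecord]:
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise InputError(f"{path}:{lineno}: expected id<TAB>text<TAB>pattern")
            yield PairRecord(
                id=row[0],
                text=normalize_sequence(row[1]),
                pattern=normalize_sequence(row[2]),
            )


def _load_paired_files(path_text: Path, path_pattern: Path, fmt: str) -> Iterator[PairRecord]:
    texts = list(SeqIO.parse(str(path_text), fmt))
    patterns = list(SeqIO.parse(str(path_pattern), fmt))
    if len(texts) != len(patterns):
        raise InputError(
            f"unequal record counts: {len(texts)} in {path_text} vs "
            f"{len(patterns)} in {path_pattern}")
    for t_rec, p_rec in zip(texts, patterns):
        yield PairRecord(
            id=t_rec.id,
            text=normalize_sequence(str(t_rec.seq)),
            pattern=normalize_sequence(str(p_rec.seq)),
        )


def load_pairs(path, format: str = "tsv", pattern_path=None) -> Iterator[PairRecord]:
    """Load pair records.

    ``tsv``: one pair per row (id, text, pattern).  ``fasta-pair`` /
    ``fastq-pair``: two files paired by record order (``path`` holds the
    text/reference records, ``pattern_path`` the read records).
    """
    path = Path(path)
    if format == "tsv":
        yield from _load_tsv(path)
    elif format in ("fasta-pair", "fastq-pair"):
        if pattern_path is None:
            raise InputError(f"format {format} needs a second file of read records")
        yield from _load_paired_files(path, Path(pattern_path), format.split("-")[0])
    else:
        raise InputError(f"unknown pair format {format!r}")


def write_alignments(results: Iterable[tuple[PairRecord, Alignment]], path,
                     format: str = "tsv", collapse_m: bool = False) -> None:
    """Write alignment results.

    ``tsv``: header plus one row (id, text_len, pattern_len, edits,
    cigar) per pair.  ``paf``: minimal PAF-like records with the CIGAR
    in a ``cg:Z:`` tag.
    """
    with open(path, "w") as handle:
        if format == "tsv":
            handle.write("\t".join(TSV_HEADER) + "\n")
            for record, aln in results:
                handle.write("\t".join([
                    record.id, str(aln.text_len), str(aln.pattern_len),
                    str(aln.edits), aln.cigar_string(collapse_m=collapse_m),
                ]) + "\n")
        elif format == "paf":
            for record, aln in results:
                matches = sum(c.length for c in aln.cigar if c.op == "=")
                block = sum(c.length for c in aln.cigar)
                handle.write("\t".join([
                    record.id, str(aln.pattern_len), "0", str(aln.pattern_len),
                    "+", record.id, str(aln.text_len), "0", str(aln.text_len),
                    str(matches), str(block), "255",
                    f"NM:i:{aln.edits}",
                    f"cg:Z:{aln.cigar_string(collapse_m=collapse_m)}",
                ]) + "\n")
        else:
            raise InputError(f"unknown output format {format!r}")


def read_alignments_tsv(path) -> Iterator[tuple[str, int, int, int, list[CigarOp]]]:
    """Re-parse a TSV written by :func:`write_alignments` (round-trip hook)."""
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header != TSV_HEADER:
            raise InputError(f"{path}: unexpected header {header}")
        for row in reader:
            if len(row) != 5:
                raise InputError(f"{path}: malformed row {row}")
            yield row[0], int(row[1]), int(row[2]), int(row[3]), parse_cigar(row[4])


def validate_truth(record: PairRecord) -> None:
    """Check that a truth CIGAR consumes exactly both sequences."""
    if record.truth_cigar is None:
        return
    ct, cp = cigar_consumed(record.truth_cigar)
    if ct != len(record.text) or cp != len(record.pattern):
        raise InputError(
            f"{record.id}: truth CIGAR consumes ({ct},{cp}), "
            f"sequences are ({len(record.text)},{len(record.pattern)})")
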