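"""Observed compositions of a codon-count table.

All observed quantities — GC content S, purine content R, their positional
counterparts S_i and R_i, nucleotide frequencies (total and per codon
position), codon frequencies and amino-acid frequencies — are computed over
the 61 sense codons; stop codons are excluded by default from every
denominator. A diagnostic flag can include them where noted.

Content definitions: S = G + C, R = A + G (coding strand), as fractions of
bases. S_i and R_i restrict the count to codon position i in {1, 2, 3}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import (
    ALL_CODONS,
    AMINO_ACIDS,
    BASES,
    GeneticCode,
    sense_codons,
    standard_code,
    synonymous_codons,
)
from .io import CodonCountTable

log = logging.getLogger(__name__)

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def _check_fraction(x: float, name: str) -> float:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return float(x)


@dataclass(frozen=True)
class GlobalContent:
    """Global GC content S and purine content R, fractions in [0, 1]."""

    S: float
    R: float

    def __post_init__(self) -> None:
        _check_fraction(self.S, "S")
        _check_fraction(self.R, "R")


@dataclass(frozen=True)
class PositionalContent:
    """S_i and R_i for codon positions i = 1, 2, 3."""

    S: tuple[float, float, float]
    R: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.S) != 3 or len(self.R) != 3:
            raise ValueError("positional content requires exactly 3 positions")
        for i, (s, r) in enumerate(zip(self.S, self.R), start=1):
            _check_fraction(s, f"S_{i}")
            _check_fraction(r, f"R_{i}")
        object.__setattr__(self, "S", tuple(float(s) for s in self.S))
        object.__setattr__(self, "R", tuple(float(r) for r in self.R))


@dataclass(frozen=True)
class NucleotideFreqs:
    """A, T, G, C frequencies, total and per codon position.

    ``total`` maps base -> fraction over all positions; ``by_position`` is a
    3-tuple of such mappings, one per codon position. Each scope sums to 1.
    """

    total: Mapping[str, float]
    by_position: tuple[Mapping[str, float], ...]

    def __post_init__(self) -> None:
        scopes = [self.total, *self.by_position]
        if len(self.by_position) != 3:
            raise ValueError("by_position must hold exactly 3 scopes")
        for scope in scopes:
            if set(scope) != set(BASES):
                raise ValueError("each scope must map exactly A, T, G, C")
            if any(v < -1e-12 or v > 1 + 1e-12 for v in scope.values()):
                raise ValueError("frequencies must lie in [0, 1]")
            if abs(sum(scope.values()) - 1.0) > 1e-9:
                raise ValueError("frequencies in each scope must sum to 1")


def _position_base_counts(table: CodonCountTable, include_stops: bool = False) -> np.ndarray:
    """3x4 array of base counts per codon position over (sense) codons."""
    codons = ALL_CODONS if include_stops else sense_codons()
    out = np.zeros((3, 4), dtype=float)
    for codon in codons:
        n = table.counts[codon]
        if n:
            for pos, base in enumerate(codon):
                out[pos, _BASE_IDX[base]] += n
    return out


def _sense_total_or_raise(table: CodonCountTable, include_stops: bool = False) -> float:
    total = table.total() if include_stops else table.sense_total()
    if total <= 0:
        raise ValueError(f"{table.label}: no sense-codon counts; cannot compute composition")
    return total


def observed_global_content(
    table: CodonCountTable, include_stops: bool = False
) -> GlobalContent:
    """S and R counted over the table's sense codons.

    S = (#G + #C) / (3 * sense codon total); R = (#A + #G) likewise.
    """
    total = _sense_total_or_raise(table, include_stops)
    counts = _position_base_counts(table, include_stops).sum(axis=0)
    a, c, g, _t = (counts[_BASE_IDX[b]] for b in "ACGT")
    return GlobalContent(S=(g + c) / (3 * total), R=(a + g) / (3 * total))


def observed_positional_content(
    table: CodonCountTable, include_stops: bool = False
) -> PositionalContent:
    """S_i and R_i counted per codon position over sense codons."""
    total = _sense_total_or_raise(table, include_stops)
    counts = _position_base_counts(table, include_stops)
    s = tuple((counts[i, _BASE_IDX["G"]] + counts[i, _BASE_IDX["C"]]) / total for i in range(3))
    r = tuple((counts[i, _BASE_IDX["A"]] + counts[i, _BASE_IDX["G"]]) / total for i in range(3))
    return PositionalContent(S=s, R=r)


def observed_nucleotide_freqs(
    table: CodonCountTable, include_stops: bool = False
) -> NucleotideFreqs:
    """Observed A/T/G/C frequencies, total and at each codon position."""
    total = _sense_total_or_raise(table, include_stops)
    counts = _position_base_counts(table, include_stops)
    by_position = tuple(
        {b: counts[i, _BASE_IDX[b]] / total for b in BASES} for i in range(3)
    )
    overall = counts.sum(axis=0) / (3 * total)
    return NucleotideFreqs(
        total={b: overall[_BASE_IDX[b]] for b in BASES}, by_position=by_position
    )


def observed_codon_distribution(table: CodonCountTable) -> dict[str, float]:
    """Sense-codon frequencies (stop codons excluded from the denominator)."""
    total = _sense_total_or_raise(table)
    return {c: table.counts[c] / total for c in sense_codons()}


def observed_amino_acid_distribution(
    dist: Mapping[str, float], code: GeneticCode | None = None
) -> dict[str, float]:
    """Amino-acid frequencies: per amino acid, the sum over its codons."""
    code = code or standard_code()
    return {
        aa: sum(dist.get(c, 0.0) for c in synonymous_codons(aa, code))
        for aa in AMINO_ACIDS
    }


def filter_collection(
    tables: Sequence[CodonCountTable], min_cds: int = 64
) -> list[CodonCountTable]:
    """Drop tables tabulated from fewer than ``min_cds`` coding sequences.

    Tables with ``n_cds >= min_cds`` are retained (a table with exactly 64
    CDS passes the default filter). Tables lacking ``n_cds`` metadata are a
    hard error listing the offending labels.
    """
    missing = [t.label for t in tables if t.n_cds is None]
    if missing:
        raise ValueError(f"tables lack n_cds metadata: {missing}")
    kept = [t for t in tables if t.n_cds >= min_cds]
    log.info("filter_collection: retained %d of %d tables (min_cds=%d)",
             len(kept), len(tables), min_cds)
    return kept
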