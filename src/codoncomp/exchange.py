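"""Amino-acid exchange matrices from aligned orthologous protein sequences.

An exchange matrix is a symmetric 20x20 tally of residue pairs observed in
the columns of orthologous protein alignments: off-diagonal entries count
substitutions (exchanges) between two amino acids, the diagonal counts
conserved positions. Columns containing a gap or an unknown residue ('X')
in either member of a pair are excluded both from the tally and from the
identity computation. Alignments below an identity threshold (default 85%,
removal strictly below) are filtered out before counting, keeping the
tallies to closely related orthologs where alignment columns are reliable.
No evolutionary-distance correction or frequency normalisation is applied;
the raw symmetric counts are the ranking key, with a per-comparable-column
normalised value available as a report column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import AMINO_ACIDS

log = logging.getLogger(__name__)

_AA_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_GAP = "-"
_UNKNOWN = "X"
_ALPHABET = set(AMINO_ACIDS) | {_GAP, _UNKNOWN}


@dataclass(frozen=True)
class ProteinAlignment:
    """Two or more aligned protein sequences of equal length."""

    records: tuple[tuple[str, str], ...]  # (id, aligned sequence)
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(f"alignment {self.label!r} needs at least 2 sequences")
        records = tuple((rid, seq.upper()) for rid, seq in self.records)
        lengths = {len(seq) for _, seq in records}
        if len(lengths) != 1:
            raise ValueError(f"alignment {self.label!r}: sequences differ in length")
        for rid, seq in records:
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"alignment {self.label!r}, sequence {rid!r}: invalid symbols {sorted(bad)}"
                )
        object.__setattr__(self, "records", records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])


def read_protein_alignment_fasta(path: str | Path) -> ProteinAlignment:
    """Read one aligned-FASTA file (gap character '-') as a ProteinAlignment."""
    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return ProteinAlignment(records=tuple(records), label=path.stem)


def _pair_identity(a: str, b: str) -> float:
    comparable = matches = 0
    for x, y in zip(a, b):
        if x in (_GAP, _UNKNOWN) or y in (_GAP, _UNKNOWN):
            continue
        comparable += 1
        if x == y:
            matches += 1
    return matches / comparable if comparable else 0.0


def alignment_identity(aln: ProteinAlignment) -> float:
    """Fraction of identical residues over columns comparable in a pair.

    Pairwise alignments are scored directly; alignments of more than two
    sequences are scored as the mean over all unordered sequence pairs.
    Returns 0 when no column is comparable.
    """
    pairs = list(combinations([seq for _, seq in aln.records], 2))
    return sum(_pair_identity(a, b) for a, b in pairs) / len(pairs)


def filter_alignments(
    alns: Sequence[ProteinAlignment], min_identity: float = 0.85
) -> list[ProteinAlignment]:
    """Keep alignments with identity >= ``min_identity`` (default 85%)."""
    kept = [a for a in alns if alignment_identity(a) >= min_identity]
    log.info(
        "filter_alignments: retained %d of %d alignments (min_identity=%.2f)",
        len(kept), len(alns), min_identity,
    )
    return kept


@dataclass
class ExchangeMatrix:
    """Symmetric 20x20 residue-pair tally; diagonal = conserved columns."""

    counts: np.ndarray
    n_columns_compared: int = 0
    group_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (20, 20):
            raise ValueError("exchange matrix must be 20x20")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("exchange matrix must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("exchange matrix counts must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=AMINO_ACIDS, columns=AMINO_ACIDS)


def build_exchange_matrix(
    alns: Sequence[ProteinAlignment], group_label: str = ""
) -> ExchangeMatrix:
    """Tally residue pairs over every alignment, sequence pair and column.

    For each column where both members of a pair carry a standard residue:
    differing residues x != y increment counts[x][y] and counts[y][x] by 1;
    identical residues increment the diagonal by 1.
    """
    counts = np.zeros((20, 20), dtype=float)
    n_columns = 0
    for aln in alns:
        for (_, a), (_, b) in combinations(aln.records, 2):
            for x, y in zip(a, b):
                if x in (_GAP, _UNKNOWN) or y in (_GAP, _UNKNOWN):
                    continue
                n_columns += 1
                i, j = _AA_IDX[x], _AA_IDX[y]
                if i == j:
                    counts[i, i] += 1
                else:
                    counts[i, j] += 1
                    counts[j, i] += 1
    return ExchangeMatrix(counts=counts, n_columns_compared=n_columns, group_label=group_label)


def top_exchange_pairs(
    matrix: ExchangeMatrix, k: int = 10
) -> list[tuple[tuple[str, str], float]]:
    """The k most exchangeable amino-acid pairs, count-descending.

    Pairs are unordered, reported alphabetically within the pair; ties are
    broken lexicographically by pair label. At most the 190 off-diagonal
    pairs are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = [
        ((AMINO_ACIDS[i], AMINO_ACIDS[j]), float(matrix.counts[i, j]))
        for i, j in combinations(range(20), 2)
    ]
    pairs.sort(key=lambda item: (-item[1], item[0]))
    return pairs[:k]
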