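"""The standard genetic code: codon enumeration, translation, degeneracy.

Only the standard code (NCBI translation table 1) is supported. Species
using alternative codes are outside the scope of the composition models,
so requesting any other table is an explicit error rather than a silent
fallback.

Codons are plain 3-character strings over the DNA alphabet ``ACGT``
(``U`` is transliterated to ``T`` by the readers in :mod:`codoncomp.io`).
The canonical codon order used everywhere in this package is lexicographic
with ``A < C < G < T``, i.e. ``AAA, AAC, ..., TTT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from types import MappingProxyType
from typing import Mapping

from Bio.Data import CodonTable as _BioCodonTable

#: DNA alphabet in canonical (lexicographic) order.
BASES = "ACGT"

#: Symbol used for the translation product of a stop codon.
STOP = "*"

#: The 20 standard amino acids, one-letter code, alphabetical.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: All 64 codons in canonical lexicographic order (A < C < G < T).
ALL_CODONS = tuple("".join(p) for p in product(BASES, repeat=3))

#: Stop codons of the standard code.
STOP_CODONS = ("TAA", "TAG", "TGA")


def is_valid_codon(codon: str) -> bool:
    """True if ``codon`` is a 3-letter string over ``ACGT``."""
    return (
        isinstance(codon, str)
        and len(codon) == 3
        and all(b in BASES for b in codon)
    )


def require_codon(codon: str) -> str:
    """Validate a codon, raising ``ValueError`` for anything malformed."""
    if not is_valid_codon(codon):
        raise ValueError(f"not a valid codon over ACGT: {codon!r}")
    return codon


@dataclass(frozen=True)
class GeneticCode:
    """A complete codon -> amino-acid table (standard code only).

    ``table`` maps each of the 64 codons to a one-letter amino acid or
    ``'*'`` for stop. Construction enforces the structure of the standard
    code: exactly 3 stop codons (TAA, TAG, TGA), 61 sense codons, and all
    20 amino acids represented.
    """

    table: Mapping[str, str]
    id: int = 1

    def __post_init__(self) -> None:
        tbl = dict(self.table)
        if set(tbl) != set(ALL_CODONS):
            raise ValueError("genetic code must map exactly the 64 codons")
        stops = {c for c, aa in tbl.items() if aa == STOP}
        if stops != set(STOP_CODONS):
            raise ValueError(f"standard code requires stops {STOP_CODONS}, got {sorted(stops)}")
        encoded = {aa for aa in tbl.values() if aa != STOP}
        if encoded != set(AMINO_ACIDS):
            raise ValueError("standard code must encode exactly the 20 standard amino acids")
        object.__setattr__(self, "table", MappingProxyType(tbl))

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return STOP_CODONS

    def is_stop(self, codon: str) -> bool:
        return self.table[require_codon(codon)] == STOP


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard genetic code (NCBI translation table 1)."""
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    table = {c: bio.forward_table.get(c, STOP) for c in ALL_CODONS}
    return GeneticCode(table=table, id=1)


def get_genetic_code(table_id: int = 1) -> GeneticCode:
    """Return the genetic code for ``table_id``.

    Only table 1 is supported; anything else raises ``ValueError``, matching
    the exclusion of species with alternative genetic codes from the models.
    """
    if table_id != 1:
        raise ValueError(
            f"translation table {table_id} is not supported; "
            "only the standard code (table 1) is implemented"
        )
    return standard_code()


def sense_codons(code: GeneticCode | None = None) -> tuple[str, ...]:
    """The 61 sense codons in canonical lexicographic order."""
    code = code or standard_code()
    return tuple(c for c in ALL_CODONS if code.table[c] != STOP)


def translate(codon: str, code: GeneticCode | None = None) -> str:
    """Translate one codon; returns a one-letter amino acid or ``'*'``."""
    code = code or standard_code()
    return code.table[require_codon(codon)]


def synonymous_codons(aa: str, code: GeneticCode | None = None) -> tuple[str, ...]:
    """All codons encoding amino acid ``aa``, in canonical order."""
    code = code or standard_code()
    if aa not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid symbol: {aa!r}")
    return tuple(c for c in ALL_CODONS if code.table[c] == aa)
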