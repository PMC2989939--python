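"""Readers and writers: CDS FASTA, SPSUM-style codon-usage tables, TSV reports.

The codon-usage dialect is the two-line-per-record format used by species
summary files of the Codon Usage Database: a header line carrying a label
(and optionally a CDS count), followed by a line of 64 whitespace-separated
integer codon counts in a declared column order. Because that column order
is a property of the file, not of the data model, the reader takes an
explicit :class:`CodonOrderSpec`; a default spec matching the database's
documented order ships with the package and can also be loaded from a
one-line config file.
"""

from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .genetic_code import ALL_CODONS, BASES, is_valid_codon

log = logging.getLogger(__name__)

# Column order of the Codon Usage Database species-summary files,
# transliterated from RNA to DNA. Codons are grouped by amino acid
# (Arg, Leu, Ser, Thr, Pro, Ala, Gly, Val, Lys, Asn, Gln, His, Glu,
# Asp, Tyr, Cys, Phe, Ile, Met, Trp) with the three stops last.
_SPSUM_ORDER_RNA = (
    "CGA CGC CGG CGU AGA AGG CUA CUC CUG CUU UUA UUG UCA UCC UCG UCU "
    "AGC AGU ACA ACC ACG ACU CCA CCC CCG CCU GCA GCC GCG GCU GGA GGC "
    "GGG GGU GUA GUC GUG GUU AAA AAG AAC AAU CAA CAG CAC CAU GAA GAG "
    "GAC GAU UAC UAU UGC UGU UUC UUU AUA AUC AUU AUG UGG UAA UAG UGA"
)


def _normalize_codon(token: str) -> str:
    return token.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class CodonOrderSpec:
    """A permutation of the 64 codons defining a file's column order."""

    order: tuple[str, ...]

    def __post_init__(self) -> None:
        order = tuple(_normalize_codon(c) for c in self.order)
        if len(order) != 64 or set(order) != set(ALL_CODONS):
            raise ValueError("codon order spec must list all 64 codons exactly once")
        object.__setattr__(self, "order", order)

    @classmethod
    def from_file(cls, path: str | Path) -> "CodonOrderSpec":
        """Load an order spec from a config file of 64 whitespace-separated codons."""
        tokens = Path(path).read_text().split()
        return cls(order=tuple(tokens))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(" ".join(self.order) + "\n")


#: Default column order for SPSUM-style files (Codon Usage Database dialect).
DEFAULT_SPSUM_ORDER = CodonOrderSpec(order=tuple(_SPSUM_ORDER_RNA.split()))


@dataclass
class CodonCountTable:
    """Codon counts for one sequence collection (a species, or a gene set).

    ``counts`` maps every one of the 64 codons to a non-negative number.
    File readers produce integer counts; the simulator's expected-count
    tables may carry real-valued counts. ``n_cds`` records how many coding
    sequences contributed, when known; ``skipped`` tallies codons dropped
    for containing non-ACGT symbols.
    """

    label: str
    counts: dict[str, float]
    n_cds: int | None = None
    skipped: int = 0

    def __post_init__(self) -> None:
        counts = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            key = _normalize_codon(codon)
            if key not in counts:
                raise ValueError(f"{self.label}: invalid codon key {codon!r}")
            if not isinstance(n, numbers.Real) or n < 0:
                raise ValueError(f"{self.label}: negative or non-numeric count for {codon}")
            counts[key] = n
        self.counts = counts

    def total(self) -> float:
        """Total codon count including stop codons."""
        return sum(self.counts.values())

    def sense_total(self) -> float:
        """Total count over the 61 sense codons."""
        from .genetic_code import sense_codons

        return sum(self.counts[c] for c in sense_codons())

    def scaled(self, k: float) -> "CodonCountTable":
        return CodonCountTable(
            label=self.label,
            counts={c: n * k for c, n in self.counts.items()},
            n_cds=self.n_cds,
            skipped=self.skipped,
        )


def aggregate_tables(tables: Sequence[CodonCountTable], label: str = "aggregate") -> CodonCountTable:
    """Sum codon counts across tables; n_cds sums where present on all."""
    if not tables:
        raise ValueError("cannot aggregate an empty list of tables")
    counts = {c: 0.0 for c in ALL_CODONS}
    for t in tables:
        for c in ALL_CODONS:
            counts[c] += t.counts[c]
    n_cds = None
    if all(t.n_cds is not None for t in tables):
        n_cds = sum(t.n_cds for t in tables)  # type: ignore[misc]
    return CodonCountTable(
        label=label,
        counts=counts,
        n_cds=n_cds,
        skipped=sum(t.skipped for t in tables),
    )


def _count_codons_in_record(seq: str, name: str, strict_frame: bool) -> CodonCountTable:
    seq = seq.upper().replace("U", "T")
    if strict_frame and len(seq) % 3 != 0:
        raise ValueError(
            f"record {name!r}: length {len(seq)} is not divisible by 3 "
            "(use the lenient frame policy to drop the trailing partial codon)"
        )
    if len(seq) % 3 != 0:
        log.warning("record %r: dropping %d trailing bases", name, len(seq) % 3)
    counts = {c: 0 for c in ALL_CODONS}
    skipped = 0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if is_valid_codon(codon):
            counts[codon] += 1
        else:
            skipped += 1
    return CodonCountTable(label=name, counts=counts, n_cds=1, skipped=skipped)


def read_cds_fasta(
    path: str | Path, strict_frame: bool = True
) -> tuple[list[CodonCountTable], CodonCountTable]:
    """Read in-frame coding sequences from FASTA into codon-count tables.

    Every record is read in frame 1 (the inputs are CDS by construction;
    no ORF search). Codons containing any symbol outside ACGT are skipped
    and tallied in the record's ``skipped`` field. Stop codons ARE counted
    here — excluding them is a composition-layer decision, not an I/O one.

    Returns ``(per_record_tables, aggregate_table)``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    tables = [
        _count_codons_in_record(str(rec.seq), rec.id, strict_frame) for rec in records
    ]
    return tables, aggregate_tables(tables, label=path.stem)


def read_codon_usage_table(
    path: str | Path, order: CodonOrderSpec | None = None
) -> list[CodonCountTable]:
    """Read an SPSUM-style codon-usage file.

    Each record is two lines: ``label[<TAB>n_cds]`` then 64 integer counts
    in the order given by ``order`` (default: the Codon Usage Database
    column order). Counts are mapped onto the canonical codon order.
    """
    order = order or DEFAULT_SPSUM_ORDER
    path = Path(path)
    lines = [
        (i + 1, ln) for i, ln in enumerate(path.read_text().splitlines()) if ln.strip()
    ]
    if len(lines) % 2 != 0:
        raise ValueError(f"{path}: odd number of non-blank lines; expected header/counts pairs")
    tables = []
    for (hno, header), (cno, counts_line) in zip(lines[::2], lines[1::2]):
        parts = header.split("\t")
        label = parts[0].strip()
        n_cds = None
        if len(parts) > 1 and parts[1].strip():
            n_cds = int(parts[1])
        fields = counts_line.split()
        if len(fields) != 64:
            raise ValueError(f"{path}:{cno}: expected 64 counts, found {len(fields)}")
        try:
            values = [int(f) for f in fields]
        except ValueError as e:
            raise ValueError(f"{path}:{cno}: non-integer codon count") from e
        if any(v < 0 for v in values):
            raise ValueError(f"{path}:{cno}: negative codon count")
        counts = dict(zip(order.order, values))
        tables.append(CodonCountTable(label=label, counts=counts, n_cds=n_cds))
    return tables


def write_codon_usage_table(
    tables: Iterable[CodonCountTable],
    path: str | Path,
    order: CodonOrderSpec | None = None,
) -> None:
    """Write tables in the SPSUM-style two-line-per-record dialect."""
    order = order or DEFAULT_SPSUM_ORDER
    out = []
    for t in tables:
        header = t.label if t.n_cds is None else f"{t.label}\t{t.n_cds}"
        values = []
        for c in order.order:
            n = t.counts[c]
            if n != int(n):
                raise ValueError(
                    f"{t.label}: non-integer count for {c}; only integer tables can be written"
                )
            values.append(str(int(n)))
        out.append(header)
        out.append(" ".join(values))
    Path(path).write_text("\n".join(out) + "\n")


def write_composition_report(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV report; floats carry 12 significant digits for round-tripping."""
    rows.to_csv(path, sep="\t", index=False, float_format="%.12g", lineterminator="\n")


def read_composition_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
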