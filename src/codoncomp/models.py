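"""Expectation models for nucleotide, codon and amino-acid compositions.

Both models take GC content (S) and purine content (R) of a coding sequence
collection as their only compositional parameters and treat the two as
statistically independent, so that each nucleotide frequency factorises:

    A = (1 - S) * R        T = (1 - S) * (1 - R)
    G = S * R              C = S * (1 - R)

The same identities applied to position-specific contents (S_i, R_i) give
the nucleotide frequencies at each codon position. A sense codon xyz then
has expected frequency x1 * y2 * z3 renormalised over the 61 sense codons
(equivalently, divided by one minus the summed stop-codon products), and an
amino acid's expected frequency is the sum over its synonymous codons.

The two models differ only in where S_i and R_i come from:

* Model 1 predicts them from global S and R through straight-line relations
  fitted across a species collection (empirical prior knowledge).
* Model 2 counts them directly from the input table (purely mechanistic).

With identity relations (slope 1, intercept 0) Model 1 degenerates to using
the global contents at every position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import (
    GlobalContent,
    NucleotideFreqs,
    PositionalContent,
    observed_codon_distribution,
    observed_amino_acid_distribution,
    observed_global_content,
    observed_nucleotide_freqs,
    observed_positional_content,
)
from .genetic_code import (
    AMINO_ACIDS,
    BASES,
    GeneticCode,
    STOP_CODONS,
    sense_codons,
    standard_code,
    synonymous_codons,
)
from .io import CodonCountTable

log = logging.getLogger(__name__)

_PREDICTORS = ("S", "R")
_POSITIONS = (1, 2, 3)


# ---------------------------------------------------------------------------
# Nucleotide expectations
# ---------------------------------------------------------------------------

def expected_nucleotides(content: GlobalContent) -> dict[str, float]:
    """Expected global A/T/G/C frequencies from S and R.

    A = (1-S)R, T = (1-S)(1-R), G = SR, C = S(1-R). The four always sum to
    1 and reconstruct the inputs: G + C = S, A + G = R.
    """
    s, r = content.S, content.R
    return {
        "A": (1 - s) * r,
        "T": (1 - s) * (1 - r),
        "G": s * r,
        "C": s * (1 - r),
    }


def expected_positional_nucleotides(
    content: PositionalContent,
) -> tuple[dict[str, float], ...]:
    """Expected A_i/T_i/G_i/C_i per codon position from (S_i, R_i)."""
    return tuple(
        expected_nucleotides(GlobalContent(S=s, R=r))
        for s, r in zip(content.S, content.R)
    )


# ---------------------------------------------------------------------------
# Positional-content strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalRelation:
    """A fitted line mapping a global content to one positional content."""

    predictor: str  # "S" or "R"
    position: int   # 1, 2, or 3
    slope: float
    intercept: float
    r_squared: float = math.nan

    def __post_init__(self) -> None:
        if self.predictor not in _PREDICTORS:
            raise ValueError(f"predictor must be one of {_PREDICTORS}")
        if self.position not in _POSITIONS:
            raise ValueError("position must be 1, 2 or 3")

    def predict(self, x: float) -> float:
        """Predicted positional content, clamped into [0, 1]."""
        y = self.intercept + self.slope * x
        if y < 0.0 or y > 1.0:
            log.warning(
                "relation %s_%d prediction %.4f clamped into [0, 1]",
                self.predictor, self.position, y,
            )
        return min(1.0, max(0.0, y))


@dataclass(frozen=True)
class EmpiricalRelationSet:
    """Model 1's prior knowledge: six lines, S->S_i and R->R_i for i=1..3."""

    relations: Mapping[tuple[str, int], EmpiricalRelation]
    provenance: str = ""
    n_species: int = 0

    def __post_init__(self) -> None:
        expected_keys = {(p, i) for p in _PREDICTORS for i in _POSITIONS}
        if set(self.relations) != expected_keys:
            missing = sorted(expected_keys - set(self.relations))
            raise ValueError(f"relation set incomplete; missing {missing}")
        object.__setattr__(self, "relations", dict(self.relations))

    @classmethod
    def identity(cls, provenance: str = "identity") -> "EmpiricalRelationSet":
        """Slope-1, intercept-0 relations: S_i = S and R_i = R everywhere."""
        rel = {
            (p, i): EmpiricalRelation(predictor=p, position=i, slope=1.0, intercept=0.0, r_squared=1.0)
            for p in _PREDICTORS
            for i in _POSITIONS
        }
        return cls(relations=rel, provenance=provenance)

    def predict_positional(self, content: GlobalContent) -> PositionalContent:
        s = tuple(self.relations[("S", i)].predict(content.S) for i in _POSITIONS)
        r = tuple(self.relations[("R", i)].predict(content.R) for i in _POSITIONS)
        return PositionalContent(S=s, R=r)

    def to_file(self, path: str | Path) -> None:
        """Serialise to a plain-text key-value file (bit-exact round trip)."""
        lines = [
            f"provenance\t{self.provenance}",
            f"n_species\t{self.n_species}",
        ]
        for p in _PREDICTORS:
            for i in _POSITIONS:
                rel = self.relations[(p, i)]
                lines.append(
                    f"{p}\t{i}\t{rel.slope!r}\t{rel.intercept!r}\t{rel.r_squared!r}"
                )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "EmpiricalRelationSet":
        provenance, n_species = "", 0
        relations: dict[tuple[str, int], EmpiricalRelation] = {}
        for ln in Path(path).read_text().splitlines():
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if fields[0] == "provenance":
                provenance = fields[1] if len(fields) > 1 else ""
            elif fields[0] == "n_species":
                n_species = int(fields[1])
            elif fields[0] in _PREDICTORS:
                p, i, slope, intercept, r2 = fields
                relations[(p, int(i))] = EmpiricalRelation(
                    predictor=p,
                    position=int(i),
                    slope=float(slope),
                    intercept=float(intercept),
                    r_squared=float(r2),
                )
            else:
                raise ValueError(f"{path}: unrecognised relations line {ln!r}")
        return cls(relations=relations, provenance=provenance, n_species=n_species)


def model2_positional_content(table: CodonCountTable) -> PositionalContent:
    """Model 2: count S_i and R_i directly from the table (sense codons)."""
    return observed_positional_content(table)


def model1_positional_content(
    content: GlobalContent, relations: EmpiricalRelationSet
) -> PositionalContent:
    """Model 1: deduce S_i and R_i from fitted linear relations."""
    return relations.predict_positional(content)


def fit_empirical_relations(
    tables: Sequence[CodonCountTable],
    label: str = "fitted",
    min_tables: int = 3,
) -> EmpiricalRelationSet:
    """Fit the six S->S_i and R->R_i lines across a species collection.

    One point per table: the table's observed global content against its
    observed positional content. Ordinary least squares, unweighted. At
    least ``min_tables`` tables are required (two points define a line but
    carry no residual information), and the predictor must vary across the
    collection.
    """
    if len(tables) < min_tables:
        raise ValueError(f"need at least {min_tables} tables to fit relations, got {len(tables)}")
    glob = [observed_global_content(t) for t in tables]
    pos = [observed_positional_content(t) for t in tables]
    x = {"S": np.array([g.S for g in glob]), "R": np.array([g.R for g in glob])}
    relations: dict[tuple[str, int], EmpiricalRelation] = {}
    for p in _PREDICTORS:
        if np.ptp(x[p]) == 0.0:
            raise ValueError(f"global {p} identical across all tables; cannot fit {p} relations")
        for i in _POSITIONS:
            y = np.array([getattr(pc, p)[i - 1] for pc in pos])
            fit = stats.linregress(x[p], y)
            relations[(p, i)] = EmpiricalRelation(
                predictor=p,
                position=i,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=float(fit.rvalue) ** 2,
            )
    return EmpiricalRelationSet(relations=relations, provenance=label, n_species=len(tables))


# ---------------------------------------------------------------------------
# Codon and amino-acid expectations
# ---------------------------------------------------------------------------

def expected_codon_distribution(
    pos_freqs: Sequence[Mapping[str, float]], code: GeneticCode | None = None
) -> dict[str, float]:
    """Expected sense-codon frequencies from positional nucleotide frequencies.

    For codon xyz the unnormalised weight is x1*y2*z3; the distribution is
    renormalised by 1 minus the summed stop-codon products so it sums to 1
    over the 61 sense codons.
    """
    code = code or standard_code()
    if len(pos_freqs) != 3:
        raise ValueError("pos_freqs must supply exactly 3 positional scopes")
    stop_mass = sum(
        pos_freqs[0][c[0]] * pos_freqs[1][c[1]] * pos_freqs[2][c[2]]
        for c in STOP_CODONS
    )
    normalizer = 1.0 - stop_mass
    if normalizer < 1e-9:
        raise ValueError("stop codons carry (almost) all probability mass; cannot normalise")
    return {
        c: pos_freqs[0][c[0]] * pos_freqs[1][c[1]] * pos_freqs[2][c[2]] / normalizer
        for c in sense_codons(code)
    }


def expected_amino_acid_distribution(
    dist: Mapping[str, float], code: GeneticCode | None = None
) -> dict[str, float]:
    """Expected amino-acid frequencies: sum over each amino acid's codons."""
    code = code or standard_code()
    return {
        aa: sum(dist.get(c, 0.0) for c in synonymous_codons(aa, code))
        for aa in AMINO_ACIDS
    }


# ---------------------------------------------------------------------------
# Full pipeline and reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionBundle:
    """Nucleotide, codon and amino-acid compositions for one table.

    ``kind`` is "observed" or "expected"; expected bundles carry the model
    tag (1 or 2) and the positional contents that drove the prediction.
    """

    label: str
    kind: str
    nucleotide: NucleotideFreqs
    codon: Mapping[str, float]
    amino_acid: Mapping[str, float]
    content: GlobalContent
    positional_content: PositionalContent
    model_tag: int | None = None


def observe(table: CodonCountTable, code: GeneticCode | None = None) -> CompositionBundle:
    """Observed composition bundle for a table (stop codons excluded)."""
    code = code or standard_code()
    codon = observed_codon_distribution(table)
    return CompositionBundle(
        label=table.label,
        kind="observed",
        nucleotide=observed_nucleotide_freqs(table),
        codon=codon,
        amino_acid=observed_amino_acid_distribution(codon, code),
        content=observed_global_content(table),
        positional_content=observed_positional_content(table),
    )


def predict(
    table: CodonCountTable,
    model: int,
    relations: EmpiricalRelationSet | None = None,
    code: GeneticCode | None = None,
) -> CompositionBundle:
    """Expected composition of a table under Model 1 or Model 2.

    Model 1 requires a fitted :class:`EmpiricalRelationSet`; Model 2 forbids
    one (its positional contents are counted from the table itself).
    """
    code = code or standard_code()
    content = observed_global_content(table)
    if model == 1:
        if relations is None:
            raise ValueError("Model 1 requires an EmpiricalRelationSet")
        pos_content = model1_positional_content(content, relations)
    elif model == 2:
        if relations is not None:
            raise ValueError("Model 2 does not take empirical relations")
        pos_content = model2_positional_content(table)
    else:
        raise ValueError(f"model must be 1 or 2, got {model!r}")
    by_position = expected_positional_nucleotides(pos_content)
    codon = expected_codon_distribution(by_position, code)
    return CompositionBundle(
        label=table.label,
        kind="expected",
        nucleotide=NucleotideFreqs(
            total=expected_nucleotides(content), by_position=by_position
        ),
        codon=codon,
        amino_acid=expected_amino_acid_distribution(codon, code),
        content=content,
        positional_content=pos_content,
        model_tag=model,
    )


def deviation_report(
    observed: CompositionBundle, expected: CompositionBundle
) -> pd.DataFrame:
    """Observed vs expected, per item: signed difference and ratio.

    Rows cover global and positional nucleotide frequencies, the 61 sense
    codons and the 20 amino acids. ``difference`` is observed - expected;
    ``ratio`` is observed / expected where expected > 0 (NaN otherwise).
    """
    if observed.label != expected.label:
        raise ValueError(
            f"label mismatch: observed {observed.label!r} vs expected {expected.label!r}"
        )
    rows = []

    def emit(category: str, item: str, obs: float, exp: float) -> None:
        rows.append(
            {
                "label": observed.label,
                "category": category,
                "item": item,
                "observed": obs,
                "expected": exp,
                "difference": obs - exp,
                "ratio": obs / exp if exp > 0 else math.nan,
            }
        )

    for b in BASES:
        emit("nucleotide", b, observed.nucleotide.total[b], expected.nucleotide.total[b])
    for i in range(3):
        for b in BASES:
            emit(
                f"nucleotide_pos{i + 1}",
                b,
                observed.nucleotide.by_position[i][b],
                expected.nucleotide.by_position[i][b],
            )
    for c in sense_codons():
        emit("codon", c, observed.codon[c], expected.codon[c])
    for aa in AMINO_ACIDS:
        emit("amino_acid", aa, observed.amino_acid[aa], expected.amino_acid[aa])
    return pd.DataFrame(rows)
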