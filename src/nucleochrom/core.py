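"""Core data model shared across the pipeline.

Coordinate convention: all internal coordinates are 0-based, half-open
``[start, end)``.  Conversion to/from 1-based closed systems (GFF3, .pairs)
happens exactly once, at the file-format boundary (see :mod:`nucleochrom.io`).

Fragments are represented as a :class:`pandas.DataFrame` with columns
``chrom`` (str), ``start`` (int), ``end`` (int) and ``weight`` (float in
(0, 1]); helper constructors live here so every module agrees on the schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("nucleus", "nucleomorph", "mitochondrion", "plastid")

FRAGMENT_COLUMNS = ["chrom", "start", "end", "weight"]


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


@dataclass(frozen=True)
class Gene:
    """A gene annotation on a chromosome.

    ``start``/``end`` are 0-based half-open; ``tss``/``tes`` are derived from
    strand (TSS is the 5' end of the transcript).
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    is_rdna: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval for {self.gene_id}: [{self.start},{self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CompartmentalizedGenome:
    """A genome split across cellular compartments.

    Attributes
    ----------
    sequences
        Mapping chromosome name -> DNA string (upper-case ACGT).
    compartment
        Mapping chromosome name -> compartment label.
    copy_number
        Mapping chromosome name -> relative copy number (> 0).
    genes
        Gene annotations; every gene must lie within its chromosome.
    telomeres
        ``(chrom, start, end)`` intervals marking telomeric ends.
    """

    sequences: dict[str, str]
    compartment: dict[str, str]
    copy_number: dict[str, float]
    genes: list[Gene] = field(default_factory=list)
    telomeres: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom in self.sequences:
            if chrom not in self.compartment:
                raise ValueError(f"chromosome {chrom} has no compartment label")
            if self.compartment[chrom] not in COMPARTMENTS:
                raise ValueError(
                    f"unknown compartment {self.compartment[chrom]!r} for {chrom}"
                )
            if self.copy_number.get(chrom, 0) <= 0:
                raise ValueError(f"copy number of {chrom} must be > 0")
        for g in self.genes:
            if g.chrom not in self.sequences:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > len(self.sequences[g.chrom]):
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")
        for chrom, start, end in self.telomeres:
            if chrom not in self.sequences:
                raise ValueError(f"telomere on unknown chromosome {chrom}")
            if not 0 <= start < end <= len(self.sequences[chrom]):
                raise ValueError(f"telomere [{start},{end}) outside {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def chroms_of(self, compartment: str) -> list[str]:
        return [c for c in self.sequences if self.compartment[c] == compartment]

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]


def make_fragments(
    chroms: Sequence[str] | np.ndarray,
    starts: Sequence[int] | np.ndarray,
    ends: Sequence[int] | np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble a fragment table with the canonical column schema."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if weights is None:
        weights = np.ones(len(starts))
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "start": starts,
            "end": ends,
            "weight": np.asarray(weights, dtype=float),
        }
    )
    validate_fragments(df)
    return df


def validate_fragments(
    fragments: pd.DataFrame, genome: CompartmentalizedGenome | None = None
) -> None:
    """Check the fragment schema and (optionally) chromosome bounds."""
    missing = [c for c in FRAGMENT_COLUMNS if c not in fragments.columns]
    if missing:
        raise ValueError(f"fragment table missing columns: {missing}")
    if len(fragments) == 0:
        return
    if (fragments["start"] < 0).any():
        raise ValueError("fragment with negative start")
    if (fragments["end"] <= fragments["start"]).any():
        raise ValueError("fragment with end <= start")
    if (fragments["weight"] <= 0).any() or (fragments["weight"] > 1).any():
        raise ValueError("fragment weights must lie in (0, 1]")
    if genome is not None:
        for chrom, sub in fragments.groupby("chrom", sort=False):
            if chrom not in genome.sequences:
                raise ValueError(f"fragment on unknown chromosome {chrom}")
            if int(sub["end"].max()) > genome.chrom_length(str(chrom)):
                raise ValueError(f"fragment past end of chromosome {chrom}")


def fragment_midpoints(fragments: pd.DataFrame) -> np.ndarray:
    """Integer midpoints, ``(start + end) // 2``."""
    return ((fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2).astype(
        np.int64
    )


def total_weight(fragments: pd.DataFrame) -> float:
    return float(fragments["weight"].sum())
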