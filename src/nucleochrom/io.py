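"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA (60-column wrap), GFF3 (1-based closed), BED3+score, bedGraph
(0-based half-open), 4DN-style ``.pairs`` (1-based positions) and TSV.
Coordinate conversion between 1-based file formats and the internal
0-based half-open convention happens here and only here.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import CompartmentalizedGenome, Gene, make_fragments, validate_fragments


class ParseError(ValueError):
    """A malformed record; carries the offending file and line number."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(parts)
                name = line[1:].split()[0]
                if not name:
                    raise ParseError(path, lineno, "empty FASTA header")
                parts = []
            else:
                if name is None:
                    raise ParseError(path, lineno, "sequence before first header")
                parts.append(line.upper())
    if name is not None:
        sequences[name] = "".join(parts)
    return sequences


# ---------------------------------------------------------------------------
# GFF3 — genes only, 1-based closed on disk, 0-based half-open in memory

def write_gff3(genes: Iterable[Gene], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.is_rdna:
                attrs += ";gene_biotype=rRNA"
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "nucleochrom",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> list[Gene]:
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(fields)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(path, lineno, f"invalid GFF3 interval {start1}..{end1}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            genes.append(
                Gene(
                    chrom=chrom,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    gene_id=attr_map.get("ID", f"gene{lineno}"),
                    is_rdna=attr_map.get("gene_biotype") == "rRNA",
                )
            )
    return genes


# ---------------------------------------------------------------------------
# BED — fragments as BED3 + weight in the score column

def write_bed(fragments: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_fragments(fragments)
    with open(path, "w") as fh:
        for chrom, start, end, weight in fragments[
            ["chrom", "start", "end", "weight"]
        ].itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t{weight:.6g}\n")


def read_bed(
    path: str | os.PathLike, genome: CompartmentalizedGenome | None = None
) -> pd.DataFrame:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    weights: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "BED record needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer BED coordinates") from None
            if start < 0:
                raise ParseError(path, lineno, f"negative start {start}")
            if end <= start:
                raise ParseError(path, lineno, f"end {end} <= start {start}")
            if genome is not None:
                if fields[0] not in genome.sequences:
                    raise ParseError(path, lineno, f"unknown chromosome {fields[0]}")
                if end > genome.chrom_length(fields[0]):
                    raise ParseError(
                        path, lineno, f"end {end} beyond chromosome {fields[0]}"
                    )
            weight = float(fields[3]) if len(fields) > 3 else 1.0
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            weights.append(weight)
    return make_fragments(chroms, starts, ends, weights)


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(
    tracks: Mapping[str, np.ndarray], path: str | os.PathLike, precision: int = 6
) -> None:
    """Write per-position score arrays, merging runs of equal value."""
    with open(path, "w") as fh:
        for chrom, values in tracks.items():
            values = np.asarray(values, dtype=float)
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:.{precision}g}\n")


def read_bedgraph(
    path: str | os.PathLike, lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    tracks = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, "bedGraph record needs 4 columns")
            chrom = fields[0]
            if chrom not in tracks:
                raise ParseError(path, lineno, f"unknown chromosome {chrom}")
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            if not 0 <= start < end <= len(tracks[chrom]):
                raise ParseError(path, lineno, f"interval [{start},{end}) out of bounds")
            tracks[chrom][start:end] = value
    return tracks


# ---------------------------------------------------------------------------
# .pairs — 4DN flavour; positions are 1-based on disk

PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


def write_pairs(
    pairs: pd.DataFrame, path: str | os.PathLike, lengths: Mapping[str, int] | None = None
) -> None:
    """Write a .pairs file.  Input positions are internal 0-based."""
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chr1 pos1 chr2 pos2 strand1 strand2\n")
        if lengths:
            for chrom, n in lengths.items():
                fh.write(f"#chromsize: {chrom} {n}\n")
        for i, row in enumerate(
            pairs[["chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]].itertuples(
                index=False
            )
        ):
            fh.write(
                f"pair{i}\t{row.chrom1}\t{row.pos1 + 1}\t{row.chrom2}\t{row.pos2 + 1}"
                f"\t{row.strand1}\t{row.strand2}\n"
            )


def read_pairs(
    path: str | os.PathLike, genome: CompartmentalizedGenome | None = None
) -> pd.DataFrame:
    """Read a .pairs file into a 0-based table (chrom1,pos1,chrom2,pos2,strand1,strand2)."""
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(path, lineno, "pairs record needs 7 columns")
            try:
                pos1, pos2 = int(fields[2]), int(fields[4])
            except ValueError:
                raise ParseError(path, lineno, "non-integer pair positions") from None
            if pos1 < 1 or pos2 < 1:
                raise ParseError(path, lineno, "pair positions must be >= 1")
            if genome is not None:
                for chrom, pos in ((fields[1], pos1), (fields[3], pos2)):
                    if chrom not in genome.sequences:
                        raise ParseError(path, lineno, f"unknown chromosome {chrom}")
                    if pos > genome.chrom_length(chrom):
                        raise ParseError(
                            path, lineno, f"position {pos} beyond chromosome {chrom}"
                        )
            rows.append(
                (fields[1], pos1 - 1, fields[3], pos2 - 1, fields[5], fields[6])
            )
    return pd.DataFrame(
        rows, columns=["chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
    )


# ---------------------------------------------------------------------------
# compartment table

def write_compartments(genome: CompartmentalizedGenome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tcompartment\tcopy_number\n")
        for chrom in genome.sequences:
            fh.write(
                f"{chrom}\t{genome.compartment[chrom]}\t{genome.copy_number[chrom]:g}\n"
            )


def read_compartments(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "compartment", "copy_number"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: compartment table must have columns {sorted(required)}")
    return df


def load_genome(
    fasta: str | os.PathLike,
    compartments: str | os.PathLike,
    gff3: str | os.PathLike | None = None,
    telomere_bed: str | os.PathLike | None = None,
) -> CompartmentalizedGenome:
    """Assemble a :class:`CompartmentalizedGenome` from its on-disk parts."""
    sequences = read_fasta(fasta)
    comp_df = read_compartments(compartments)
    compartment = dict(zip(comp_df["chrom"], comp_df["compartment"]))
    copy_number = dict(zip(comp_df["chrom"], comp_df["copy_number"].astype(float)))
    genes = read_gff3(gff3) if gff3 else []
    telomeres: list[tuple[str, int, int]] = []
    if telomere_bed:
        tel = read_bed(telomere_bed)
        telomeres = [
            (str(c), int(s), int(e))
            for c, s, e in tel[["chrom", "start", "end"]].itertuples(index=False)
        ]
    return CompartmentalizedGenome(
        sequences=sequences,
        compartment=compartment,
        copy_number=copy_number,
        genes=genes,
        telomeres=telomeres,
    )
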