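"""Unique-mappability tracks from exact k-mer multiplicity.

The genome is tiled with L-mers at every valid start position; a tile is
uniquely mapping iff its sequence occurs exactly once genome-wide, counting
both strands.  The per-position score is

    M(i) = (# unique tiles covering i) / (# tiles covering i)

which equals R/L in chromosome interiors and keeps fully unique genomes at
M = 1 right up to chromosome ends (the denominator shrinks with the number
of valid tile placements).  Uniqueness here is exact-match (stricter than a
mismatch-tolerant aligner).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import CompartmentalizedGenome

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class MappabilityTrack:
    """Per-position mappability scores in [0, 1] for a fixed read length."""

    read_length: int
    scores: dict[str, np.ndarray]

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        arr = self.scores[chrom]
        if not 0 <= start < end <= len(arr):
            raise ValueError(f"region [{start},{end}) outside {chrom}")
        return float(arr[start:end].mean())


def compute_mappability(
    genome: CompartmentalizedGenome | Mapping[str, str], read_length: int
) -> MappabilityTrack:
    """Tile every chromosome with ``read_length``-mers and score uniqueness."""
    sequences = genome.sequences if isinstance(genome, CompartmentalizedGenome) else dict(genome)
    if not sequences:
        raise ValueError("empty genome")
    if read_length < 1:
        raise ValueError("read length must be >= 1")
    too_short = [c for c, s in sequences.items() if len(s) < read_length]
    if too_short:
        raise ValueError(
            f"read length {read_length} exceeds chromosome length for: "
            + ", ".join(too_short)
        )

    counts: Counter[str] = Counter()
    for seq in sequences.values():
        for i in range(len(seq) - read_length + 1):
            counts[_canonical(seq[i : i + read_length])] += 1

    scores: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        n = len(seq)
        n_tiles = n - read_length + 1
        unique = np.fromiter(
            (counts[_canonical(seq[i : i + read_length])] == 1 for i in range(n_tiles)),
            dtype=np.float64,
            count=n_tiles,
        )
        # (# unique tiles covering i) via a cumulative sum over tile starts
        csum = np.concatenate(([0.0], np.cumsum(unique)))
        pos = np.arange(n)
        lo = np.maximum(pos - read_length + 1, 0)
        hi = np.minimum(pos, n_tiles - 1)
        numer = csum[hi + 1] - csum[lo]
        denom = (hi - lo + 1).astype(np.float64)
        scores[chrom] = numer / denom
    return MappabilityTrack(read_length=read_length, scores=scores)


def uniform_track(lengths: Mapping[str, int], read_length: int = 0) -> MappabilityTrack:
    """An all-ones track (useful when no mappability correction is wanted)."""
    return MappabilityTrack(
        read_length=read_length, scores={c: np.ones(n) for c, n in lengths.items()}
    )


class UnquantifiableRegion(ValueError):
    """Mean mappability of the region is zero; RPKM correction is undefined."""


def mappability_correct_rpkm(
    rpkm: float, region: tuple[str, int, int], track: MappabilityTrack
) -> float:
    """Multiply RPKM by the reciprocal of the region's mean mappability."""
    chrom, start, end = region
    mean = track.mean_over(chrom, start, end)
    if mean == 0:
        raise UnquantifiableRegion(
            f"region {chrom}:[{start},{end}) has zero mean mappability"
        )
    return rpkm / mean
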