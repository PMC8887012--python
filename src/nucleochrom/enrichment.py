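"""Compartment-resolved coverage statistics and treatment/input enrichment.

Fragments are assigned to regions by their midpoint (single assignment, so
total weight is conserved by every partition).  RPKM values are corrected by
the reciprocal of the region's mean mappability; enrichment is the ratio of
corrected treatment RPKM to corrected input RPKM, computed on pooled weights
per group (not averaged over per-chromosome ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CompartmentalizedGenome,
    fragment_midpoints,
    total_weight,
    validate_fragments,
)
from .mappability import MappabilityTrack

GROUPINGS = ("compartment", "chromosome", "region-class")


@dataclass(frozen=True)
class Region:
    """A named collection of intervals treated as one quantification unit."""

    name: str
    intervals: tuple[tuple[str, int, int], ...]

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def assign_multimapper_weights(
    placements: Mapping[str, Sequence[tuple[str, int, int]]]
) -> pd.DataFrame:
    """Uniform 1/k weight split across the k candidate placements of each fragment.

    ``placements`` maps fragment id -> list of (chrom, start, end).  Total
    weight per fragment is exactly 1.
    """
    chroms, starts, ends, weights, ids = [], [], [], [], []
    for frag_id, sites in placements.items():
        if len(sites) == 0:
            raise ValueError(f"fragment {frag_id} has no placements")
        w = 1.0 / len(sites)
        for chrom, start, end in sites:
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            weights.append(w)
            ids.append(frag_id)
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "weight": weights, "fragment_id": ids}
    )
    validate_fragments(df)
    return df


def weight_in_region(fragments: pd.DataFrame, region: Region) -> float:
    """Summed fragment weight whose midpoints fall inside the region."""
    mids = fragment_midpoints(fragments)
    chroms = fragments["chrom"].to_numpy()
    w = fragments["weight"].to_numpy()
    mask = np.zeros(len(fragments), dtype=bool)
    for chrom, start, end in region.intervals:
        mask |= (chroms == chrom) & (mids >= start) & (mids < end)
    return float(w[mask].sum())


def _region_mean_mappability(region: Region, track: MappabilityTrack) -> float:
    total = 0.0
    n = 0
    for chrom, start, end in region.intervals:
        arr = track.scores[chrom]
        total += float(arr[start:end].sum())
        n += end - start
    return total / n if n else 0.0


def compute_rpkm(
    fragments: pd.DataFrame,
    regions: Iterable[Region],
    track: MappabilityTrack | None = None,
    library_size: float | None = None,
) -> pd.DataFrame:
    """Mappability-corrected RPKM per region.

    RPKM = weight_in_region / (region_kbp * library_size / 1e6), then divided
    by the region's mean mappability.  Regions with zero mean mappability get
    ``NaN`` and a warning (unquantifiable).
    """
    if library_size is None:
        library_size = total_weight(fragments)
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    rows = []
    for region in regions:
        if region.length == 0:
            raise ValueError(f"region {region.name} has zero length")
        weight = weight_in_region(fragments, region)
        rpkm = weight / (region.length / 1e3 * library_size / 1e6)
        if track is None:
            mean_map = 1.0
        else:
            mean_map = _region_mean_mappability(region, track)
        if mean_map == 0:
            warnings.warn(
                f"region {region.name} has zero mean mappability; RPKM undefined",
                stacklevel=2,
            )
            corrected = np.nan
        else:
            corrected = rpkm / mean_map
        rows.append(
            {
                "region": region.name,
                "length_bp": region.length,
                "weight": weight,
                "rpkm": rpkm,
                "mean_mappability": mean_map,
                "corrected_rpkm": corrected,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def compartment_read_fractions(
    fragments: pd.DataFrame, genome: CompartmentalizedGenome
) -> dict[str, float]:
    """Fraction of total fragment weight mapped to each compartment (sums to 1)."""
    total = total_weight(fragments)
    if total <= 0:
        raise ValueError("empty fragment set")
    fractions = {c: 0.0 for c in set(genome.compartment.values())}
    for chrom, sub in fragments.groupby("chrom", sort=False):
        fractions[genome.compartment[str(chrom)]] += float(sub["weight"].sum())
    return {c: w / total for c, w in fractions.items()}


def grouping_regions(
    genome: CompartmentalizedGenome, group_by: str
) -> list[Region]:
    """Build quantification regions for a grouping mode.

    ``compartment``: whole chromosomes pooled per compartment.
    ``chromosome``: each chromosome alone.
    ``region-class``: rDNA gene territory vs everything else, within the
    compartments that have rDNA annotations.
    """
    if group_by == "chromosome":
        return [
            Region(c, ((c, 0, genome.chrom_length(c)),)) for c in genome.chroms
        ]
    if group_by == "compartment":
        out = []
        for comp in sorted(set(genome.compartment.values())):
            intervals = tuple(
                (c, 0, genome.chrom_length(c)) for c in genome.chroms_of(comp)
            )
            out.append(Region(comp, intervals))
        return out
    if group_by == "region-class":
        rdna = [g for g in genome.genes if g.is_rdna]
        if not rdna:
            raise ValueError("genome has no rDNA annotations for region-class grouping")
        rdna_chroms = sorted({g.chrom for g in rdna})
        rdna_iv = tuple((g.chrom, g.start, g.end) for g in rdna)
        rest = []
        for chrom in rdna_chroms:
            boundaries = sorted(
                [(g.start, g.end) for g in rdna if g.chrom == chrom]
            )
            cursor = 0
            for s, e in boundaries:
                if s > cursor:
                    rest.append((chrom, cursor, s))
                cursor = max(cursor, e)
            if cursor < genome.chrom_length(chrom):
                rest.append((chrom, cursor, genome.chrom_length(chrom)))
        return [Region("rdna", rdna_iv), Region("non_rdna", tuple(rest))]
    raise ValueError(f"unknown grouping {group_by!r}; expected one of {GROUPINGS}")


def estimate_copy_numbers(
    input_fragments: pd.DataFrame,
    genome: CompartmentalizedGenome,
    track: MappabilityTrack | None = None,
) -> dict[str, float]:
    """Relative copy number per chromosome from an input (DNA-mass) library.

    Corrected RPKM per chromosome, divided by the median corrected RPKM of
    nuclear chromosomes (so the nucleus sits at 1).
    """
    regions = grouping_regions(genome, "chromosome")
    table = compute_rpkm(input_fragments, regions, track)
    nuclear = [c for c in genome.chroms if genome.compartment[c] == "nucleus"]
    if not nuclear:
        raise ValueError("no nuclear chromosomes to define the copy-number baseline")
    baseline = float(np.nanmedian(table.loc[nuclear, "corrected_rpkm"]))
    if baseline <= 0 or np.isnan(baseline):
        raise ValueError("nuclear baseline RPKM is zero")
    return {
        c: float(table.loc[c, "corrected_rpkm"] / baseline) for c in genome.chroms
    }


def compute_enrichment(
    treatment: pd.DataFrame,
    input_fragments: pd.DataFrame,
    genome: CompartmentalizedGenome,
    track: MappabilityTrack | None = None,
    group_by: str = "compartment",
) -> pd.DataFrame:
    """Treatment vs input enrichment table for the requested grouping.

    Both libraries are normalised identically (RPKM with the same mappability
    correction); enrichment is their ratio.  Groups with zero input weight
    are reported with ``NaN`` enrichment and a warning.
    """
    if len(treatment) == 0 or len(input_fragments) == 0:
        raise ValueError("both treatment and input libraries must be non-empty")
    regions = grouping_regions(genome, group_by)
    t = compute_rpkm(treatment, regions, track)
    i = compute_rpkm(input_fragments, regions, track)
    table = pd.DataFrame(
        {
            "treatment_rpkm": t["corrected_rpkm"],
            "input_rpkm": i["corrected_rpkm"],
        }
    )
    zero_input = table["input_rpkm"] <= 0
    if zero_input.any():
        warnings.warn(
            "groups with zero input weight: "
            + ", ".join(table.index[zero_input]),
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["enrichment"] = np.where(
            table["input_rpkm"] > 0,
            table["treatment_rpkm"] / table["input_rpkm"],
            np.nan,
        )
    return table
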