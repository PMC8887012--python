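"""TSS-anchored profiles, gene-level signal, a Poisson peak-caller stand-in,
and peak-to-TSS distance distributions.

Anchors are ``(chrom, position, strand)`` triples; profiles are strand
oriented so that positive offsets point in the direction of transcription.
Coverage counts full fragment spans by default; a cut-site mode (fragment
ends only) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CompartmentalizedGenome, Gene, fragment_midpoints, total_weight

Anchor = tuple[str, int, str]


def gene_anchors(genes: list[Gene]) -> list[Anchor]:
    return [(g.chrom, g.tss, g.strand) for g in genes]


def coverage_tracks(
    fragments: pd.DataFrame,
    lengths: dict[str, int],
    cut_sites: bool = False,
) -> dict[str, np.ndarray]:
    """Weighted per-base coverage (or cut-site counts) per chromosome."""
    tracks = {c: np.zeros(n + 1) for c, n in lengths.items()}
    for chrom, sub in fragments.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in tracks:
            continue
        arr = tracks[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        w = sub["weight"].to_numpy()
        if cut_sites:
            np.add.at(arr, starts, w)
            np.add.at(arr, np.minimum(ends - 1, len(arr) - 2), w)
        else:
            np.add.at(arr, starts, w)
            np.add.at(arr, ends, -w)
    out = {}
    for chrom, arr in tracks.items():
        if cut_sites:
            out[chrom] = arr[:-1]
        else:
            out[chrom] = np.cumsum(arr)[:-1]
    return out


@dataclass
class ProfileMatrix:
    """Anchor-by-offset coverage matrix plus its column-mean metaplot."""

    anchors: list[Anchor]
    window: int
    bin_size: int
    matrix: np.ndarray  # anchors x n_bins

    @property
    def offsets(self) -> np.ndarray:
        """Bin-centre offsets relative to the anchor, strand-oriented."""
        n_bins = self.matrix.shape[1]
        starts = -self.window + np.arange(n_bins) * self.bin_size
        return starts + (self.bin_size - 1) / 2.0

    @property
    def metaplot(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def tss_profile(
    fragments: pd.DataFrame,
    anchors: list[Anchor],
    window: int,
    bin_size: int = 1,
    lengths: dict[str, int] | None = None,
    cut_sites: bool = False,
) -> ProfileMatrix:
    """Strand-oriented coverage profile around each anchor.

    Positions outside the chromosome contribute zero.  ``window`` must be a
    multiple of ``bin_size``; the profile spans offsets -window..window.
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin size")
    if not anchors:
        raise ValueError("no anchors")
    if lengths is None:
        lengths = {}
        for chrom, sub in fragments.groupby("chrom", sort=False):
            lengths[str(chrom)] = int(sub["end"].max())
        for chrom, pos, _ in anchors:
            lengths[chrom] = max(lengths.get(chrom, 0), pos + window + 1)
    cov = coverage_tracks(fragments, lengths, cut_sites=cut_sites)
    span = 2 * window + 1
    matrix = np.zeros((len(anchors), span))
    for i, (chrom, pos, strand) in enumerate(anchors):
        arr = cov.get(chrom)
        if arr is None:
            continue
        lo, hi = pos - window, pos + window + 1
        src_lo, src_hi = max(lo, 0), min(hi, len(arr))
        row = np.zeros(span)
        row[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        if strand == "-":
            row = row[::-1]
        matrix[i] = row
    if bin_size > 1:
        n_bins = span // bin_size
        matrix = matrix[:, : n_bins * bin_size].reshape(
            len(anchors), n_bins, bin_size
        ).mean(axis=2)
    return ProfileMatrix(anchors=list(anchors), window=window, bin_size=bin_size, matrix=matrix)


def quantify_gene_signal(
    fragments: pd.DataFrame,
    genes: list[Gene],
    genome: CompartmentalizedGenome,
    mode: str = "promoter",
    promoter_halfwidth: int = 250,
    track=None,
    library_size: float | None = None,
) -> pd.Series:
    """Per-gene corrected RPKM over promoters (TSS +/- halfwidth) or gene bodies."""
    from .enrichment import Region, compute_rpkm

    if mode not in ("promoter", "gene_body"):
        raise ValueError("mode must be 'promoter' or 'gene_body'")
    regions = []
    for g in genes:
        if mode == "promoter":
            lo = max(g.tss - promoter_halfwidth, 0)
            hi = min(g.tss + promoter_halfwidth + 1, genome.chrom_length(g.chrom))
        else:
            lo, hi = g.start, g.end
        regions.append(Region(g.gene_id, ((g.chrom, lo, hi),)))
    table = compute_rpkm(fragments, regions, track=track, library_size=library_size)
    return table["corrected_rpkm"]


def rank_correlation(x, y) -> float:
    """Spearman rho with midrank ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the peak interval")


def call_peaks_simple(
    fragments: pd.DataFrame,
    genome: CompartmentalizedGenome,
    window: int = 200,
    step: int | None = None,
    local_bg_span: int = 5000,
    p_threshold: float = 1e-5,
    return_window_stats: bool = False,
) -> list[Peak] | tuple[list[Peak], int, int]:
    """Sliding-window Poisson peak caller.

    Window counts (fragment midpoints) are tested against
    ``Poisson(lambda_local)`` with ``lambda_local`` the larger of the
    genome-wide rate and the rate in +/- local_bg_span around the window.
    Overlapping significant windows are merged; the summit is the
    maximum-coverage base of the merged interval.
    """
    if window < 50:
        raise ValueError("window must be >= 50 bp")
    if step is None:
        step = max(window // 2, 1)
    if len(fragments) == 0:
        warnings.warn("empty fragment library; no peaks called", stacklevel=2)
        return ([], 0, 0) if return_window_stats else []
    lengths = genome.lengths
    genome_bp = sum(lengths.values())
    lib = total_weight(fragments)
    genome_rate = lib / genome_bp  # weight per bp

    mids = fragment_midpoints(fragments)
    chrom_arr = fragments["chrom"].to_numpy()
    w = fragments["weight"].to_numpy()

    peaks: list[Peak] = []
    n_windows = n_significant = 0
    for chrom, n in lengths.items():
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        mid_w = np.zeros(n)
        np.add.at(mid_w, np.clip(mids[sel], 0, n - 1), w[sel])
        cum = np.concatenate(([0.0], np.cumsum(mid_w)))

        starts = np.arange(0, max(n - window, 0) + 1, step)
        if len(starts) == 0:
            starts = np.array([0])
        ends = np.minimum(starts + window, n)
        counts = cum[ends] - cum[starts]

        bg_lo = np.maximum(starts - local_bg_span, 0)
        bg_hi = np.minimum(ends + local_bg_span, n)
        bg_rate = (cum[bg_hi] - cum[bg_lo]) / (bg_hi - bg_lo)
        lam = np.maximum(genome_rate, bg_rate) * (ends - starts)
        pvals = stats.poisson.sf(np.ceil(counts) - 1, lam)
        sig = np.flatnonzero((pvals < p_threshold) & (counts > 0))
        n_windows += len(starts)
        n_significant += len(sig)
        if len(sig) == 0:
            continue

        # merge overlapping significant windows
        merged: list[list] = []
        for i in sig:
            s, e, p, c = int(starts[i]), int(ends[i]), float(pvals[i]), float(counts[i])
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = min(merged[-1][2], p)
                merged[-1][3] = max(merged[-1][3], c)
            else:
                merged.append([s, e, p, c])
        cov = coverage_tracks(fragments[sel], {chrom: n})[chrom]
        for s, e, p, c in merged:
            summit = s + int(np.argmax(cov[s:e]))
            fold = c / (genome_rate * window) if genome_rate > 0 else np.inf
            peaks.append(Peak(chrom, s, e, summit, fold, p))
    if return_window_stats:
        return peaks, n_windows, n_significant
    return peaks


def random_control_peaks(
    genome: CompartmentalizedGenome, bin_size: int = 500
) -> dict[str, np.ndarray]:
    """Bin-boundary positions 0, bin, 2*bin, ... plus the chromosome end."""
    if bin_size <= 0:
        raise ValueError("bin size must be > 0")
    out = {}
    for chrom, n in genome.lengths.items():
        positions = list(range(0, n + 1, bin_size))
        if positions[-1] != n:
            positions.append(n)
        out[chrom] = np.array(positions, dtype=np.int64)
    return out


def peak_tss_distances(
    peak_positions: dict[str, np.ndarray] | list[Peak],
    anchors: list[Anchor],
    max_range: int = 2000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Signed strand-oriented distance from each peak summit to its nearest TSS.

    Distances beyond +/- max_range are pooled into the edge bins.  Nearest-
    anchor ties break toward the upstream anchor (negative offset).
    """
    if isinstance(peak_positions, list):
        by_chrom: dict[str, list[int]] = {}
        for p in peak_positions:
            by_chrom.setdefault(p.chrom, []).append(p.summit)
        peak_positions = {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}

    anchor_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, strand in anchors:
        anchor_by_chrom.setdefault(chrom, []).append((pos, strand))

    distances: list[int] = []
    for chrom, positions in peak_positions.items():
        alist = anchor_by_chrom.get(chrom)
        if not alist:
            continue
        apos = np.array([p for p, _ in alist])
        signs = np.array([1 if s == "+" else -1 for _, s in alist])
        order = np.argsort(apos)
        apos, signs = apos[order], signs[order]
        for summit in positions:
            diffs = np.abs(apos - summit)
            best = int(np.min(diffs))
            cands = np.flatnonzero(diffs == best)
            # tie -> choose the anchor for which the peak lies upstream
            chosen = None
            for ci in cands:
                if (summit - apos[ci]) * signs[ci] <= 0:
                    chosen = ci
                    break
            if chosen is None:
                chosen = cands[0]
            distances.append(int((summit - apos[chosen]) * signs[chosen]))

    edges = np.arange(-max_range, max_range + bin_size, bin_size)
    clipped = np.clip(distances, -max_range, max_range - 1) if distances else []
    hist, _ = np.histogram(clipped, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": hist}
    )
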