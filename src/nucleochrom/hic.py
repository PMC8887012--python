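"""Hi-C contact matrices: binning, balancing (NONE / VC / VC_SQRT / KR),
distance decay, per-chromosome trans profiles and telomere-network scores.

Matrices are dense symmetric numpy arrays over a genome-wide bin table —
fine at desk scale (a few hundred bins).  KR balancing finds a positive
vector ``x`` with ``x_i (C x)_i = 1`` over unmasked bins via the inner-outer
Newton/conjugate-gradient iteration; VC divides by row-sum products and
rescales to preserve the total sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CompartmentalizedGenome

NORMALIZATIONS = ("NONE", "VC", "VC_SQRT", "KR")


class BalancingError(RuntimeError):
    pass


@dataclass
class ContactMatrix:
    resolution: int
    bins: pd.DataFrame  # columns: chrom, start
    matrix: np.ndarray  # dense, symmetric
    normalization: str = "NONE"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match the bin table")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        if len(idx) == 0:
            raise KeyError(f"chromosome {chrom} not in bin table")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def total_pairs(self) -> float:
        """Sum over the upper triangle including the diagonal."""
        return float(np.triu(self.matrix).sum())

    def bin_mask(self, chrom: str, intervals: list[tuple[int, int]]) -> np.ndarray:
        """Boolean mask (within the chromosome slice) of bins overlapping intervals."""
        sl = self.chrom_slice(chrom)
        starts = self.bins["start"].to_numpy()[sl]
        ends = starts + self.resolution
        mask = np.zeros(len(starts), dtype=bool)
        for lo, hi in intervals:
            mask |= (starts < hi) & (ends > lo)
        return mask


def make_bin_table(
    lengths: dict[str, int], resolution: int
) -> pd.DataFrame:
    rows = []
    for chrom, n in lengths.items():
        for start in range(0, n, resolution):
            rows.append((chrom, start))
    return pd.DataFrame(rows, columns=["chrom", "start"])


def bin_contacts(
    pairs: pd.DataFrame, genome: CompartmentalizedGenome, resolution: int
) -> ContactMatrix:
    """Accumulate pairs into a symmetric binned matrix (one count per pair)."""
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    lengths = genome.lengths
    bins = make_bin_table(lengths, resolution)
    offsets: dict[str, int] = {}
    cursor = 0
    for chrom, n in lengths.items():
        offsets[chrom] = cursor
        cursor += math.ceil(n / resolution)
    matrix = np.zeros((cursor, cursor))
    b1 = (
        pairs["chrom1"].map(offsets).to_numpy()
        + pairs["pos1"].to_numpy() // resolution
    )
    b2 = (
        pairs["chrom2"].map(offsets).to_numpy()
        + pairs["pos2"].to_numpy() // resolution
    )
    np.add.at(matrix, (b1, b2), 1.0)
    matrix = matrix + matrix.T - np.diag(np.diag(matrix))
    return ContactMatrix(resolution=resolution, bins=bins, matrix=matrix)


# ---------------------------------------------------------------------------
# balancing

def _kr_vector(A: np.ndarray, tol: float = 1e-8, max_outer: int = 100) -> np.ndarray:
    """Knight-Ruiz scaling vector x with x * (A @ x) = 1 (inner-outer Newton/CG)."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = float(rk @ rk)
    rout = rold = rho_km1
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise BalancingError(
                "KR balancing did not converge; try masking sparse bins"
            )
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = float(p @ w)
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = ((big_delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            if k > 10 * n:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        rat = rout / rold
        rold = rout
        eta = max(min(g * rat, etamax), 0.5 * tol / max(math.sqrt(rout), tol))
    return x


def balance(
    matrix: ContactMatrix,
    method: str = "KR",
    mask_min_contacts: float = 5.0,
    tol: float = 1e-8,
) -> ContactMatrix:
    """Return a balanced copy of the matrix.

    Bins with zero coverage are always masked; KR additionally masks bins
    with fewer than ``mask_min_contacts`` raw contacts.  Masked rows/columns
    are zeroed in the output and their weights are NaN.
    """
    method = method.upper()
    if method not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {method!r}")
    C = matrix.matrix.astype(float)
    row = C.sum(axis=1)
    keep = row > 0
    if method == "KR":
        keep &= row >= mask_min_contacts
    if not keep.any():
        raise BalancingError("all bins masked; nothing to balance")

    if method == "NONE":
        return replace(
            matrix,
            matrix=C.copy(),
            normalization="NONE",
            weights=np.where(keep, 1.0, np.nan),
        )

    out = np.zeros_like(C)
    weights = np.full(matrix.n_bins, np.nan)
    sub = C[np.ix_(keep, keep)]
    total = sub.sum()

    if method in ("VC", "VC_SQRT"):
        r = sub.sum(axis=1)
        denom = np.outer(r, r)
        if method == "VC_SQRT":
            denom = np.sqrt(denom)
        scaled = sub / denom
        scale = total / scaled.sum() if scaled.sum() > 0 else 1.0
        out[np.ix_(keep, keep)] = scaled * scale
        w = 1.0 / r if method == "VC" else 1.0 / np.sqrt(r)
        weights[keep] = w * math.sqrt(scale)
        return replace(matrix, matrix=out, normalization=method, weights=weights)

    # KR: drop rows that lose all support inside the kept set
    while True:
        inner_row = sub.sum(axis=1)
        alive = inner_row > 0
        if alive.all():
            break
        keep[np.flatnonzero(keep)[~alive]] = False
        if not keep.any():
            raise BalancingError("all bins masked; nothing to balance")
        sub = C[np.ix_(keep, keep)]
    x = _kr_vector(sub, tol=tol)
    out[np.ix_(keep, keep)] = sub * np.outer(x, x)
    weights[keep] = x
    return replace(matrix, matrix=out, normalization="KR", weights=weights)


# ---------------------------------------------------------------------------
# summaries

def distance_decay(
    matrix: ContactMatrix, chrom: str, log_bins: bool = False
) -> pd.DataFrame:
    """Mean contact at each bin separation within one chromosome."""
    sl = matrix.chrom_slice(chrom)
    sub = matrix.matrix[sl, sl]
    n = sub.shape[0]
    seps = np.arange(n)
    means = np.array([np.mean(np.diag(sub, k=int(s))) for s in seps])
    table = pd.DataFrame(
        {"separation_bp": seps * matrix.resolution, "mean_contact": means}
    )
    if log_bins:
        table = table[table["separation_bp"] > 0].copy()
        edges = np.geomspace(
            matrix.resolution, table["separation_bp"].max() + 1, num=20
        )
        table["log_bin"] = np.digitize(table["separation_bp"], edges)
        table = (
            table.groupby("log_bin")
            .agg(separation_bp=("separation_bp", "mean"), mean_contact=("mean_contact", "mean"))
            .reset_index(drop=True)
        )
    return table


def decay_exponent(
    matrix: ContactMatrix, chrom: str, max_fraction: float = 0.25
) -> float:
    """Fitted log-log slope of P(s), sign-flipped (so exponent 1 means s^-1).

    The fit uses separations up to ``max_fraction`` of the chromosome length,
    where counts are dense enough for a stable regression.
    """
    table = distance_decay(matrix, chrom)
    sl = matrix.chrom_slice(chrom)
    span = (sl.stop - sl.start) * matrix.resolution
    table = table[
        (table["separation_bp"] > 0)
        & (table["separation_bp"] <= span * max_fraction)
        & (table["mean_contact"] > 0)
    ]
    slope, _ = np.polyfit(
        np.log(table["separation_bp"]), np.log(table["mean_contact"]), 1
    )
    return float(-slope)


def trans_profile(matrix: ContactMatrix, source_chrom: str) -> pd.Series:
    """Per-target normalized trans contact frequency:
    sum(contacts source x target) / (n_source_bins * n_target_bins)."""
    src = matrix.chrom_slice(source_chrom)
    n_src = src.stop - src.start
    out = {}
    for chrom in matrix.bins["chrom"].unique():
        if chrom == source_chrom:
            continue
        tgt = matrix.chrom_slice(chrom)
        n_tgt = tgt.stop - tgt.start
        out[chrom] = float(matrix.matrix[src, tgt].sum()) / (n_src * n_tgt)
    return pd.Series(out, name=f"trans_from_{source_chrom}")


@dataclass
class TelomereNetworkResult:
    ratio: float
    per_pair: pd.DataFrame
    cis_end_fold: dict[str, float] = field(default_factory=dict)


def default_telomere_intervals(
    genome: CompartmentalizedGenome, width: int = 10_000, compartment: str = "nucleomorph"
) -> list[tuple[str, int, int]]:
    """Outermost ``width`` bp of each chromosome of a compartment."""
    out = []
    for chrom in genome.chroms_of(compartment):
        n = genome.chrom_length(chrom)
        w = min(width, n // 2)
        out.append((chrom, 0, w))
        out.append((chrom, n - w, n))
    return out


def telomere_network_score(
    matrix: ContactMatrix, telomeres: list[tuple[str, int, int]]
) -> TelomereNetworkResult:
    """Observed/expected ratio of trans contacts with both bins telomeric.

    Expected = per-chromosome-pair trans total x the telomeric bin-pair
    fraction; pairs are restricted to chromosomes carrying telomere
    annotations.  Also reports, per chromosome, the cis end-to-end contact
    fold relative to the chromosome's distance-decay expectation.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, lo, hi in telomeres:
        by_chrom.setdefault(chrom, []).append((lo, hi))
    chroms = sorted(by_chrom)
    if len(chroms) < 2:
        raise ValueError("need telomere annotations on at least two chromosomes")

    rows = []
    obs_total = exp_total = 0.0
    for i, a in enumerate(chroms):
        sl_a = matrix.chrom_slice(a)
        tel_a = matrix.bin_mask(a, by_chrom[a])
        for b in chroms[i + 1 :]:
            sl_b = matrix.chrom_slice(b)
            tel_b = matrix.bin_mask(b, by_chrom[b])
            block = matrix.matrix[sl_a, sl_b]
            total = float(block.sum())
            obs = float(block[np.ix_(tel_a, tel_b)].sum())
            frac = (tel_a.sum() * tel_b.sum()) / (len(tel_a) * len(tel_b))
            exp = total * frac
            rows.append(
                {
                    "chrom1": a,
                    "chrom2": b,
                    "observed": obs,
                    "expected": exp,
                    "ratio": obs / exp if exp > 0 else np.nan,
                }
            )
            obs_total += obs
            exp_total += exp
    ratio = obs_total / exp_total if exp_total > 0 else np.nan

    cis_fold: dict[str, float] = {}
    for chrom in chroms:
        wins = sorted(by_chrom[chrom])
        if len(wins) < 2:
            continue
        sl = matrix.chrom_slice(chrom)
        sub = matrix.matrix[sl, sl]
        first = np.flatnonzero(matrix.bin_mask(chrom, [wins[0]]))
        last = np.flatnonzero(matrix.bin_mask(chrom, [wins[-1]]))
        decay = distance_decay(matrix, chrom)["mean_contact"].to_numpy()
        obs = exp = 0.0
        for i in first:
            for j in last:
                obs += sub[i, j]
                exp += decay[abs(j - i)]
        cis_fold[chrom] = obs / exp if exp > 0 else np.nan
    return TelomereNetworkResult(
        ratio=ratio, per_pair=pd.DataFrame(rows), cis_end_fold=cis_fold
    )


# ---------------------------------------------------------------------------
# text export

def matrix_to_tsv(matrix: ContactMatrix, path) -> None:
    labels = [
        f"{c}:{s}" for c, s in matrix.bins[["chrom", "start"]].itertuples(index=False)
    ]
    df = pd.DataFrame(matrix.matrix, index=labels, columns=labels)
    df.index.name = f"bin[{matrix.normalization}@{matrix.resolution}]"
    df.to_csv(path, sep="\t")


def weights_to_tsv(matrix: ContactMatrix, path) -> None:
    df = matrix.bins.copy()
    df["weight"] = matrix.weights if matrix.weights is not None else 1.0
    df.to_csv(path, sep="\t", index=False)
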