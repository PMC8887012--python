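"""Synthetic four-compartment genome and library generator.

Emulates the statistical structure of a chlorarachniophyte-like cell:
a haploid multi-chromosome nucleus, a diploid AT-rich "nucleomorph" of a
few hundred kbp in three chromosomes with subtelomeric rDNA arrays, and
high-copy organelles.  Generates aligned fragment coordinates directly
(ATAC-like accessibility libraries, KAS-like transcription libraries,
uniform input) plus Hi-C contact pairs, with every generative parameter
recorded in a ground-truth JSON so downstream analyses can be validated
by parameter recovery.

All sampling is driven by per-library RNG streams derived from the config
seed, so outputs are byte-reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    COMPARTMENTS,
    CompartmentalizedGenome,
    ConfigurationError,
    Gene,
    make_fragments,
)
from . import io as nio

# RNG stream ids, one per output artefact
_STREAMS = {"genome": 0, "dyads": 1, "atac": 2, "kas": 3, "input": 4, "hic": 5}

NUCLEOSOME_FOOTPRINT = 147


@dataclass(frozen=True)
class ChromPlan:
    name: str
    length: int
    compartment: str
    copy_number: float = 1.0
    at_fraction: float = 0.55


@dataclass(frozen=True)
class LengthComponent:
    """One truncated-normal component of a fragment-length mixture.

    Components with ``nucleosomal=True`` are sampled centred on planted
    nucleosome dyads (when the chromosome has any); the rest start in
    accessible DNA.
    """

    mode: float
    sd: float
    weight: float
    nucleosomal: bool = False


@dataclass
class HiCParams:
    decay_exponent: float = 1.0
    telomere_boost: float = 1.0
    trans_multiplier: dict[tuple[str, str], float] = field(default_factory=dict)
    cis_weight: float = 3.0
    min_separation: int = 1000
    subtelomere_bp: int = 10_000

    def trans_mult(self, comp_a: str, comp_b: str) -> float:
        key = tuple(sorted((comp_a, comp_b)))
        return float(self.trans_multiplier.get(key, 1.0))


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_plan: list[ChromPlan] = field(default_factory=list)
    genes_per_chrom: int = 20
    intergenic_bp: int = 500
    rdna_subtelomere_bp: int = 7000
    rdna_unit_bp: int = 2000
    telomere_bp: int = 500
    accessibility_multiplier: dict[str, float] = field(default_factory=dict)
    transcription_rate: dict[str, float] = field(default_factory=dict)
    default_transcription_rate: float = 1.0
    rdna_transcription_multiplier: float = 20.0
    frag_len_mixture: dict[str, list[LengthComponent]] = field(default_factory=dict)
    kas_frag_len: tuple[float, float] = (150.0, 30.0)
    input_frag_len: tuple[float, float] = (300.0, 50.0)
    min_frag_len: int = 20
    rdna_accessibility_multiplier: float = 2.0
    ndr_width: int = 120
    ndr_boost: float = 5.0
    nucleosome_dip: float = 0.2
    nucleosome_spacing: int = 175
    plus_one_offset: int = 110
    minus_one_offset: int = -130
    positioning_sd: float = 10.0
    hic: HiCParams = field(default_factory=HiCParams)
    depth: dict[str, int] = field(default_factory=lambda: dict(
        atac=100_000, kas=100_000, input=100_000, hic=100_000))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.chrom_plan:
            raise ConfigurationError("chrom_plan is empty")
        names = [p.name for p in self.chrom_plan]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names in chrom_plan")
        for plan in self.chrom_plan:
            if plan.length <= 0:
                raise ConfigurationError(f"{plan.name}: non-positive length")
            if plan.copy_number <= 0:
                raise ConfigurationError(f"{plan.name}: copy_number must be > 0")
            if plan.compartment not in COMPARTMENTS:
                raise ConfigurationError(
                    f"{plan.name}: unknown compartment {plan.compartment!r}"
                )
            if not 0.0 <= plan.at_fraction <= 1.0:
                raise ConfigurationError(f"{plan.name}: AT fraction outside [0,1]")
        for comp, mixture in self.frag_len_mixture.items():
            total = sum(c.weight for c in mixture)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"frag_len_mixture[{comp}]: weights sum to {total}, not 1"
                )
        for value in (self.telomere_bp, self.intergenic_bp, self.ndr_width):
            if value < 0:
                raise ConfigurationError("lengths must be non-negative")
        for comp, mult in self.accessibility_multiplier.items():
            if mult <= 0:
                raise ConfigurationError(f"accessibility_multiplier[{comp}] must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def mixture_for(self, compartment: str) -> list[LengthComponent]:
        if compartment in self.frag_len_mixture:
            return self.frag_len_mixture[compartment]
        return [LengthComponent(mode=150.0, sd=40.0, weight=1.0)]

    def gene_rate(self, gene: Gene) -> float:
        if gene.gene_id in self.transcription_rate:
            return float(self.transcription_rate[gene.gene_id])
        if gene.is_rdna:
            return self.default_transcription_rate * self.rdna_transcription_multiplier
        return self.default_transcription_rate


def default_config(seed: int = 0, depth: int = 100_000) -> SimulationConfig:
    """A desk-scale default plan mimicking the target cell's architecture.

    Four nuclear chromosomes (haploid), three AT-rich nucleomorph
    chromosomes totalling 380 kbp (diploid) with subtelomeric rDNA arrays
    covering ~11% of the nucleomorph, a high-copy mitochondrion and plastid.
    """
    plan = [
        ChromPlan("chr1", 300_000, "nucleus", 1.0, 0.55),
        ChromPlan("chr2", 250_000, "nucleus", 1.0, 0.55),
        ChromPlan("chr3", 200_000, "nucleus", 1.0, 0.55),
        ChromPlan("chr4", 150_000, "nucleus", 1.0, 0.55),
        ChromPlan("NM1", 140_000, "nucleomorph", 2.0, 0.75),
        ChromPlan("NM2", 130_000, "nucleomorph", 2.0, 0.75),
        ChromPlan("NM3", 110_000, "nucleomorph", 2.0, 0.75),
        ChromPlan("chrP", 70_000, "plastid", 20.0, 0.65),
        ChromPlan("chrM", 40_000, "mitochondrion", 50.0, 0.65),
    ]
    mixtures = {
        "nucleus": [
            LengthComponent(100.0, 25.0, 0.6, nucleosomal=False),
            LengthComponent(200.0, 20.0, 0.4, nucleosomal=True),
        ],
        "nucleomorph": [
            LengthComponent(90.0, 20.0, 0.55, nucleosomal=False),
            LengthComponent(220.0, 18.0, 0.45, nucleosomal=True),
        ],
        "mitochondrion": [LengthComponent(120.0, 35.0, 1.0)],
        "plastid": [LengthComponent(120.0, 35.0, 1.0)],
    }
    return SimulationConfig(
        seed=seed,
        chrom_plan=plan,
        accessibility_multiplier={
            "nucleus": 1.0,
            "nucleomorph": 10.0,
            "plastid": 50.0,
            "mitochondrion": 100.0,
        },
        frag_len_mixture=mixtures,
        hic=HiCParams(
            decay_exponent=1.0,
            telomere_boost=5.0,
            trans_multiplier={
                tuple(sorted(("mitochondrion", "nucleomorph"))): 3.0,
                tuple(sorted(("mitochondrion", "plastid"))): 3.0,
            },
        ),
        depth=dict(atac=depth, kas=depth, input=depth, hic=depth),
    )


# ---------------------------------------------------------------------------
# genome

def simulate_genome(config: SimulationConfig) -> CompartmentalizedGenome:
    """Draw sequences and lay out annotations according to the plan.

    Telomeres are placed at both ends of nuclear and nucleomorph
    chromosomes; rDNA units tile the subtelomeric windows of nucleomorph
    chromosomes; regular genes tile the interior with the configured
    intergenic spacing on alternating strands.
    """
    rng = config.rng("genome")
    sequences: dict[str, str] = {}
    compartment: dict[str, str] = {}
    copy_number: dict[str, float] = {}
    genes: list[Gene] = []
    telomeres: list[tuple[str, int, int]] = []
    bases = np.array(["A", "T", "C", "G"])

    for plan in config.chrom_plan:
        at = plan.at_fraction
        probs = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
        seq = "".join(bases[rng.choice(4, size=plan.length, p=probs)])
        sequences[plan.name] = seq
        compartment[plan.name] = plan.compartment
        copy_number[plan.name] = plan.copy_number

        linear = plan.compartment in ("nucleus", "nucleomorph")
        tel = config.telomere_bp if linear else 0
        if tel:
            telomeres.append((plan.name, 0, tel))
            telomeres.append((plan.name, plan.length - tel, plan.length))

        interior_lo, interior_hi = tel, plan.length - tel
        if plan.compartment == "nucleomorph" and config.rdna_subtelomere_bp > 0:
            rdna = config.rdna_subtelomere_bp
            if interior_hi - interior_lo < 2 * rdna:
                raise ConfigurationError(
                    f"{plan.name}: rDNA subtelomeres do not fit in the chromosome"
                )
            genes.extend(
                _tile_rdna(plan.name, interior_lo, interior_lo + rdna, "+", config, "L")
            )
            genes.extend(
                _tile_rdna(plan.name, interior_hi - rdna, interior_hi, "-", config, "R")
            )
            interior_lo += rdna
            interior_hi -= rdna

        genes.extend(
            _tile_genes(plan.name, interior_lo, interior_hi, config)
        )

    return CompartmentalizedGenome(
        sequences=sequences,
        compartment=compartment,
        copy_number=copy_number,
        genes=genes,
        telomeres=telomeres,
    )


def _tile_rdna(
    chrom: str, lo: int, hi: int, strand: str, config: SimulationConfig, tag: str
) -> list[Gene]:
    """Fill [lo, hi) completely with rDNA units (last unit absorbs remainder)."""
    span = hi - lo
    n_units = max(1, span // config.rdna_unit_bp)
    unit = span // n_units
    out = []
    for i in range(n_units):
        start = lo + i * unit
        end = hi if i == n_units - 1 else start + unit
        out.append(Gene(chrom, start, end, strand, f"{chrom}_rdna_{tag}{i}", is_rdna=True))
    return out


def _tile_genes(
    chrom: str, lo: int, hi: int, config: SimulationConfig
) -> list[Gene]:
    n = config.genes_per_chrom
    if n <= 0:
        return []
    gene_len = (hi - lo - (n + 1) * config.intergenic_bp) // n
    if gene_len < 2 * NUCLEOSOME_FOOTPRINT:
        raise ConfigurationError(
            f"{chrom}: {n} genes with {config.intergenic_bp} bp spacing do not fit "
            f"in [{lo},{hi}) (gene length would be {gene_len} bp)"
        )
    out = []
    for i in range(n):
        start = lo + config.intergenic_bp + i * (gene_len + config.intergenic_bp)
        strand = "+" if i % 2 == 0 else "-"
        out.append(Gene(chrom, start, start + gene_len, strand, f"{chrom}_g{i}"))
    return out


def write_genome_files(genome: CompartmentalizedGenome, outdir: str | os.PathLike) -> dict[str, str]:
    """Write genome.fa / genes.gff3 / compartments.tsv / telomeres.bed; return paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "compartments": os.path.join(outdir, "compartments.tsv"),
        "telomeres": os.path.join(outdir, "telomeres.bed"),
    }
    nio.write_fasta(genome.sequences, paths["fasta"])
    nio.write_gff3(genome.genes, paths["gff3"])
    nio.write_compartments(genome, paths["compartments"])
    with open(paths["telomeres"], "w") as fh:
        for chrom, start, end in genome.telomeres:
            fh.write(f"{chrom}\t{start}\t{end}\t1\n")
    return paths


# ---------------------------------------------------------------------------
# planted nucleosomes

def plant_dyads(
    genome: CompartmentalizedGenome, config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Ground-truth dyad positions: a -1 / +1 / +2 array around each TSS.

    Offsets are strand-oriented and each dyad centre is jittered once with
    ``positioning_sd``.  Compartments whose length mixture has no nucleosomal
    component get no dyads.
    """
    rng = config.rng("dyads")
    offsets = [
        config.minus_one_offset,
        config.plus_one_offset,
        config.plus_one_offset + config.nucleosome_spacing,
    ]
    dyads: dict[str, list[int]] = {c: [] for c in genome.chroms}
    for chrom in genome.chroms:
        comp = genome.compartment[chrom]
        if not any(c.nucleosomal for c in config.mixture_for(comp)):
            continue
        length = genome.chrom_length(chrom)
        for gene in genome.genes_on(chrom):
            if gene.is_rdna:  # rDNA arrays stay nucleosome-free
                continue
            sign = 1 if gene.strand == "+" else -1
            for off in offsets:
                pos = gene.tss + sign * off
                pos += int(round(rng.normal(0.0, config.positioning_sd)))
                if 0 <= pos < length:
                    dyads[chrom].append(pos)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in dyads.items()}


def accessibility_profile(
    genome: CompartmentalizedGenome,
    config: SimulationConfig,
    chrom: str,
    dyads: np.ndarray,
) -> np.ndarray:
    """Per-base fragment start rate, normalised so its mean is
    ``copy_number * accessibility_multiplier`` for the chromosome.

    The profile is flat, boosted over the NDR upstream of each TSS, and
    multiplicatively dipped across each planted 147-bp nucleosome footprint.
    """
    length = genome.chrom_length(chrom)
    prof = np.ones(length)
    for gene in genome.genes_on(chrom):
        if gene.is_rdna:
            prof[gene.start : gene.end] *= config.rdna_accessibility_multiplier
            continue
        if gene.strand == "+":
            lo, hi = gene.tss - config.ndr_width, gene.tss
        else:
            lo, hi = gene.tss + 1, gene.tss + 1 + config.ndr_width
        prof[max(lo, 0) : min(hi, length)] *= config.ndr_boost
    half = NUCLEOSOME_FOOTPRINT // 2
    for d in dyads:
        prof[max(d - half, 0) : min(d + half + 1, length)] *= config.nucleosome_dip
    prof /= prof.mean()
    comp = genome.compartment[chrom]
    mult = config.accessibility_multiplier.get(comp, 1.0)
    return prof * genome.copy_number[chrom] * mult


def _sample_lengths(
    rng: np.random.Generator, mode: float, sd: float, n: int, min_len: int
) -> np.ndarray:
    """Truncated-normal lengths (>= min_len), sampled by rejection."""
    out = np.rint(rng.normal(mode, sd, size=n)).astype(np.int64)
    bad = out < min_len
    while bad.any():
        out[bad] = np.rint(rng.normal(mode, sd, size=int(bad.sum()))).astype(np.int64)
        bad = out < min_len
    return out


def _fit_to_chrom(starts: np.ndarray, lengths: np.ndarray, chrom_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Shift fragments so they lie within [0, chrom_len), preserving length."""
    lengths = np.minimum(lengths, chrom_len)
    starts = np.clip(starts, 0, chrom_len - lengths)
    return starts, starts + lengths


def simulate_atac_fragments(
    genome: CompartmentalizedGenome,
    config: SimulationConfig,
    dyads: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Accessibility library: starts follow the accessibility profile;
    nucleosome-spanning fragments are centred on planted dyads."""
    rng = config.rng("atac")
    if dyads is None:
        dyads = plant_dyads(genome, config)
    depth = int(config.depth["atac"])
    profiles = {
        c: accessibility_profile(genome, config, c, dyads.get(c, np.array([], dtype=np.int64)))
        for c in genome.chroms
    }
    chrom_rates = np.array([profiles[c].sum() for c in genome.chroms])
    if chrom_rates.sum() <= 0:
        raise ValueError("total accessibility rate is zero")
    counts = rng.multinomial(depth, chrom_rates / chrom_rates.sum())

    parts = []
    for chrom, n in zip(genome.chroms, counts):
        if n == 0:
            continue
        comp = genome.compartment[chrom]
        mixture = config.mixture_for(comp)
        weights = np.array([c.weight for c in mixture])
        comp_idx = rng.choice(len(mixture), size=n, p=weights / weights.sum())
        length = genome.chrom_length(chrom)
        prof = profiles[chrom]
        p = prof / prof.sum()
        chrom_dyads = dyads.get(chrom, np.array([], dtype=np.int64))

        starts = np.empty(n, dtype=np.int64)
        lengths = np.empty(n, dtype=np.int64)
        for k, component in enumerate(mixture):
            sel = comp_idx == k
            m = int(sel.sum())
            if m == 0:
                continue
            lens = _sample_lengths(rng, component.mode, component.sd, m, config.min_frag_len)
            if component.nucleosomal and len(chrom_dyads) > 0:
                centers = chrom_dyads[rng.integers(0, len(chrom_dyads), size=m)]
                centers = centers + np.rint(
                    rng.normal(0.0, config.positioning_sd, size=m)
                ).astype(np.int64)
                st = centers - lens // 2
            else:
                st = rng.choice(length, size=m, p=p)
            starts[sel] = st
            lengths[sel] = lens
        starts, ends = _fit_to_chrom(starts, lengths, length)
        parts.append(make_fragments(np.repeat(chrom, n), starts, ends))
    frags = pd.concat(parts, ignore_index=True)
    assert len(frags) == depth
    return frags


def simulate_kas_fragments(
    genome: CompartmentalizedGenome, config: SimulationConfig
) -> pd.DataFrame:
    """Transcription library: per-bp rate within gene bodies proportional to
    transcription_rate x copy_number; uniform coverage inside each gene."""
    rng = config.rng("kas")
    depth = int(config.depth["kas"])
    genes = genome.genes
    if not genes:
        raise ValueError("genome has no genes to transcribe")
    rates = np.array(
        [config.gene_rate(g) * genome.copy_number[g.chrom] * g.length for g in genes]
    )
    if rates.sum() <= 0:
        raise ValueError("total transcription rate is zero")
    counts = rng.multinomial(depth, rates / rates.sum())

    mode, sd = config.kas_frag_len
    parts = []
    for gene, n in zip(genes, counts):
        if n == 0:
            continue
        mids = rng.integers(gene.start, gene.end, size=n)
        lens = _sample_lengths(rng, mode, sd, n, config.min_frag_len)
        starts, ends = _fit_to_chrom(mids - lens // 2, lens, genome.chrom_length(gene.chrom))
        parts.append(make_fragments(np.repeat(gene.chrom, n), starts, ends))
    frags = pd.concat(parts, ignore_index=True)
    assert len(frags) == depth
    return frags


def simulate_input_fragments(
    genome: CompartmentalizedGenome, config: SimulationConfig
) -> pd.DataFrame:
    """DNA-mass input: chromosome totals proportional to length x copy_number,
    start sites uniform."""
    rng = config.rng("input")
    depth = int(config.depth["input"])
    chroms = genome.chroms
    rates = np.array(
        [genome.chrom_length(c) * genome.copy_number[c] for c in chroms], dtype=float
    )
    counts = rng.multinomial(depth, rates / rates.sum())
    mode, sd = config.input_frag_len
    parts = []
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        length = genome.chrom_length(chrom)
        starts = rng.integers(0, length, size=n)
        lens = _sample_lengths(rng, mode, sd, n, config.min_frag_len)
        starts, ends = _fit_to_chrom(starts, lens, length)
        parts.append(make_fragments(np.repeat(chrom, n), starts, ends))
    frags = pd.concat(parts, ignore_index=True)
    assert len(frags) == depth
    return frags


# ---------------------------------------------------------------------------
# Hi-C

def _subtelomere_windows(
    genome: CompartmentalizedGenome, chrom: str, width: int
) -> list[tuple[int, int]]:
    n = genome.chrom_length(chrom)
    width = min(width, n // 2)
    return [(0, width), (n - width, n)]


def simulate_hic_pairs(
    genome: CompartmentalizedGenome, config: SimulationConfig
) -> pd.DataFrame:
    """Contact pairs: cis separations follow a power-law decay; trans rates
    scale with copy numbers and compartment multipliers; nucleomorph
    both-ends-subtelomeric trans pairs are boosted by ``telomere_boost``."""
    rng = config.rng("hic")
    hic = config.hic
    depth = int(config.depth["hic"])
    chroms = genome.chroms
    mb = {c: genome.chrom_length(c) / 1e6 for c in chroms}

    # one sampling bucket per cis chromosome and per unordered trans pair
    buckets: list[tuple[str, str]] = []
    weights: list[float] = []
    for i, a in enumerate(chroms):
        buckets.append((a, a))
        weights.append(hic.cis_weight * genome.copy_number[a] * mb[a])
        for b in chroms[i + 1 :]:
            buckets.append((a, b))
            weights.append(
                genome.copy_number[a]
                * genome.copy_number[b]
                * mb[a]
                * mb[b]
                * hic.trans_mult(genome.compartment[a], genome.compartment[b])
            )
    weights = np.asarray(weights)
    if weights.sum() <= 0:
        raise ValueError("total Hi-C contact rate is zero")
    counts = rng.multinomial(depth, weights / weights.sum())

    parts = []
    for (a, b), n in zip(buckets, counts):
        if n == 0:
            continue
        if a == b:
            parts.append(_sample_cis(rng, genome, config, a, n))
        else:
            parts.append(_sample_trans(rng, genome, config, a, b, n))
    pairs = pd.concat(parts, ignore_index=True)
    assert len(pairs) == depth
    return canonical_pair_order(pairs, chroms)


def _sample_cis(rng, genome, config, chrom: str, n: int) -> pd.DataFrame:
    hic = config.hic
    length = genome.chrom_length(chrom)
    s_min = min(hic.min_separation, max(length // 10, 1))
    seps = np.arange(s_min, length, dtype=float)
    # per-locus-pair contact probability ~ s^-alpha: weight separations by the
    # number of locus pairs at that separation, (L - s)
    p = seps ** (-hic.decay_exponent) * (length - seps)
    p /= p.sum()
    s = rng.choice(len(seps), size=n, p=p) + s_min
    pos1 = (rng.random(n) * (length - s)).astype(np.int64)
    pos2 = pos1 + s
    return _pairs_frame(chrom, pos1, chrom, pos2, rng)


def _sample_trans(rng, genome, config, a: str, b: str, n: int) -> pd.DataFrame:
    hic = config.hic
    la, lb = genome.chrom_length(a), genome.chrom_length(b)
    boost = hic.telomere_boost
    nm_pair = (
        genome.compartment[a] == "nucleomorph" and genome.compartment[b] == "nucleomorph"
    )
    if not nm_pair or boost == 1.0:
        return _pairs_frame(
            a, rng.integers(0, la, size=n), b, rng.integers(0, lb, size=n), rng
        )

    wins_a = _subtelomere_windows(genome, a, hic.subtelomere_bp)
    wins_b = _subtelomere_windows(genome, b, hic.subtelomere_bp)
    frac_a = sum(e - s for s, e in wins_a) / la
    frac_b = sum(e - s for s, e in wins_b) / lb
    joint = frac_a * frac_b
    p_tt = boost * joint / (boost * joint + (1.0 - joint))
    is_tt = rng.random(n) < p_tt
    pos1 = np.empty(n, dtype=np.int64)
    pos2 = np.empty(n, dtype=np.int64)

    n_tt = int(is_tt.sum())
    if n_tt:
        pos1[is_tt] = _uniform_in_windows(rng, wins_a, n_tt)
        pos2[is_tt] = _uniform_in_windows(rng, wins_b, n_tt)
    n_rest = n - n_tt
    if n_rest:
        # uniform conditioned on NOT both-telomeric, by rejection
        p1 = rng.integers(0, la, size=n_rest)
        p2 = rng.integers(0, lb, size=n_rest)
        bad = _in_windows(p1, wins_a) & _in_windows(p2, wins_b)
        while bad.any():
            k = int(bad.sum())
            p1[bad] = rng.integers(0, la, size=k)
            p2[bad] = rng.integers(0, lb, size=k)
            bad = _in_windows(p1, wins_a) & _in_windows(p2, wins_b)
        pos1[~is_tt] = p1
        pos2[~is_tt] = p2
    return _pairs_frame(a, pos1, b, pos2, rng)


def _uniform_in_windows(rng, windows: list[tuple[int, int]], n: int) -> np.ndarray:
    sizes = np.array([e - s for s, e in windows], dtype=float)
    idx = rng.choice(len(windows), size=n, p=sizes / sizes.sum())
    out = np.empty(n, dtype=np.int64)
    for i, (s, e) in enumerate(windows):
        sel = idx == i
        out[sel] = rng.integers(s, e, size=int(sel.sum()))
    return out


def _in_windows(pos: np.ndarray, windows: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for s, e in windows:
        mask |= (pos >= s) & (pos < e)
    return mask


def _pairs_frame(c1, pos1, c2, pos2, rng) -> pd.DataFrame:
    n = len(pos1)
    strands = np.array(["+", "-"])
    return pd.DataFrame(
        {
            "chrom1": np.repeat(c1, n),
            "pos1": np.asarray(pos1, dtype=np.int64),
            "chrom2": np.repeat(c2, n),
            "pos2": np.asarray(pos2, dtype=np.int64),
            "strand1": strands[rng.integers(0, 2, size=n)],
            "strand2": strands[rng.integers(0, 2, size=n)],
        }
    )


def canonical_pair_order(pairs: pd.DataFrame, chrom_order: Sequence[str]) -> pd.DataFrame:
    """Upper-triangular ordering: (chrom1, pos1) <= (chrom2, pos2) by genome order."""
    rank = {c: i for i, c in enumerate(chrom_order)}
    r1 = pairs["chrom1"].map(rank).to_numpy()
    r2 = pairs["chrom2"].map(rank).to_numpy()
    flip = (r1 > r2) | ((r1 == r2) & (pairs["pos1"].to_numpy() > pairs["pos2"].to_numpy()))
    out = pairs.copy()
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        out.loc[flip, [a, b]] = pairs.loc[flip, [b, a]].to_numpy()
    return out


# ---------------------------------------------------------------------------
# ground truth

def ground_truth(
    genome: CompartmentalizedGenome,
    config: SimulationConfig,
    dyads: Mapping[str, np.ndarray] | None = None,
) -> dict:
    """Everything the generator planted, for parameter-recovery tests."""
    if dyads is None:
        dyads = plant_dyads(genome, config)
    return {
        "seed": config.seed,
        "accessibility_multiplier": dict(config.accessibility_multiplier),
        "rdna_accessibility_multiplier": config.rdna_accessibility_multiplier,
        "copy_number": {c: genome.copy_number[c] for c in genome.chroms},
        "compartment": dict(genome.compartment),
        "transcription_rate": {g.gene_id: config.gene_rate(g) for g in genome.genes},
        "dyads": {c: [int(d) for d in v] for c, v in dyads.items() if len(v)},
        "frag_len_modes": {
            comp: [c.mode for c in config.mixture_for(comp)]
            for comp in set(genome.compartment.values())
        },
        "hic": {
            "decay_exponent": config.hic.decay_exponent,
            "telomere_boost": config.hic.telomere_boost,
            "trans_multiplier": {
                f"{a}|{b}": v for (a, b), v in config.hic.trans_multiplier.items()
            },
            "subtelomere_bp": config.hic.subtelomere_bp,
        },
        "depth": dict(config.depth),
    }


def write_truth(truth: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def simulate_all(config: SimulationConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Run the whole generator and write every artefact under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    genome = simulate_genome(config)
    paths = write_genome_files(genome, outdir)
    dyads = plant_dyads(genome, config)
    for name, frags in (
        ("atac", simulate_atac_fragments(genome, config, dyads)),
        ("kas", simulate_kas_fragments(genome, config)),
        ("input", simulate_input_fragments(genome, config)),
    ):
        paths[name] = os.path.join(outdir, f"{name}.bed")
        nio.write_bed(frags, paths[name])
    pairs = simulate_hic_pairs(genome, config)
    paths["pairs"] = os.path.join(outdir, "hic.pairs")
    nio.write_pairs(pairs, paths["pairs"], genome.lengths)
    paths["truth"] = os.path.join(outdir, "truth.json")
    write_truth(ground_truth(genome, config, dyads), paths["truth"])
    return paths
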