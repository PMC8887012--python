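"""Generator tests: determinism, composition, annotation arithmetic and
distributional properties recoverable from the planted ground truth."""

import filecmp
import json

import numpy as np
import pytest
from scipy import stats

from nucleochrom import io as nio
from nucleochrom import synthetic
from nucleochrom.core import ConfigurationError, fragment_midpoints
from nucleochrom.synthetic import (
    ChromPlan,
    HiCParams,
    LengthComponent,
    SimulationConfig,
    default_config,
)


def _flat_config(seed=0, length=200_000, depth=50_000, compartment="nucleus", **kw):
    """Single featureless chromosome: uniform accessibility."""
    return SimulationConfig(
        seed=seed,
        chrom_plan=[ChromPlan("c1", length, compartment)],
        genes_per_chrom=0,
        frag_len_mixture={compartment: [LengthComponent(150.0, 30.0, 1.0)]},
        depth=dict(atac=depth, kas=depth, input=depth, hic=depth),
        **kw,
    )


class TestGenome:
    def test_pure_at_composition(self):
        cfg = SimulationConfig(
            seed=0,
            chrom_plan=[ChromPlan("NM1", 50_000, "nucleomorph", 2.0, at_fraction=1.0)],
            genes_per_chrom=3,
            rdna_subtelomere_bp=5000,
        )
        genome = synthetic.simulate_genome(cfg)
        assert set(genome.sequences["NM1"]) <= {"A", "T"}

    def test_deterministic_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            cfg = default_config(seed=5, depth=2000)
            synthetic.simulate_all(cfg, tmp_path / sub)
        for name in (
            "genome.fa", "genes.gff3", "compartments.tsv", "telomeres.bed",
            "atac.bed", "kas.bed", "input.bed", "hic.pairs", "truth.json",
        ):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name

    def test_realized_at_fraction_within_2pc(self, genome, sim_config):
        for plan in sim_config.chrom_plan:
            if plan.length < 50_000:
                continue
            seq = genome.sequences[plan.name]
            at = (seq.count("A") + seq.count("T")) / len(seq)
            assert abs(at - plan.at_fraction) < 0.02

    def test_rdna_annotation_arithmetic(self, tmp_path):
        # 3 nucleomorph chromosomes totalling 380 kbp, rDNA ~11% of that
        cfg = default_config(seed=0, depth=10)
        genome = synthetic.simulate_genome(cfg)
        paths = synthetic.write_genome_files(genome, tmp_path)
        genes = nio.read_gff3(paths["gff3"])
        nm_total = sum(
            len(genome.sequences[c]) for c in genome.chroms_of("nucleomorph")
        )
        assert nm_total == 380_000
        rdna_bp = sum(g.length for g in genes if g.is_rdna)
        expected = 2 * cfg.rdna_subtelomere_bp * 3  # both ends of 3 chromosomes
        assert rdna_bp == expected
        assert rdna_bp / nm_total == pytest.approx(0.11, abs=0.01)

    def test_rdna_confined_to_subtelomeric_windows(self, genome, sim_config):
        tel, rd = sim_config.telomere_bp, sim_config.rdna_subtelomere_bp
        for g in genome.genes:
            if not g.is_rdna:
                continue
            n = genome.chrom_length(g.chrom)
            in_left = tel <= g.start and g.end <= tel + rd
            in_right = n - tel - rd <= g.start and g.end <= n - tel
            assert in_left or in_right, g

    def test_features_do_not_fit_names_chromosome(self):
        cfg = SimulationConfig(
            seed=0,
            chrom_plan=[ChromPlan("NM1", 20_000, "nucleomorph", 2.0)],
            genes_per_chrom=30,
            rdna_subtelomere_bp=9000,
        )
        with pytest.raises(ConfigurationError, match="NM1"):
            synthetic.simulate_genome(cfg)

    def test_invalid_copy_number_rejected(self):
        with pytest.raises(ConfigurationError, match="copy_number"):
            SimulationConfig(
                seed=0, chrom_plan=[ChromPlan("c", 1000, "nucleus", copy_number=0.0)]
            )

    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="weights"):
            SimulationConfig(
                seed=0,
                chrom_plan=[ChromPlan("c", 1000, "nucleus")],
                frag_len_mixture={"nucleus": [LengthComponent(100, 10, 0.5)]},
            )


class TestAtac:
    def test_uniform_null_start_sites(self):
        cfg = _flat_config(seed=2, depth=100_000)
        genome = synthetic.simulate_genome(cfg)
        frags = synthetic.simulate_atac_fragments(genome, cfg)
        counts, _ = np.histogram(
            frags["start"].to_numpy(), bins=np.arange(0, 200_001, 1000)
        )
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_depth_conserved_exactly(self, atac, sim_config):
        assert len(atac) == sim_config.depth["atac"]

    def test_coordinates_within_bounds(self, atac, genome):
        for chrom, sub in atac.groupby("chrom"):
            assert sub["start"].min() >= 0
            assert sub["end"].max() <= genome.chrom_length(str(chrom))

    def test_nucleosomal_midpoints_peak_at_planted_dyad(self):
        # one + strand gene, dyads planted at TSS+110 (and +285 / -130)
        cfg = SimulationConfig(
            seed=4,
            chrom_plan=[ChromPlan("c1", 30_000, "nucleomorph", 2.0)],
            genes_per_chrom=1,
            rdna_subtelomere_bp=0,
            positioning_sd=5.0,
            frag_len_mixture={
                "nucleomorph": [LengthComponent(220.0, 18.0, 1.0, nucleosomal=True)]
            },
            depth=dict(atac=20_000, kas=10, input=10, hic=10),
        )
        genome = synthetic.simulate_genome(cfg)
        gene = genome.genes[0]
        assert gene.strand == "+"
        frags = synthetic.simulate_atac_fragments(genome, cfg)
        lens = (frags["end"] - frags["start"]).to_numpy()
        sel = (lens >= 160) & (lens <= 250)
        mids = fragment_midpoints(frags[sel])
        offsets = mids - gene.tss
        near = offsets[(offsets > 50) & (offsets < 200)]
        hist = np.bincount(near - 51, minlength=150)
        assert abs((np.argmax(hist) + 51) - 110) <= 10

    def test_zero_total_rate_errors(self):
        cfg = _flat_config(seed=0, depth=100)
        genome = synthetic.simulate_genome(cfg)
        genome.copy_number["c1"] = 0.0  # mutate after validation to force zero rate
        with pytest.raises(ValueError, match="rate"):
            synthetic.simulate_atac_fragments(genome, cfg)


class TestKas:
    def test_equal_rates_give_uniform_rpkm(self):
        cfg = SimulationConfig(
            seed=3,
            chrom_plan=[ChromPlan("c1", 200_000, "nucleus")],
            genes_per_chrom=40,
            depth=dict(atac=10, kas=100_000, input=10, hic=10),
        )
        genome = synthetic.simulate_genome(cfg)
        frags = synthetic.simulate_kas_fragments(genome, cfg)
        mids = fragment_midpoints(frags)
        rpkms = []
        for g in genome.genes:
            n = ((mids >= g.start) & (mids < g.end)).sum()
            rpkms.append(n / g.length)
        rpkms = np.array(rpkms, dtype=float)
        assert rpkms.std() / rpkms.mean() < 0.1

    def test_rdna_rate_recovered_20x(self, genome, sim_config, kas):
        mids = fragment_midpoints(kas)
        chroms = kas["chrom"].to_numpy()
        rdna_rpkm, other_rpkm = [], []
        for g in genome.genes:
            if genome.compartment[g.chrom] != "nucleomorph":
                continue
            n = ((chroms == g.chrom) & (mids >= g.start) & (mids < g.end)).sum()
            (rdna_rpkm if g.is_rdna else other_rpkm).append(n / g.length)
        ratio = np.mean(rdna_rpkm) / np.mean(other_rpkm)
        assert ratio == pytest.approx(20.0, rel=0.15)

    def test_zero_rate_gene_gets_no_fragments(self):
        cfg = SimulationConfig(
            seed=5,
            chrom_plan=[ChromPlan("c1", 100_000, "nucleus")],
            genes_per_chrom=10,
            transcription_rate={"c1_g0": 0.0},
            depth=dict(atac=10, kas=50_000, input=10, hic=10),
        )
        genome = synthetic.simulate_genome(cfg)
        frags = synthetic.simulate_kas_fragments(genome, cfg)
        g0 = genome.genes[0]
        mids = fragment_midpoints(frags)
        overlapping = ((frags["end"] > g0.start) & (frags["start"] < g0.end)).sum()
        # fragments from neighbouring genes may hang over the edges slightly,
        # but none should have a midpoint inside g0
        assert ((mids >= g0.start) & (mids < g0.end)).sum() == 0
        assert overlapping <= 20  # edge overhang only


class TestInput:
    def test_copy_ratio_recovered(self):
        cfg = SimulationConfig(
            seed=6,
            chrom_plan=[
                ChromPlan("a", 100_000, "nucleus", 1.0),
                ChromPlan("b", 100_000, "nucleomorph", 2.0),
            ],
            genes_per_chrom=0,
            rdna_subtelomere_bp=0,
            depth=dict(atac=10, kas=10, input=100_000, hic=10),
        )
        genome = synthetic.simulate_genome(cfg)
        frags = synthetic.simulate_input_fragments(genome, cfg)
        counts = frags.groupby("chrom").size()
        assert counts["b"] / counts["a"] == pytest.approx(2.0, rel=0.05)

    def test_single_chromosome(self):
        cfg = _flat_config(seed=7, depth=500)
        genome = synthetic.simulate_genome(cfg)
        frags = synthetic.simulate_input_fragments(genome, cfg)
        assert (frags["chrom"] == "c1").all()

    def test_zero_copy_number_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                seed=0, chrom_plan=[ChromPlan("c", 1000, "nucleus", copy_number=0.0)]
            )


class TestHiC:
    def test_depth_conserved(self, hic_pairs, sim_config):
        assert len(hic_pairs) == sim_config.depth["hic"]

    def test_canonical_ordering(self, hic_pairs, genome):
        rank = {c: i for i, c in enumerate(genome.chroms)}
        r1 = hic_pairs["chrom1"].map(rank).to_numpy()
        r2 = hic_pairs["chrom2"].map(rank).to_numpy()
        same = r1 == r2
        assert np.all(r1 <= r2)
        assert np.all(
            hic_pairs.loc[same, "pos1"].to_numpy() <= hic_pairs.loc[same, "pos2"].to_numpy()
        )

    def test_exchangeable_trans_shares(self):
        cfg = SimulationConfig(
            seed=8,
            chrom_plan=[
                ChromPlan("a", 100_000, "nucleus"),
                ChromPlan("b", 100_000, "nucleus"),
                ChromPlan("c", 100_000, "nucleus"),
            ],
            genes_per_chrom=0,
            hic=HiCParams(telomere_boost=1.0, cis_weight=0.1),
            depth=dict(atac=10, kas=10, input=10, hic=120_000),
        )
        genome = synthetic.simulate_genome(cfg)
        pairs = synthetic.simulate_hic_pairs(genome, cfg)
        trans = pairs[pairs["chrom1"] != pairs["chrom2"]]
        shares = trans.groupby(["chrom1", "chrom2"]).size()
        assert shares.max() / shares.min() < 1.05

    def test_telomere_boost_fraction(self):
        cfg = SimulationConfig(
            seed=9,
            chrom_plan=[
                ChromPlan("NM1", 100_000, "nucleomorph", 2.0),
                ChromPlan("NM2", 100_000, "nucleomorph", 2.0),
            ],
            genes_per_chrom=0,
            rdna_subtelomere_bp=0,
            hic=HiCParams(telomere_boost=5.0, subtelomere_bp=10_000),
            depth=dict(atac=10, kas=10, input=10, hic=100_000),
        )
        genome = synthetic.simulate_genome(cfg)
        pairs = synthetic.simulate_hic_pairs(genome, cfg)
        trans = pairs[pairs["chrom1"] != pairs["chrom2"]]
        in_tel1 = (trans["pos1"] < 10_000) | (trans["pos1"] >= 90_000)
        in_tel2 = (trans["pos2"] < 10_000) | (trans["pos2"] >= 90_000)
        observed = (in_tel1 & in_tel2).mean()
        area = 0.2 * 0.2
        expected = 5.0 * area / (5.0 * area + 1 - area)
        assert observed == pytest.approx(expected, rel=0.2)
        assert observed / area == pytest.approx(5.0, rel=0.25)

    def test_decay_exponent_slope(self):
        from nucleochrom import hic as H

        cfg = SimulationConfig(
            seed=10,
            chrom_plan=[ChromPlan("c1", 1_000_000, "nucleus")],
            genes_per_chrom=0,
            hic=HiCParams(decay_exponent=1.0),
            depth=dict(atac=10, kas=10, input=10, hic=100_000),
        )
        genome = synthetic.simulate_genome(cfg)
        pairs = synthetic.simulate_hic_pairs(genome, cfg)
        matrix = H.bin_contacts(pairs, genome, 5000)
        assert H.decay_exponent(matrix, "c1") == pytest.approx(1.0, abs=0.1)


def test_truth_json_round_trip(tmp_path, genome, sim_config, dyads):
    truth = synthetic.ground_truth(genome, sim_config, dyads)
    path = tmp_path / "truth.json"
    synthetic.write_truth(truth, path)
    loaded = json.loads(path.read_text())
    assert loaded["accessibility_multiplier"]["nucleomorph"] == 10.0
    assert loaded["copy_number"]["NM1"] == 2.0
    assert set(loaded["dyads"]) == {c for c, v in dyads.items() if len(v)}
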