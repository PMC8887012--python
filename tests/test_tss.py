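"""TSS profile, gene-signal, peak-caller and distance-histogram tests."""

import numpy as np
import pytest
from scipy import stats

from nucleochrom import synthetic, tss
from nucleochrom.core import fragment_midpoints, make_fragments
from nucleochrom.synthetic import ChromPlan, SimulationConfig


class TestProfile:
    def test_single_fragment_rectangular(self):
        frags = make_fragments(["c"], [950], [1050])
        profile = tss.tss_profile(frags, [("c", 1000, "+")], window=100,
                                  lengths={"c": 2000})
        expected = np.zeros(201)
        expected[(np.arange(-100, 101) >= -50) & (np.arange(-100, 101) < 50)] = 1.0
        np.testing.assert_allclose(profile.matrix[0], expected)

    def test_symmetric_fragments_give_symmetric_metaplot(self):
        anchors = [("c", 1000, "+"), ("c", 5000, "+")]
        rows = []
        for _, pos, _ in anchors:
            rows.append((pos - 120, pos - 20))   # [-120, -20)
            rows.append((pos + 21, pos + 121))   # mirror: [21, 121)
        starts, ends = zip(*rows)
        frags = make_fragments(["c"] * len(rows), starts, ends)
        profile = tss.tss_profile(frags, anchors, window=200, lengths={"c": 10_000})
        meta = profile.metaplot
        np.testing.assert_allclose(meta, meta[::-1], atol=1e-9)

    def test_minus_strand_orientation_flips(self):
        # fragment strictly downstream of a minus-strand TSS
        frags = make_fragments(["c"], [880], [980])  # upstream in + coords
        profile = tss.tss_profile(frags, [("c", 1000, "-")], window=200,
                                  lengths={"c": 2000})
        offsets = np.arange(-200, 201)
        covered = offsets[profile.matrix[0] > 0]
        assert covered.min() >= 20  # appears downstream after flipping

    def test_metaplot_is_mean_of_rows(self, atac, genome):
        genes = [g for g in genome.genes if g.chrom == "NM1" and not g.is_rdna][:10]
        profile = tss.tss_profile(atac, tss.gene_anchors(genes), window=500,
                                  lengths=genome.lengths)
        np.testing.assert_allclose(profile.metaplot, profile.matrix.mean(axis=0))

    def test_cut_site_metaplot_max_in_ndr(self, atac, genome, sim_config):
        genes = [g for g in genome.genes
                 if genome.compartment[g.chrom] == "nucleomorph" and not g.is_rdna]
        profile = tss.tss_profile(atac, tss.gene_anchors(genes), window=500,
                                  lengths=genome.lengths, cut_sites=True)
        peak_offset = profile.offsets[int(np.argmax(profile.metaplot))]
        assert -sim_config.ndr_width <= peak_offset <= 0

    def test_nucleosomal_midpoint_maxima_at_planted_offsets(self, atac, genome, sim_config):
        lens = (atac["end"] - atac["start"]).to_numpy()
        nucl = atac[(lens >= 160) & (lens <= 250)]
        mid = nucl.copy()
        mids = fragment_midpoints(nucl)
        mid["start"], mid["end"] = mids, mids + 1
        genes = [g for g in genome.genes
                 if genome.compartment[g.chrom] == "nucleomorph" and not g.is_rdna]
        profile = tss.tss_profile(mid, tss.gene_anchors(genes), window=400,
                                  lengths=genome.lengths)
        meta = profile.metaplot
        offsets = profile.offsets
        for planted in (sim_config.minus_one_offset, sim_config.plus_one_offset,
                        sim_config.plus_one_offset + sim_config.nucleosome_spacing):
            sel = np.abs(offsets - planted) <= 30
            local_peak = offsets[sel][np.argmax(meta[sel])]
            assert abs(local_peak - planted) <= 10, planted

    def test_window_must_be_multiple_of_bin(self, atac):
        with pytest.raises(ValueError):
            tss.tss_profile(atac, [("chr1", 100, "+")], window=100, bin_size=33)


class TestGeneSignal:
    def test_gene_without_fragments_is_zero(self, genome):
        frags = make_fragments(["chr1"], [0], [100])
        gene = [g for g in genome.genes if g.chrom == "chr2"][0]
        signal = tss.quantify_gene_signal(frags, [gene], genome, mode="gene_body")
        assert signal[gene.gene_id] == 0.0

    def test_scale_invariance(self, kas, genome):
        genes = [g for g in genome.genes if not g.is_rdna][:20]
        s1 = tss.quantify_gene_signal(kas, genes, genome, mode="gene_body")
        doubled = kas.copy()
        import pandas as pd

        doubled = pd.concat([kas, kas], ignore_index=True)
        s2 = tss.quantify_gene_signal(doubled, genes, genome, mode="gene_body")
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_rate_ratio_recovery(self):
        cfg = SimulationConfig(
            seed=21,
            chrom_plan=[ChromPlan("c1", 100_000, "nucleus")],
            genes_per_chrom=10,
            transcription_rate={"c1_g0": 5.0, "c1_g1": 1.0},
            depth=dict(atac=10, kas=100_000, input=10, hic=10),
        )
        genome = synthetic.simulate_genome(cfg)
        kas = synthetic.simulate_kas_fragments(genome, cfg)
        genes = {g.gene_id: g for g in genome.genes}
        signal = tss.quantify_gene_signal(
            kas, [genes["c1_g0"], genes["c1_g1"]], genome, mode="gene_body"
        )
        assert signal["c1_g0"] / signal["c1_g1"] == pytest.approx(5.0, rel=0.15)

    def test_kas_rank_correlates_with_truth(self, kas, genome, sim_config):
        genes = [g for g in genome.genes if genome.compartment[g.chrom] == "nucleomorph"]
        signal = tss.quantify_gene_signal(kas, genes, genome, mode="gene_body")
        truth = [sim_config.gene_rate(g) for g in genes]
        rho = tss.rank_correlation(signal.to_numpy(), truth)
        assert rho > 0.5  # rDNA genes rank on top


class TestRankCorrelation:
    def test_identity(self, rng):
        x = rng.random(50)
        assert tss.rank_correlation(x, x) == pytest.approx(1.0)

    def test_antitone(self, rng):
        x = rng.random(50)
        assert tss.rank_correlation(x, -x) == pytest.approx(-1.0)

    def test_small_table_matches_rank_formula(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 0.5, 6.0, 1.0, 3.0]
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        d2 = ((rx - ry) ** 2).sum()
        expected = 1 - 6 * d2 / (5 * 24)
        assert tss.rank_correlation(x, y) == pytest.approx(expected)


class TestPeakCaller:
    def _uniform(self, rng, n=10_000, L=100_000):
        cfg = SimulationConfig(
            seed=int(rng.integers(1 << 30)),
            chrom_plan=[ChromPlan("c1", L, "nucleus")],
            genes_per_chrom=0,
        )
        genome = synthetic.simulate_genome(cfg)
        starts = rng.integers(0, L - 100, size=n)
        return genome, make_fragments(np.repeat("c1", n), starts, starts + 100)

    @pytest.mark.parametrize("p", [1e-3, 1e-5])
    def test_type_one_calibration(self, rng, p):
        genome, frags = self._uniform(rng)
        _, n_windows, n_sig = tss.call_peaks_simple(
            frags, genome, p_threshold=p, return_window_stats=True
        )
        assert n_sig <= max(2 * p * n_windows, 1)

    def test_spiked_region_yields_one_peak(self, rng):
        genome, frags = self._uniform(rng, n=5000)
        # 200-bp region at ~50x background midpoint density
        extra_n = 500
        starts = rng.integers(50_000, 50_200, size=extra_n) - 50
        import pandas as pd

        spike = make_fragments(np.repeat("c1", extra_n), starts, starts + 100)
        all_frags = pd.concat([frags, spike], ignore_index=True)
        peaks = tss.call_peaks_simple(all_frags, genome, p_threshold=1e-5)
        assert len(peaks) == 1
        assert peaks[0].start <= 50_000 and peaks[0].end >= 50_200

    def test_empty_library_warns_and_returns_nothing(self, genome, atac):
        with pytest.warns(UserWarning, match="empty"):
            peaks = tss.call_peaks_simple(atac.iloc[:0], genome)
        assert peaks == []


class TestRandomControl:
    def test_exact_boundary_count(self):
        cfg = SimulationConfig(
            seed=0, chrom_plan=[ChromPlan("c", 10_000, "nucleus")], genes_per_chrom=0
        )
        genome = synthetic.simulate_genome(cfg)
        positions = tss.random_control_peaks(genome, 500)
        assert len(positions["c"]) == 21

    def test_partial_final_bin(self):
        cfg = SimulationConfig(
            seed=0, chrom_plan=[ChromPlan("c", 10_250, "nucleus")], genes_per_chrom=0
        )
        genome = synthetic.simulate_genome(cfg)
        positions = tss.random_control_peaks(genome, 500)
        assert len(positions["c"]) == 22
        assert positions["c"][-1] == 10_250

    def test_two_chromosomes_union(self):
        cfg = SimulationConfig(
            seed=0,
            chrom_plan=[
                ChromPlan("a", 10_000, "nucleus"),
                ChromPlan("b", 5_000, "nucleus"),
            ],
            genes_per_chrom=0,
        )
        genome = synthetic.simulate_genome(cfg)
        positions = tss.random_control_peaks(genome, 500)
        assert set(positions) == {"a", "b"}
        assert len(positions["a"]) == 21 and len(positions["b"]) == 11


class TestPeakDistances:
    def test_peaks_at_tss_all_mass_at_zero(self, genome):
        genes = [g for g in genome.genes if not g.is_rdna][:30]
        anchors = tss.gene_anchors(genes)
        positions = {}
        for chrom, pos, _ in anchors:
            positions.setdefault(chrom, []).append(pos)
        positions = {c: np.array(v) for c, v in positions.items()}
        hist = tss.peak_tss_distances(positions, anchors, max_range=1000, bin_size=100)
        zero_bin = hist[(hist["bin_start"] <= 0) & (hist["bin_end"] > 0)]
        assert zero_bin["count"].iloc[0] == len(genes)
        assert hist["count"].sum() == len(genes)

    def test_promoter_peaks_concentrate_within_500(self, rng, genome):
        genes = [g for g in genome.genes if g.chrom == "chr1" and not g.is_rdna]
        anchors = tss.gene_anchors(genes)
        jitter = rng.normal(0, 150, size=len(anchors)).astype(int)
        positions = {"chr1": np.array([p + j for (_, p, _), j in zip(anchors, jitter)])}
        hist = tss.peak_tss_distances(positions, anchors, max_range=2000, bin_size=100)
        within = hist[(hist["bin_start"] >= -500) & (hist["bin_end"] <= 500)]["count"].sum()
        assert within / hist["count"].sum() >= 0.9

    def test_random_control_approximately_flat(self, rng):
        # dense, irregularly spaced anchors: bin boundaries land uniformly
        cfg = SimulationConfig(
            seed=0, chrom_plan=[ChromPlan("c", 500_000, "nucleus")], genes_per_chrom=0
        )
        genome = synthetic.simulate_genome(cfg)
        anchor_pos = np.cumsum(rng.integers(1500, 3500, size=180))
        anchors = [("c", int(p), "+") for p in anchor_pos if p < 490_000]
        positions = tss.random_control_peaks(genome, 500)
        hist = tss.peak_tss_distances(positions, anchors, max_range=1000, bin_size=250)
        inner = hist["count"].to_numpy()[1:-1]  # edge bins pool the tails
        assert inner.min() > 0
        assert inner.max() < 2.5 * inner.min()
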