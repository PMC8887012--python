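"""End-to-end pipeline driver.

Chains simulate -> mappability -> enrichment -> fragment spectra ->
TSS profiles/peaks -> nucleosome positioning/V-plots -> Hi-C into one
reproducible run, controlled by a single YAML/JSON config with strict key
checking, and emits a machine-readable JSON report.
"""

from __future__ import annotations

import copy
import json
import logging
import os
import time
from typing import Any

import numpy as np
import yaml

from . import enrichment as enr
from . import hic as hic_mod
from . import io as nio
from . import nucleosomes as nuc
from . import spectra as spec_mod
from . import synthetic
from . import tss as tss_mod
from .mappability import compute_mappability

logger = logging.getLogger("nucleochrom")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "nucleochrom_run",
    "depth": 100_000,
    "mappability": {"read_length": 36},
    "enrichment": {"groupings": ["compartment", "chromosome", "region-class"]},
    "spectra": {"smoothing_bw": 10.0, "min_prominence": 0.05},
    "tss": {"window": 1000, "bin_size": 10, "compartment": "nucleomorph"},
    "peaks": {"window": 200, "local_bg_span": 5000, "p_threshold": 1e-5,
              "distance_range": 2000, "distance_bin": 100},
    "nucleosomes": {"window_size": 1000, "step": 500, "threshold": 2.0,
                    "kernel_bw": 20.0, "min_separation": 120,
                    "nuc_len_min": 160, "nuc_len_max": 250,
                    "vplot_window": 500, "compartment": "nucleomorph"},
    "hic": {"resolution": 5000, "normalizations": ["NONE", "VC", "VC_SQRT", "KR"],
            "mask_min_contacts": 5.0, "trans_source_compartment": "mitochondrion",
            "telomere_width": 10_000},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _merge_config(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {where} must be a mapping")
            out[key] = _merge_config(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Resolve a run config from defaults + optional YAML/JSON file + overrides."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        config = _merge_config(config, user)
    if overrides:
        config = _merge_config(config, overrides)
    return config


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # fail fast, naming the stage
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done in %.1f s", name, time.time() - t0)
            return result
        return inner
    return wrap


def run_pipeline(config: dict, outdir: str | None = None) -> dict:
    """Execute every stage in dependency order; return (and write) the report."""
    outdir = outdir or config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    report: dict[str, Any] = {"seed": config["seed"]}

    sim_cfg = synthetic.default_config(seed=config["seed"], depth=config["depth"])
    paths = _stage("simulate")(synthetic.simulate_all)(sim_cfg, outdir)
    genome = nio.load_genome(paths["fasta"], paths["compartments"], paths["gff3"],
                             paths["telomeres"])
    atac = nio.read_bed(paths["atac"], genome)
    kas = nio.read_bed(paths["kas"], genome)
    inputlib = nio.read_bed(paths["input"], genome)
    pairs = nio.read_pairs(paths["pairs"], genome)

    track = _stage("mappability")(compute_mappability)(
        genome, config["mappability"]["read_length"]
    )
    nio.write_bedgraph(
        track.scores,
        os.path.join(outdir, f"mappability_{track.read_length}.bedGraph"),
    )

    @_stage("enrichment")
    def _enrichment():
        out = {}
        for grouping in config["enrichment"]["groupings"]:
            table = enr.compute_enrichment(atac, inputlib, genome, track, grouping)
            table.to_csv(os.path.join(outdir, f"enrichment_{grouping}.tsv"), sep="\t")
            out[grouping] = {
                str(k): round(float(v), 6) if np.isfinite(v) else None
                for k, v in table["enrichment"].items()
            }
        out["copy_numbers"] = {
            c: round(v, 4) for c, v in enr.estimate_copy_numbers(inputlib, genome, track).items()
        }
        out["read_fractions"] = {
            c: round(v, 6) for c, v in enr.compartment_read_fractions(atac, genome).items()
        }
        return out

    report["enrichment"] = _enrichment()

    @_stage("fragment_spectra")
    def _spectra():
        table = spec_mod.spectra_table(
            atac, genome,
            smoothing_bw=config["spectra"]["smoothing_bw"],
            min_prominence=config["spectra"]["min_prominence"],
        )
        table.to_csv(os.path.join(outdir, "fragment_spectra.tsv"), sep="\t", index=False)
        spec_mod.density_table(atac, genome).to_csv(
            os.path.join(outdir, "fragment_densities.tsv"), sep="\t", index=False
        )
        return {
            row["compartment"]: row["modes_bp"] for _, row in table.iterrows()
        }

    report["spectrum_modes"] = _spectra()

    @_stage("tss_profiles")
    def _tss():
        comp = config["tss"]["compartment"]
        genes = [g for g in genome.genes
                 if genome.compartment[g.chrom] == comp and not g.is_rdna]
        anchors = tss_mod.gene_anchors(genes)
        profile = tss_mod.tss_profile(
            atac, anchors, config["tss"]["window"], config["tss"]["bin_size"],
            lengths=genome.lengths,
        )
        np.savetxt(
            os.path.join(outdir, f"metaplot_{comp}.tsv"),
            np.column_stack([profile.offsets, profile.metaplot]),
            delimiter="\t", header="offset\tmean_coverage", comments="",
        )
        peaks = tss_mod.call_peaks_simple(
            atac, genome,
            window=config["peaks"]["window"],
            local_bg_span=config["peaks"]["local_bg_span"],
            p_threshold=config["peaks"]["p_threshold"],
        )
        with open(os.path.join(outdir, "peaks.bed"), "w") as fh:
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t{p.fold_enrichment:.3f}"
                         f"\t{p.p_value:.3g}\n")
        all_anchors = tss_mod.gene_anchors([g for g in genome.genes if not g.is_rdna])
        dist = tss_mod.peak_tss_distances(
            peaks, all_anchors,
            max_range=config["peaks"]["distance_range"],
            bin_size=config["peaks"]["distance_bin"],
        )
        dist.to_csv(os.path.join(outdir, "peak_tss_distances.tsv"), sep="\t", index=False)
        metaplot_peak = int(profile.offsets[int(np.argmax(profile.metaplot))])
        return {"n_peaks": len(peaks), "metaplot_peak_offset": metaplot_peak}

    report["tss"] = _tss()

    @_stage("nucleosomes")
    def _nucleosomes():
        ncfg = config["nucleosomes"]
        comp = ncfg["compartment"]
        comp_chroms = set(genome.chroms_of(comp))
        sub_genome_windows = [
            w for w in nuc.sliding_windows(genome, ncfg["window_size"], ncfg["step"])
            if w[0] in comp_chroms
        ]
        dyads = nuc.call_dyads(
            atac, sub_genome_windows, genome,
            nuc_len_range=(ncfg["nuc_len_min"], ncfg["nuc_len_max"]),
            kernel_bw=ncfg["kernel_bw"],
            threshold=ncfg["threshold"],
            min_separation=ncfg["min_separation"],
        )
        nuc.dyads_to_bed(dyads, os.path.join(outdir, f"dyads_{comp}.bed"))
        vplot = nuc.make_vplot(
            atac[atac["chrom"].isin(comp_chroms)], dyads,
            window=ncfg["vplot_window"],
        )
        nuc.vplot_to_tsv(vplot, os.path.join(outdir, f"vplot_{comp}.tsv"))
        row_mass = vplot.matrix.sum(axis=1)
        dominant = int(vplot.lengths[int(np.argmax(row_mass))]) if vplot.total else None
        return {
            "n_dyads": len(dyads),
            "vplot_total": vplot.total,
            "vplot_dominant_length": dominant,
        }

    report["nucleosomes"] = _nucleosomes()

    @_stage("hic")
    def _hic():
        hcfg = config["hic"]
        matrix = hic_mod.bin_contacts(pairs, genome, hcfg["resolution"])
        hic_mod.matrix_to_tsv(matrix, os.path.join(outdir, "hic_raw.tsv"))
        source = genome.chroms_of(hcfg["trans_source_compartment"])[0]
        trans = {}
        for method in hcfg["normalizations"]:
            balanced = hic_mod.balance(
                matrix, method, mask_min_contacts=hcfg["mask_min_contacts"]
            )
            if method != "NONE":
                hic_mod.weights_to_tsv(
                    balanced, os.path.join(outdir, f"hic_weights_{method}.tsv")
                )
            profile = hic_mod.trans_profile(balanced, source)
            trans[method] = {c: round(float(v), 8) for c, v in profile.items()}
        telomeres = hic_mod.default_telomere_intervals(
            genome, hcfg["telomere_width"]
        )
        tel = hic_mod.telomere_network_score(matrix, telomeres)
        tel.per_pair.to_csv(
            os.path.join(outdir, "telomere_network.tsv"), sep="\t", index=False
        )
        nm = genome.chroms_of("nucleomorph")
        def _num(v, nd):
            return round(float(v), nd) if np.isfinite(v) else None

        return {
            "trans_profile_source": source,
            "trans_profile": trans,
            "telomere_network_ratio": _num(tel.ratio, 6),
            "cis_end_fold": {c: _num(v, 4) for c, v in tel.cis_end_fold.items()},
            "decay_exponent": {
                c: round(hic_mod.decay_exponent(matrix, c), 4) for c in nm
            },
        }

    report["hic"] = _hic()

    report_path = os.path.join(outdir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", report_path)
    return report
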