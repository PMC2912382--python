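"""End-to-end pipeline stages as plain functions over files.

Each stage reads/writes the TSV formats of :mod:`sporescan.io`, so a run
can be driven stage by stage (CLI subcommands) or chained in one call.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .bias import (aneuploidy_counts_from_tracks, aneuploidy_deficit_test,
                   chromosome_inheritance_bias)
from .genotyping import call_cohort, summarize_cohort
from .linkage import scan_with_fdr
from .multilocus import count_zero_category_triples, permutation_baseline_triples
from .segmentation import segment_cohort
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)


def stage_simulate(config: sio.RunConfig, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config.sim, config.incompatibilities,
                             seed=config.seed)
    sio.write_probe_panel(cohort.panel, outdir / "panel.tsv")
    sio.write_logratio_matrix(cohort.logratios, cohort.panel,
                              cohort.spore_ids, outdir / "logratios.tsv")
    truth_rows = []
    for s in cohort.truth.spores:
        for chrom, g in sorted(s.gamete.items()):
            truth_rows.append({
                "spore": s.spore_id, "chrom": chrom,
                "first_origin": g.first_origin,
                "crossovers": ",".join(f"{x:.0f}" for x in g.crossovers),
                "aneuploid": int(g.aneuploid)})
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t",
                                    index=False)
    logger.info("simulated %d viable spores (%d gametes rejected)",
                len(cohort.spore_ids), cohort.truth.n_rejected)


def stage_genotype(panel_path, matrix_path, config: sio.RunConfig,
                   outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = sio.read_probe_panel(panel_path)
    logratios, spore_ids = sio.read_logratio_matrix(matrix_path, panel)
    tracks = call_cohort(logratios, panel, config.genotype, spore_ids)
    sio.write_genotype_tracks(tracks, outdir / "tracks.tsv")
    sio.write_breakpoints(tracks, outdir / "breakpoints.tsv")
    summarize_cohort(tracks).to_csv(outdir / "event_summary.tsv", sep="\t",
                                    index=False)


def stage_segment(panel_path, tracks_path, config: sio.RunConfig,
                  outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = sio.read_probe_panel(panel_path)
    tracks = sio.read_genotype_tracks(tracks_path, panel)
    matrices = segment_cohort(tracks, panel, config.scan.merge_tol_bp)
    for genome, m in matrices.items():
        sio.write_segment_matrix(m, outdir / f"segments_{genome}.tsv")
        sio.write_segments_bed(m, outdir / f"segments_{genome}.bed")


def stage_scan_pairs(matrix_path, config: sio.RunConfig, out_path) -> None:
    matrix = sio.read_segment_matrix(matrix_path)
    results = scan_with_fdr(matrix, n_perm=config.scan.n_perm,
                            seed=config.seed,
                            interchromosomal_only=config.scan.interchromosomal_only)
    results.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    n_sig = int((results["fdr"] < config.scan.fdr_threshold).sum())
    logger.info("scanned %d pairs; %d at FDR < %g", len(results), n_sig,
                config.scan.fdr_threshold)


def stage_scan_triples(matrix_path, config: sio.RunConfig, out_path) -> None:
    matrix = sio.read_segment_matrix(matrix_path)
    obs = count_zero_category_triples(matrix,
                                      max_triples=config.scan.max_triples,
                                      seed=config.seed)
    base = permutation_baseline_triples(matrix,
                                        n_perm=config.scan.triple_n_perm,
                                        seed=config.seed,
                                        max_triples=config.scan.max_triples)
    pd.DataFrame([{
        "flagged": obs.flagged, "examined": obs.examined,
        "total": obs.total, "sampled": obs.sampled,
        "rate": obs.rate, "rate_ci_low": obs.rate_ci[0],
        "rate_ci_high": obs.rate_ci[1],
        "baseline_mean": base.mean, "baseline_sd": base.sd,
        "z_score": base.z_score(obs.estimated_flagged),
    }]).to_csv(out_path, sep="\t", index=False, float_format="%.6g")


def stage_bias(panel_path, tracks_path, config: sio.RunConfig,
               out_path, alpha: float = 0.05) -> None:
    panel = sio.read_probe_panel(panel_path)
    tracks = sio.read_genotype_tracks(tracks_path, panel)
    inherit = chromosome_inheritance_bias(tracks)
    aneu = aneuploidy_deficit_test(aneuploidy_counts_from_tracks(tracks),
                                   alpha=alpha)
    merged = inherit.merge(aneu, on="chrom")
    merged.to_csv(out_path, sep="\t", index=False, float_format="%.6g")


def run_all(config: sio.RunConfig, outdir) -> None:
    """simulate -> genotype -> segment -> scan-pairs -> scan-triples -> bias."""
    outdir = Path(outdir)
    stage_simulate(config, outdir)
    stage_genotype(outdir / "panel.tsv", outdir / "logratios.tsv",
                   config, outdir)
    stage_segment(outdir / "panel.tsv", outdir / "tracks.tsv", config, outdir)
    for genome in ("cer", "par"):
        stage_scan_pairs(outdir / f"segments_{genome}.tsv", config,
                         outdir / f"pairs_{genome}.tsv")
        matrix = sio.read_segment_matrix(outdir / f"segments_{genome}.tsv")
        if matrix.n_segments >= 3:
            stage_scan_triples(outdir / f"segments_{genome}.tsv", config,
                               outdir / f"triples_{genome}.tsv")
    stage_bias(outdir / "panel.tsv", outdir / "tracks.tsv", config,
               outdir / "bias.tsv")
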