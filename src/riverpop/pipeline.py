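"""End-to-end pipeline: simulate (or load) a cohort, QC/filter, population
structure, diversity statistics, private alleles, and a selection scan,
with one global seed fanned out deterministically per stage and a JSON
run manifest recording row counts at every step.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, private, qc, scan, structure, synthetic
from .datamodel import GenotypeMatrix
from .io import read_vcf, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the source pipeline's values."""

    out_dir: str = "riverpop_run"
    seed: int = 0
    input_vcf: str | None = None          # None -> synthetic cohort
    # synthetic cohort
    n_pops: int = 3
    samples_per_pop: int = 20
    n_sites: int = 4000
    chrom_length: int = 40_000_000
    fst: float = 0.10
    mean_depth: float = 16.0
    # filters
    max_missing: float = 0.10
    depth_range: tuple[float, float] = (8.0, 100.0)
    maf_min: float = 0.01
    min_sample_depth: float = 8.0
    prune_window_bp: int = 20_000
    prune_r2: float = 0.4
    prune_n: int = 2
    # structure
    k_min: int = 1
    k_max: int = 5
    ancestry_threshold: float = 0.7
    # private alleles
    min_carriers: int = 3
    # diversity
    diversity_min_depth: float = 15.0
    dedup_cutoff: float = 0.15
    # scan
    scan_threshold: float = 10.0
    scan_window: int = 10_000
    scan_min_markers: int = 8
    # stage toggles
    run_scan: bool = True
    run_relatedness: bool = True

    def validate(self) -> None:
        problems = []
        if not 0 < self.maf_min < 0.5:
            problems.append(f"maf_min={self.maf_min} outside (0, 0.5)")
        if not 0 <= self.max_missing <= 1:
            problems.append(f"max_missing={self.max_missing} outside [0, 1]")
        if self.depth_range[0] > self.depth_range[1]:
            problems.append("empty depth_range")
        if not 0 < self.ancestry_threshold <= 1:
            problems.append("ancestry_threshold outside (0, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            problems.append("invalid K range")
        if self.min_carriers < 1:
            problems.append("min_carriers must be >= 1")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed salted with the stage name."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    Result tables are written as TSV under ``cfg.out_dir`` and the
    manifest as ``manifest.json``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}}

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    # --- input ---
    truth = None
    if cfg.input_vcf is None:
        pm = synthetic.PopulationModel(
            n_pops=cfg.n_pops, samples_per_pop=cfg.samples_per_pop,
            n_sites=cfg.n_sites, chrom_length=cfg.chrom_length, fst=cfg.fst,
            seed=stage_seed(cfg.seed, "simulate"),
        )
        truth = synthetic.simulate_haplotypes(pm)
        gm = synthetic.observe(
            truth, synthetic.ObservationModel(mean_depth=cfg.mean_depth),
            seed=stage_seed(cfg.seed, "observe"),
        )
        write_vcf(gm, str(out / "cohort.vcf"))
        synthetic.write_truth_tables(truth, str(out / "truth"))
        meta = pd.DataFrame(
            {"sample": gm.samples,
             "location": [f"loc{p}" for p in truth.pop_labels]}
        )
    else:
        gm = read_vcf(cfg.input_vcf, require_fields=("GT", "DP"))
        meta = pd.DataFrame({"sample": gm.samples, "location": "unknown"})
    record("input", n_samples=gm.n_samples, n_sites=gm.n_sites)

    # --- QC / filtering ---
    gm = qc.filter_samples_by_depth(gm, cfg.min_sample_depth)
    site_cfg = qc.SiteFilterConfig(
        max_missing=cfg.max_missing, depth_range=cfg.depth_range,
        maf_min=cfg.maf_min,
    )
    gm, removal_log = qc.apply_site_filters(gm, site_cfg, return_log=True)
    stats = qc.sample_stats(gm)
    stats.to_csv(out / "sample_stats.tsv", sep="\t", index=False)
    record("qc_filter", n_samples=gm.n_samples, n_sites=gm.n_sites,
           **removal_log)

    pruned = qc.prune_ld(
        gm, qc.PruneConfig(cfg.prune_window_bp, cfg.prune_r2, cfg.prune_n)
    )
    record("prune", n_sites=pruned.n_sites)

    # --- structure ---
    best_k, cv = structure.select_k(
        pruned, range(cfg.k_min, cfg.k_max + 1),
        seed=stage_seed(cfg.seed, "select_k"),
    )
    cv.to_csv(out / "cv_errors.tsv", sep="\t", index=False)
    fit = structure.fit_admixture(
        pruned, best_k, seed=stage_seed(cfg.seed, "admixture")
    )
    pd.DataFrame(fit.Q, index=fit.samples).to_csv(out / "Q.tsv", sep="\t")
    pca = structure.genotype_pca(pruned, n_components=4)
    pd.DataFrame(pca.scores, index=pca.index).to_csv(out / "pca.tsv", sep="\t")
    assignments = structure.assign_groups(
        fit.Q, meta, threshold=cfg.ancestry_threshold, level="sample"
    )
    assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
    record("structure", best_k=best_k,
           n_assigned=int((assignments["group"] != structure.UNASSIGNED).sum()))

    # --- diversity ---
    div = diversity.pi_and_polymorphic(gm, meta,
                                       min_depth=cfg.diversity_min_depth)
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    labels = assignments.set_index("unit")["group"].reindex(gm.samples)
    assigned_mask = (labels != structure.UNASSIGNED).to_numpy()
    fst_value = float("nan")
    if assigned_mask.sum() >= 4 and labels[assigned_mask].nunique() >= 2:
        sub = gm.take_samples(np.flatnonzero(assigned_mask))
        fst_value = diversity.wc_fst(sub, labels[assigned_mask].to_numpy()).theta
    seg, roh_summary = diversity.detect_roh(gm)
    seg.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
    roh_summary.to_csv(out / "roh_summary.tsv", sep="\t", index=False)
    record("diversity", n_locations=len(div), fst=fst_value,
           n_roh_segments=len(seg))

    if cfg.run_relatedness:
        rel = diversity.ritland_relatedness(pruned)
        retained = diversity.dedup_related(rel, cfg.dedup_cutoff)
        rel.to_csv(out / "relatedness.tsv", sep="\t")
        record("relatedness", n_retained_after_dedup=len(retained))

    # --- private alleles ---
    try:
        psets = private.find_private_alleles(
            gm, assignments, min_carriers=cfg.min_carriers
        )
        pd.concat(
            [p.sites.assign(group=g) for g, p in psets.items()],
            ignore_index=True,
        ).to_csv(out / "private_alleles.tsv", sep="\t", index=False)
        counts = private.individual_private_counts(gm, assignments, psets)
        counts.to_csv(out / "private_per_individual.tsv", sep="\t", index=False)
        record("private_alleles",
               **{str(g): int(p.n_private) for g, p in psets.items()})
    except ValueError as exc:
        record("private_alleles", skipped=str(exc))

    # --- selection scan (synthetic runs only: needs phased truth) ---
    if cfg.run_scan and truth is not None:
        labels_arr = truth.pop_labels
        hs = scan.HaplotypeSet(
            truth.haplotypes[np.repeat(labels_arr == 0, 2)],
            truth.positions, truth.chrom,
        )
        scores = scan.ihs(hs)
        scores.to_csv(out / "ihs.tsv", sep="\t", index=False)
        regions = scan.candidate_regions(
            scores, threshold=cfg.scan_threshold,
            window_size=cfg.scan_window,
            min_n_extr_mrk=cfg.scan_min_markers, chrom=truth.chrom,
        )
        regions.to_csv(out / "candidate_regions.tsv", sep="\t", index=False)
        record("scan", n_scored=len(scores), n_regions=len(regions))

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
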