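"""Per-individual statistics, sample/site filters, MAF carrier arithmetic
and LD pruning.

Percent-heterozygous uses *all* genotypes in the denominator, missing
included, so values are standardized against the full variant set.
Site filters follow the resequencing pipeline conventions: biallelic
only, per-site missingness at most 10%, mean depth within [8, 100]x,
and minor allele frequency at least 0.01.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SiteFilterConfig:
    max_missing: float = 0.10
    depth_range: tuple[float, float] = (8.0, 100.0)
    maf_min: float = 0.01
    biallelic: bool = True      # ingestion already guarantees this
    #: MAF denominator: "total" = 2 * n_samples (reproduces the printed
    #: carrier bounds), "observed" = nonmissing allele count
    maf_denominator: str = "total"

    def validate(self) -> None:
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth range is empty")
        if self.maf_denominator not in ("total", "observed"):
            raise ValueError("maf_denominator must be 'total' or 'observed'")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")


@dataclass
class PruneConfig:
    window_bp: int = 20_000
    r2_max: float = 0.4
    max_per_window: int = 2

    def validate(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window span must be positive")
        if not 0.0 < self.r2_max <= 1.0:
            raise ValueError("r2 ceiling must be in (0, 1]")
        if self.max_per_window < 1:
            raise ValueError("max retained per window must be >= 1")


def sample_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample mean depth and genotype-class counts.

    Percent heterozygous = het count / all genotypes (missing included) x 100.
    Mean depth averages over sites with nonmissing depth.
    """
    geno = gm.geno
    n_sites = gm.n_sites
    counts = {
        "n_hom_ref": (geno == 0).sum(axis=1),
        "n_het": (geno == 1).sum(axis=1),
        "n_hom_alt": (geno == 2).sum(axis=1),
        "n_missing": (geno == MISSING).sum(axis=1),
    }
    if gm.depth is not None:
        d = gm.depth.astype(float)
        valid = d >= 0
        if np.issubdtype(gm.depth.dtype, np.floating):
            valid &= ~np.isnan(d)
        with np.errstate(invalid="ignore"):
            mean_depth = np.where(
                valid.sum(axis=1) > 0,
                np.where(valid, d, 0).sum(axis=1) / np.maximum(valid.sum(axis=1), 1),
                math.nan,
            )
    else:
        mean_depth = np.full(gm.n_samples, math.nan)
    pct_het = (
        counts["n_het"] / n_sites * 100.0 if n_sites else np.zeros(gm.n_samples)
    )
    return pd.DataFrame(
        {"sample": gm.samples, "mean_depth": mean_depth, **counts,
         "pct_het": pct_het}
    )


def percent_het(n_het: int, n_total: int, include_missing: bool = True,
                n_missing: int = 0) -> float:
    """Percent heterozygous; denominator includes missing by default."""
    denom = n_total if include_missing else n_total - n_missing
    if denom <= 0:
        return math.nan
    return n_het / denom * 100.0


def filter_samples_by_depth(
    gm: GenotypeMatrix, min_mean_depth: float
) -> GenotypeMatrix:
    """Drop samples whose mean SNP depth is strictly below the threshold."""
    if min_mean_depth <= 0:
        raise ValueError("min_mean_depth must be positive")
    if gm.depth is None:
        raise ValueError("depth matrix required for depth-based sample filter")
    stats = sample_stats(gm)
    keep = np.flatnonzero(stats["mean_depth"].to_numpy() >= min_mean_depth)
    if len(keep) == 0:
        raise ValueError("depth filter would remove every sample")
    removed = sorted(set(gm.samples) - {gm.samples[i] for i in keep})
    if removed:
        logger.info("filter_samples_by_depth(%g): removed %d samples: %s",
                    min_mean_depth, len(removed), removed)
    return gm.take_samples(keep)


def site_maf(gm: GenotypeMatrix, denominator: str = "total") -> np.ndarray:
    """Per-site minor allele frequency.

    ``denominator='total'`` divides ALT (or REF) copies by 2 x n_samples,
    treating missing genotypes as contributing no minor copies —
    the convention under which the printed carrier bounds hold.
    """
    called = gm.called()
    alt = np.where(called, gm.geno, 0).sum(axis=0).astype(float)
    if denominator == "total":
        n_alleles = np.full(gm.n_sites, 2.0 * gm.n_samples)
        ref = n_alleles - alt
    elif denominator == "observed":
        n_alleles = 2.0 * called.sum(axis=0)
        ref = n_alleles - alt
    else:
        raise ValueError("denominator must be 'total' or 'observed'")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def apply_site_filters(
    gm: GenotypeMatrix, cfg: SiteFilterConfig | None = None,
    return_log: bool = False,
):
    """Remove sites failing missingness, mean-depth or MAF criteria.

    Depth bounds are inclusive. Per-criterion removal counts (a site can
    fail several) are logged and optionally returned.
    """
    cfg = cfg or SiteFilterConfig()
    cfg.validate()
    n = gm.n_samples
    miss_frac = (gm.geno == MISSING).sum(axis=0) / n
    fail_miss = miss_frac > cfg.max_missing

    if gm.depth is not None:
        mean_depth = gm.depth.mean(axis=0)
        lo, hi = cfg.depth_range
        fail_depth = (mean_depth < lo) | (mean_depth > hi)
    else:
        fail_depth = np.zeros(gm.n_sites, dtype=bool)

    maf = site_maf(gm, cfg.maf_denominator)
    fail_maf = ~(maf >= cfg.maf_min)   # NaN MAF (all-missing site) fails

    fail = fail_miss | fail_depth | fail_maf
    removal_log = {
        "missingness": int(fail_miss.sum()),
        "mean_depth": int(fail_depth.sum()),
        "maf": int(fail_maf.sum()),
        "total_removed": int(fail.sum()),
    }
    logger.info("apply_site_filters: %s", removal_log)
    out = gm.take_sites(np.flatnonzero(~fail))
    return (out, removal_log) if return_log else out


def maf_carrier_bounds(n_samples: int, maf_min: float = 0.01) -> tuple[int, int]:
    """Smallest heterozygous / homozygous carrier counts that survive a
    MAF filter on a cohort of *n_samples* diploids.

    A heterozygous carrier contributes one minor-allele copy out of 2n; a
    homozygous carrier contributes two. Returns (min het carriers,
    min hom carriers) that reach ``maf_min``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    two_n = 2 * n_samples
    c_het = math.ceil(maf_min * two_n - 1e-12)
    c_hom = math.ceil(maf_min * n_samples - 1e-12)
    return max(c_het, 1), max(c_hom, 1)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, missing cells
    pairwise-excluded. Undefined (monomorphic) pairs return 0."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
    return r * r


def prune_ld(
    gm: GenotypeMatrix, cfg: PruneConfig | None = None
) -> GenotypeMatrix:
    """Greedy LD pruning in sliding physical windows.

    Sites are visited in position order per chromosome. A site is dropped
    if its genotype r² against any already-retained site within
    ``window_bp`` exceeds ``r2_max``, or if ``max_per_window`` sites are
    already retained in that trailing window. Deterministic: ties keep the
    earliest positions.
    """
    cfg = cfg or PruneConfig()
    cfg.validate()
    keep: list[int] = []
    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.positions
    retained: list[int] = []   # indices retained on the current chromosome
    current_chrom = None
    for j in range(gm.n_sites):
        if chroms[j] != current_chrom:
            current_chrom = chroms[j]
            retained = []
        # positions ascend, so older retained sites can be discarded for good
        while retained and pos[j] - pos[retained[0]] > cfg.window_bp:
            retained.pop(0)
        window = retained
        if len(window) >= cfg.max_per_window:
            continue
        if any(_pairwise_r2(gm.geno[:, i], gm.geno[:, j]) > cfg.r2_max
               for i in window):
            continue
        retained.append(j)
        keep.append(j)
    return gm.take_sites(np.array(keep, dtype=int))
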