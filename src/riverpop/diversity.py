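"""Diversity and relatedness statistics: Ritland pairwise relatedness with
relatedness-based deduplication, per-location nucleotide diversity and
polymorphic-locus counts, Weir–Cockerham Fst, PLINK-parameterized
runs-of-homozygosity detection, and mutation-rate scaling.

Conventions worth knowing:

* pi is averaged over the dataset-wide retained SNP set, not genome
  length — sites monomorphic within a location contribute zero.
* The Ritland estimator is allele-frequency weighted and can legitimately
  fall below 0 (unshared markers) or above 1 (shared rare markers).
* ROH detection follows the PLINK sliding-window semantics: 50-SNP
  windows with at most 1 heterozygote and 5 missing calls, per-SNP hit
  fraction threshold 0.05, segments of >= 25 SNPs subject to length,
  density and gap constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix

#: sentinel for an undefined pairwise relatedness (no shared informative loci)
REL_UNDEFINED = np.nan


# ---------------------------------------------------------------------------
# Ritland relatedness and deduplication
# ---------------------------------------------------------------------------

def ritland_relatedness(
    gm: GenotypeMatrix, freqs: np.ndarray | None = None
) -> pd.DataFrame:
    """Pairwise multilocus Ritland (1996) relatedness.

    For a biallelic locus with allele frequencies (p, q) and per-individual
    allele-share fractions S (0, 1/2 or 1 for each allele), the locus
    estimator is ``2 * (Sx_p*Sy_p/p + Sx_q*Sy_q/q - 1)`` and loci are
    weighted equally (the n_alleles - 1 weight is 1 for biallelic SNPs).
    Monomorphic loci are uninformative and skipped; a pair with no shared
    informative loci gets NaN.

    Parameters
    ----------
    freqs : optional
        ALT allele frequency per site; defaults to frequencies estimated
        from the full retained sample set.
    """
    p = gm.alt_freq() if freqs is None else np.asarray(freqs, dtype=float)
    informative = (p > 0) & (p < 1)
    geno = gm.geno[:, informative].astype(float)
    geno[gm.geno[:, informative] == MISSING] = np.nan
    p = p[informative]
    q = 1.0 - p
    s_alt = geno / 2.0          # share of ALT allele per individual
    s_ref = 1.0 - s_alt
    n = gm.n_samples
    out = np.full((n, n), REL_UNDEFINED)
    # per-locus kernel evaluated lazily per pair; vectorized over loci
    for i in range(n):
        xi_alt, xi_ref = s_alt[i], s_ref[i]
        for j in range(i, n):
            ok = ~np.isnan(s_alt[i]) & ~np.isnan(s_alt[j])
            if not ok.any():
                continue
            r_loc = 2.0 * (
                xi_alt[ok] * s_alt[j][ok] / p[ok]
                + xi_ref[ok] * s_ref[j][ok] / q[ok]
                - 1.0
            )
            out[i, j] = out[j, i] = float(r_loc.mean())
    return pd.DataFrame(out, index=gm.samples, columns=gm.samples)


def dedup_related(rel: pd.DataFrame, cutoff: float = 0.15) -> list[str]:
    """Greedy removal of related samples until no pair is >= cutoff.

    Repeatedly drops the sample participating in the most over-cutoff
    pairs (ties broken toward the later sample id), leaving one individual
    per related cluster. Returns the retained sample ids in input order.
    """
    samples = list(rel.index)
    mat = rel.to_numpy(dtype=float).copy()
    np.fill_diagonal(mat, -np.inf)
    alive = np.ones(len(samples), dtype=bool)
    while True:
        over = (mat >= cutoff) & alive[:, None] & alive[None, :]
        if not over.any():
            break
        degree = over.sum(axis=1)
        worst = np.flatnonzero(degree == degree.max())[-1]   # later id on tie
        alive[worst] = False
    return [s for s, a in zip(samples, alive) if a]


# ---------------------------------------------------------------------------
# Nucleotide diversity / polymorphic loci
# ---------------------------------------------------------------------------

def pi_and_polymorphic(
    gm: GenotypeMatrix, meta: pd.DataFrame, min_depth: float | None = 15.0
) -> pd.DataFrame:
    """Per-location pi and polymorphic-locus counts.

    Only samples with mean depth >= ``min_depth`` are used (set None to
    keep all). Per site within a location with m nonmissing alleles and
    ALT frequency p, site pi = (m/(m-1)) * 2p(1-p); the location's pi is
    the mean over the full retained SNP set, so sites monomorphic within
    the location contribute 0. Polymorphic count = sites with 0 < p < 1
    within the location. Locations with < 2 usable samples are flagged.
    """
    from .qc import sample_stats

    if min_depth is not None and gm.depth is not None:
        stats = sample_stats(gm)
        usable = set(stats.loc[stats["mean_depth"] >= min_depth, "sample"])
    else:
        usable = set(gm.samples)
    sample_loc = dict(zip(meta["sample"], meta["location"]))
    rows = []
    for loc in pd.unique(meta["location"]):
        idx = [i for i, s in enumerate(gm.samples)
               if s in usable and sample_loc.get(s) == loc]
        if len(idx) < 2:
            rows.append({"location": loc, "pi": math.nan,
                         "n_polymorphic": 0, "n_samples": len(idx),
                         "ok": False})
            continue
        sub = gm.geno[idx]
        called = sub != MISSING
        m = 2.0 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pfreq = np.where(m > 0, alt / np.maximum(m, 1), np.nan)
            site_pi = np.where(
                m > 1, (m / np.maximum(m - 1, 1)) * 2.0 * pfreq * (1.0 - pfreq), 0.0
            )
        site_pi = np.nan_to_num(site_pi)
        poly = int(((pfreq > 0) & (pfreq < 1)).sum())
        rows.append({"location": loc, "pi": float(site_pi.mean()),
                     "n_polymorphic": poly, "n_samples": len(idx), "ok": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    a: np.ndarray               # per-site among-population variance component
    b: np.ndarray               # among-individual within-population
    c: np.ndarray               # within-individual
    theta_site: np.ndarray      # per-site a/(a+b+c)
    theta: float                # weighted overall: sum(a)/sum(a+b+c)
    n_sites_used: int
    n_sites_skipped: int


def wc_fst(gm: GenotypeMatrix, groups: np.ndarray | list) -> FstResult:
    """Weir & Cockerham (1984) theta from genotypes and group labels.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are computed per site from
    sample sizes, ALT frequencies and heterozygote frequencies of each
    group; the overall estimate is the components-weighted ratio
    sum(a) / sum(a+b+c). Sites with fewer than two called genotypes in
    any group, or monomorphic overall, are skipped and counted.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    r = len(labels)
    if r < 2:
        raise ValueError("wc_fst needs at least 2 groups")
    masks = [groups == g for g in labels]
    if any(m.sum() == 0 for m in masks):
        raise ValueError("empty group")
    called = gm.geno != MISSING
    geno = np.where(called, gm.geno, 0).astype(float)

    n_i = np.stack([called[m].sum(axis=0) for m in masks]).astype(float)  # (r, m)
    alt_i = np.stack([geno[m].sum(axis=0) for m in masks])
    het_i = np.stack([((gm.geno[m] == 1) & called[m]).sum(axis=0)
                      for m in masks]).astype(float)
    usable = (n_i >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / (2.0 * n_i)
        h_i = het_i / n_i

        nbar = n_i.mean(axis=0)
        nsum = n_i.sum(axis=0)
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum

        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1.0)
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0

    poly = (pbar > 0) & (pbar < 1)
    usable &= poly & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a, b, c = (np.where(usable, x, np.nan) for x in (a, b, c))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_site = a / (a + b + c)
    denom = np.nansum(a + b + c)
    theta = float(np.nansum(a) / denom) if denom != 0 else math.nan
    return FstResult(
        a=a, b=b, c=c, theta_site=theta_site, theta=theta,
        n_sites_used=int(usable.sum()),
        n_sites_skipped=int((~usable).sum()),
    )


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

@dataclass
class RohParams:
    """PLINK-style ROH scan parameters. Flags the source pipeline printed
    without values fall back to PLINK 1.9 defaults."""

    min_snp: int = 25               # --homozyg-snp
    min_kb: float = 1000.0          # --homozyg-kb (PLINK default)
    max_kb_per_snp: float = 50.0    # --homozyg-density (PLINK default)
    max_gap_kb: float = 1000.0      # --homozyg-gap (PLINK default)
    window_snp: int = 50            # --homozyg-window-snp
    window_het: int = 1             # --homozyg-window-het
    window_missing: int = 5         # --homozyg-window-missing
    hit_threshold: float = 0.05     # --homozyg-window-threshold


def _roh_one_chrom(
    geno: np.ndarray, pos: np.ndarray, params: RohParams
) -> list[tuple[int, int, int, int]]:
    """Segments on one chromosome for one sample.

    Returns (start_idx, end_idx, n_snps, n_het) site-index tuples."""
    m = len(pos)
    w = params.window_snp
    if m < w:
        return []
    het = (geno == 1).astype(np.int32)
    mis = (geno == MISSING).astype(np.int32)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - w + 1
    starts = np.arange(n_win)
    hom_win = (
        (chet[starts + w] - chet[starts] <= params.window_het)
        & (cmis[starts + w] - cmis[starts] <= params.window_missing)
    )
    # per-SNP: fraction of windows containing it that are "homozygous"
    chom = np.concatenate([[0], np.cumsum(hom_win.astype(np.int64))])
    j = np.arange(m)
    lo = np.maximum(j - w + 1, 0)
    hi = np.minimum(j, n_win - 1)
    total = hi - lo + 1
    hits = chom[hi + 1] - chom[lo]
    included = hits / total >= params.hit_threshold

    segments = []
    start = None
    prev = None
    max_gap = params.max_gap_kb * 1000.0

    def flush(s: int, e: int) -> None:
        n_snps = e - s + 1
        length_kb = (pos[e] - pos[s] + 1) / 1000.0
        if n_snps < params.min_snp or length_kb < params.min_kb:
            return
        if length_kb / n_snps > params.max_kb_per_snp:
            return
        n_het = int(het[s:e + 1].sum())
        segments.append((s, e, n_snps, n_het))

    for idx in np.flatnonzero(included):
        if start is None:
            start = prev = idx
            continue
        if idx == prev + 1 and pos[idx] - pos[prev] <= max_gap:
            prev = idx
            continue
        flush(start, prev)
        start = prev = idx
    if start is not None:
        flush(start, prev)
    return segments


def detect_roh(
    gm: GenotypeMatrix, params: RohParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Runs of homozygosity per sample, PLINK sliding-window style.

    Returns (segment table, per-sample summary with total kb and segment
    count). Chromosomes with fewer SNPs than the window size yield no
    calls there.
    """
    params = params or RohParams()
    pos_all = gm.positions
    if gm.n_sites > 1:
        order_ok = gm.sites.sort_values(["chrom", "pos"], kind="stable").index
        if not (order_ok == np.arange(gm.n_sites)).all():
            raise ValueError("sites must be sorted by (chrom, pos)")
    rows = []
    chrom_col = gm.sites["chrom"].to_numpy()
    for chrom in pd.unique(chrom_col):
        sel = np.flatnonzero(chrom_col == chrom)
        pos = pos_all[sel]
        for i, sample in enumerate(gm.samples):
            for s, e, n_snps, n_het in _roh_one_chrom(gm.geno[i, sel], pos, params):
                rows.append(
                    {"sample": sample, "chrom": chrom,
                     "start": int(pos[s]), "end": int(pos[e]),
                     "n_snps": n_snps, "n_het": n_het,
                     "length_kb": (pos[e] - pos[s] + 1) / 1000.0}
                )
    seg = pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snps", "n_het",
                       "length_kb"]
    )
    summary = (
        seg.groupby("sample")
        .agg(total_kb=("length_kb", "sum"), n_segments=("chrom", "size"))
        .reindex(gm.samples, fill_value=0)
        .reset_index()
        .rename(columns={"index": "sample"})
    )
    summary["total_kb"] = summary["total_kb"].astype(float)
    return seg, summary


# ---------------------------------------------------------------------------
# Mutation-rate scaling
# ---------------------------------------------------------------------------

def scale_mutation_rate(base_rate: float, snp_ratio: float) -> float:
    """Scale a mutation rate by a cross-species SNP-count ratio, rounded
    to 2 significant figures."""
    if base_rate <= 0 or snp_ratio <= 0:
        raise ValueError("base_rate and snp_ratio must be positive")
    x = base_rate * snp_ratio
    ndigits = 1 - int(math.floor(math.log10(abs(x))))
    return round(x, ndigits)
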