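"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles — plain loops and direct
definitions — deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


def ehh_pair_enumeration(haplotypes, positions, focal, allele, stop=0.05):
    """EHH curve by exhaustive enumeration of carrier haplotype pairs.

    Returns {position: ehh} for the focal site and every site reached
    before EHH drops below *stop*, on both sides.
    """
    hap = np.asarray(haplotypes)
    carriers = [i for i in range(hap.shape[0]) if hap[i, focal] == allele]
    if len(carriers) < 2:
        return None
    out = {int(positions[focal]): 1.0}
    pairs = list(itertools.combinations(carriers, 2))
    for step in (-1, 1):
        j = focal + step
        while 0 <= j < hap.shape[1]:
            lo, hi = (j, focal) if step < 0 else (focal, j)
            same = sum(
                1 for a, b in pairs
                if np.array_equal(hap[a, lo:hi + 1], hap[b, lo:hi + 1])
            )
            e = same / len(pairs)
            if e < stop:
                break
            out[int(positions[j])] = e
            if e == 0.0:
                break
            j += step
    return out


def roh_reference_scanner(geno, pos, *, window_snp=50, window_het=1,
                          window_missing=5, hit_threshold=0.05, min_snp=25,
                          min_kb=1000.0, max_kb_per_snp=50.0,
                          max_gap_kb=1000.0):
    """PLINK-style ROH segments for one sample on one chromosome, written
    as explicit loops over windows and SNPs. Returns (start_bp, end_bp,
    n_snps) tuples."""
    m = len(pos)
    if m < window_snp:
        return []
    hom_windows = []
    for s in range(m - window_snp + 1):
        window = geno[s:s + window_snp]
        n_het = sum(1 for g in window if g == 1)
        n_mis = sum(1 for g in window if g == MISSING)
        hom_windows.append(n_het <= window_het and n_mis <= window_missing)
    included = []
    for j in range(m):
        hits = total = 0
        for s in range(max(0, j - window_snp + 1),
                       min(j, m - window_snp) + 1):
            total += 1
            if hom_windows[s]:
                hits += 1
        included.append(total > 0 and hits / total >= hit_threshold)
    segments = []
    run = []
    for j in range(m):
        if included[j]:
            if run and (j != run[-1] + 1
                        or pos[j] - pos[run[-1]] > max_gap_kb * 1000):
                segments.append(run)
                run = []
            run.append(j)
        elif run:
            segments.append(run)
            run = []
    if run:
        segments.append(run)
    out = []
    for run in segments:
        n_snps = len(run)
        length_kb = (pos[run[-1]] - pos[run[0]] + 1) / 1000
        if (n_snps >= min_snp and length_kb >= min_kb
                and length_kb / n_snps <= max_kb_per_snp):
            out.append((int(pos[run[0]]), int(pos[run[-1]]), n_snps))
    return out


def wc_theta_direct(genotype_groups):
    """Weir & Cockerham (1984) theta for one biallelic site, computed
    scalar-by-scalar from the printed variance-component formulas.

    *genotype_groups*: list of lists of diploid ALT dosages per group.
    """
    r = len(genotype_groups)
    n = [len(g) for g in genotype_groups]
    p = [sum(g) / (2 * len(g)) for g in genotype_groups]
    h = [sum(1 for x in g if x == 1) / len(g) for g in genotype_groups]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c, a / (a + b + c)


def min_carriers_enumeration(n_samples, maf_min):
    """Smallest het / hom carrier counts reaching maf_min, by enumeration."""
    c_het = next(c for c in range(1, 2 * n_samples + 1)
                 if c / (2 * n_samples) >= maf_min - 1e-12)
    c_hom = next(c for c in range(1, n_samples + 1)
                 if 2 * c / (2 * n_samples) >= maf_min - 1e-12)
    return c_het, c_hom
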