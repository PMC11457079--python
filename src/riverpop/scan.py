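"""Extended-haplotype selection statistics on phased data.

EHH(x) for a focal allele is the probability that two distinct carrier
haplotypes are identical over every site between the focal SNP and x; it
is 1 at the focal SNP and non-increasing outward, and the walk stops once
it drops below a cutoff (0.05). iHH integrates the curve over physical
distance (trapezoid) on each side. The within-group statistic iHS is the
frequency-bin-standardized log-ratio of major- vs minor-allele iHH
(unpolarized convention: no ancestral allele is assumed); the between-
group statistic Rsb is the standardized log-ratio of site-integrated
haplotype homozygosity (iES) between two groups. Candidate regions are
fixed windows containing enough markers with extreme -log10 p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

EHH_STOP = 0.05


@dataclass
class HaplotypeSet:
    """Phased haplotypes (2N x sites, entries 0/1) for one group."""

    haplotypes: np.ndarray
    positions: np.ndarray
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("positions length must equal number of sites")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("haplotype entries must be 0/1")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class EHHCurve:
    """One-sided walks from the focal site: (positions, ehh) left and right,
    both including the focal point with EHH = 1."""

    focal_pos: int
    left_pos: np.ndarray
    left_ehh: np.ndarray
    right_pos: np.ndarray
    right_ehh: np.ndarray


def _homozygosity(groups: np.ndarray) -> float:
    """Probability two random distinct haplotypes share the same group id."""
    n = len(groups)
    if n < 2:
        return math.nan
    _, counts = np.unique(groups, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _walk(hap: np.ndarray, pos: np.ndarray, focal: int, step: int,
          stop: float) -> tuple[np.ndarray, np.ndarray]:
    """Extend haplotype prefixes site by site in one direction, recording
    EHH until it falls below *stop* (below-stop point excluded)."""
    n, m = hap.shape
    out_pos = [pos[focal]]
    out_ehh = [1.0]
    groups = np.zeros(n, dtype=np.int64)
    j = focal + step
    while 0 <= j < m:
        pair = groups * 2 + hap[:, j]
        _, groups = np.unique(pair, return_inverse=True)
        e = _homozygosity(groups)
        if e < stop:
            break
        out_pos.append(pos[j])
        out_ehh.append(e)
        if e == 0.0:
            break
        j += step
    return np.array(out_pos), np.array(out_ehh)


def ehh(hs: HaplotypeSet, focal: int, allele: int,
        stop: float = EHH_STOP) -> EHHCurve | None:
    """EHH curve for one allele at one focal site; None if < 2 carriers."""
    carriers = hs.haplotypes[:, focal] == allele
    if carriers.sum() < 2:
        return None
    hap = hs.haplotypes[carriers]
    lp, le = _walk(hap, hs.positions, focal, -1, stop)
    rp, re = _walk(hap, hs.positions, focal, +1, stop)
    return EHHCurve(focal_pos=int(hs.positions[focal]),
                    left_pos=lp, left_ehh=le, right_pos=rp, right_ehh=re)


def ihh(curve: EHHCurve) -> float:
    """Integrated EHH: trapezoid area over physical distance, both sides."""
    total = 0.0
    for pos, vals in ((curve.left_pos, curve.left_ehh),
                      (curve.right_pos, curve.right_ehh)):
        if len(pos) > 1:
            d = np.abs(np.diff(pos.astype(float)))
            total += float(np.sum(d * (vals[:-1] + vals[1:]) / 2.0))
    return total


def _ehhs_walk(hap: np.ndarray, pos: np.ndarray, focal: int, step: int,
               stop: float) -> tuple[np.ndarray, np.ndarray]:
    """Site-EHHS walk: homozygosity of ALL haplotypes over the growing
    interval, normalized to 1 at the focal site (Tang convention)."""
    n, m = hap.shape
    groups = hap[:, focal].astype(np.int64)
    h0 = _homozygosity(groups)
    out_pos = [pos[focal]]
    out_vals = [1.0]
    if h0 == 0 or math.isnan(h0):
        return np.array(out_pos), np.array(out_vals)
    j = focal + step
    while 0 <= j < m:
        pair = groups * 2 + hap[:, j]
        _, groups = np.unique(pair, return_inverse=True)
        e = _homozygosity(groups) / h0
        if e < stop:
            break
        out_pos.append(pos[j])
        out_vals.append(e)
        if e == 0.0:
            break
        j += step
    return np.array(out_pos), np.array(out_vals)


def ies(hs: HaplotypeSet, focal: int, stop: float = EHH_STOP) -> float:
    """Site-integrated EHHS over both alleles and all haplotypes."""
    lp, le = _ehhs_walk(hs.haplotypes, hs.positions, focal, -1, stop)
    rp, re = _ehhs_walk(hs.haplotypes, hs.positions, focal, +1, stop)
    curve = EHHCurve(int(hs.positions[focal]), lp, le, rp, re)
    return ihh(curve)


def _two_sided_neglog10_p(z: np.ndarray) -> np.ndarray:
    # -log10 of the two-sided standard-normal p, stable for large |z|
    logp = sps.norm.logsf(np.abs(z)) + math.log(2.0)
    return np.clip(-logp / math.log(10.0), 0.0, None)


def ihs(
    hs: HaplotypeSet, min_maf: float = 0.05, bin_width: float = 0.025,
    stop: float = EHH_STOP,
) -> pd.DataFrame:
    """Unpolarized iHS scan over all sites above *min_maf*.

    Raw score = ln(iHH_major / iHH_minor); standardized to mean 0, sd 1
    within minor-allele-frequency bins of width *bin_width*. Sites in a
    bin with fewer than 2 scores keep their raw value and are flagged
    unstandardized.
    """
    freqs = hs.freq()
    maf = np.minimum(freqs, 1.0 - freqs)
    rows = []
    for j in range(hs.n_sites):
        if maf[j] < min_maf:
            continue
        minor = 1 if freqs[j] <= 0.5 else 0
        major = 1 - minor
        c_major = ehh(hs, j, major, stop)
        c_minor = ehh(hs, j, minor, stop)
        if c_major is None or c_minor is None:
            continue
        ihh_major, ihh_minor = ihh(c_major), ihh(c_minor)
        if ihh_major <= 0 or ihh_minor <= 0:
            continue
        rows.append({"site": j, "pos": int(hs.positions[j]),
                     "maf": float(maf[j]),
                     "raw": math.log(ihh_major / ihh_minor)})
    df = pd.DataFrame(rows, columns=["site", "pos", "maf", "raw"])
    if df.empty:
        df["ihs"] = df["neglog10_p"] = df["standardized"] = []
        return df
    bins = (df["maf"] / bin_width).astype(int)
    df["ihs"] = np.nan
    df["standardized"] = False
    for b, idx in df.groupby(bins).groups.items():
        vals = df.loc[idx, "raw"]
        sd = vals.std(ddof=0)
        if len(idx) >= 2 and sd > 0:
            df.loc[idx, "ihs"] = (vals - vals.mean()) / sd
            df.loc[idx, "standardized"] = True
        else:
            df.loc[idx, "ihs"] = vals
    df["neglog10_p"] = _two_sided_neglog10_p(df["ihs"].to_numpy())
    return df.reset_index(drop=True)


def rsb(
    hs_a: HaplotypeSet, hs_b: HaplotypeSet, stop: float = EHH_STOP,
) -> pd.DataFrame:
    """Between-group Rsb scan on the shared site set.

    Raw score = ln(iES_a / iES_b) per site; standardized by subtracting
    the median and dividing by the standard deviation of raw scores.
    Positive values indicate longer haplotype homozygosity in group a.
    """
    if hs_a.n_sites != hs_b.n_sites or not np.array_equal(
        hs_a.positions, hs_b.positions
    ):
        shared, ia, ib = np.intersect1d(
            hs_a.positions, hs_b.positions, return_indices=True
        )
        hs_a = HaplotypeSet(hs_a.haplotypes[:, ia], shared, hs_a.chrom)
        hs_b = HaplotypeSet(hs_b.haplotypes[:, ib], shared, hs_b.chrom)
    rows = []
    for j in range(hs_a.n_sites):
        ies_a = ies(hs_a, j, stop)
        ies_b = ies(hs_b, j, stop)
        if ies_a <= 0 or ies_b <= 0:
            continue
        rows.append({"site": j, "pos": int(hs_a.positions[j]),
                     "raw": math.log(ies_a / ies_b)})
    df = pd.DataFrame(rows, columns=["site", "pos", "raw"])
    if df.empty:
        df["rsb"] = df["neglog10_p"] = []
        return df
    sd = df["raw"].std(ddof=0)
    df["rsb"] = (df["raw"] - df["raw"].median()) / sd if sd > 0 else 0.0
    df["neglog10_p"] = _two_sided_neglog10_p(df["rsb"].to_numpy())
    return df


def candidate_regions(
    scores: pd.DataFrame,
    threshold: float = 10.0,
    window_size: int = 10_000,
    min_n_extr_mrk: int = 8,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Fixed-window candidate-region calling with adjacent-window merging.

    A window [k*W+1, (k+1)*W] is a candidate iff it contains at least
    ``min_n_extr_mrk`` markers with -log10 p >= threshold; adjacent
    candidate windows merge into one region.
    """
    if scores.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_markers",
                                     "n_extreme", "max_neglog10_p"])
    pos = scores["pos"].to_numpy()
    nlp = scores["neglog10_p"].to_numpy()
    win = (pos - 1) // window_size
    cand = []
    for k in np.unique(win):
        inwin = win == k
        n_ext = int((nlp[inwin] >= threshold).sum())
        if n_ext >= min_n_extr_mrk:
            cand.append((int(k), int(inwin.sum()), n_ext,
                         float(nlp[inwin].max())))
    regions = []
    for k, n_mark, n_ext, mx in cand:
        start = k * window_size + 1
        end = (k + 1) * window_size
        if regions and regions[-1]["end"] + 1 == start:
            regions[-1]["end"] = end
            regions[-1]["n_markers"] += n_mark
            regions[-1]["n_extreme"] += n_ext
            regions[-1]["max_neglog10_p"] = max(regions[-1]["max_neglog10_p"], mx)
        else:
            regions.append({"chrom": chrom, "start": start, "end": end,
                            "n_markers": n_mark, "n_extreme": n_ext,
                            "max_neglog10_p": mx})
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_markers",
                                          "n_extreme", "max_neglog10_p"])


def bonferroni_log10(alpha: float, n_tests: int) -> float:
    """-log10 of the Bonferroni-corrected p-value threshold."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return -math.log10(alpha / n_tests)


def cross_species_overlap(
    tables: dict[str, pd.DataFrame], window_size: int = 10_000,
) -> pd.DataFrame:
    """Joint extreme windows across species on shared coordinates.

    Per window, each species contributes its maximum -log10 p; the joint
    score is the minimum of those maxima, so a window only ranks high when
    every species has a strong signal there. Windows missing from any
    species are excluded. Sorted by joint score, descending.
    """
    per_species = {}
    for name, df in tables.items():
        if df.empty:
            return pd.DataFrame(columns=["window_start", "window_end",
                                         "joint_score"] + list(tables))
        win = ((df["pos"].to_numpy() - 1) // window_size)
        agg = pd.Series(df["neglog10_p"].to_numpy()).groupby(win).max()
        per_species[name] = agg
    joined = pd.DataFrame(per_species).dropna()
    if joined.empty:
        return pd.DataFrame(columns=["window_start", "window_end",
                                     "joint_score"] + list(tables))
    out = pd.DataFrame(
        {"window_start": joined.index.to_numpy() * window_size + 1,
         "window_end": (joined.index.to_numpy() + 1) * window_size,
         "joint_score": joined.min(axis=1).to_numpy()}
    )
    for name in tables:
        out[name] = joined[name].to_numpy()
    return out.sort_values("joint_score", ascending=False).reset_index(drop=True)
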