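"""Group-private alleles and per-individual private-allele counts.

An allele (REF or ALT) is private to an admixture group when every
observed carrier — any sample with at least one copy — belongs to that
group, and there are at least ``min_carriers`` of them. Samples whose
maximum ancestry fell below the assignment threshold are excluded
entirely. Missing genotypes never count as carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix
from .structure import UNASSIGNED


@dataclass
class PrivateAlleleSet:
    group: str
    #: rows: site_index, chrom, pos, allele ("ref"/"alt"), n_carriers
    sites: pd.DataFrame
    n_private: int = 0
    pct_of_snps: float = 0.0


def _carrier_matrix(gm: GenotypeMatrix, allele: str) -> np.ndarray:
    if allele == "alt":
        return (gm.geno == 1) | (gm.geno == 2)
    if allele == "ref":
        return (gm.geno == 0) | (gm.geno == 1)
    raise ValueError(allele)


def find_private_alleles(
    gm: GenotypeMatrix,
    assignments: pd.DataFrame,
    min_carriers: int = 3,
) -> dict[str, PrivateAlleleSet]:
    """Identify alleles unique to each admixture group.

    *assignments* is the sample-level table from
    :func:`riverpop.structure.assign_groups`; UNASSIGNED samples are
    dropped before carrier counting.
    """
    assign = dict(zip(assignments["unit"], assignments["group"]))
    keep_idx = [i for i, s in enumerate(gm.samples)
                if assign.get(s, UNASSIGNED) != UNASSIGNED]
    sub = gm.take_samples(keep_idx)
    labels = np.array([assign[s] for s in sub.samples])
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("private-allele analysis needs >= 2 assigned groups")

    result: dict[str, PrivateAlleleSet] = {
        g: PrivateAlleleSet(group=g, sites=None) for g in groups
    }
    frames: dict[str, list] = {g: [] for g in groups}
    for allele in ("alt", "ref"):
        carrier = _carrier_matrix(sub, allele)
        counts = np.stack([carrier[labels == g].sum(axis=0) for g in groups])
        total = counts.sum(axis=0)
        for gi, g in enumerate(groups):
            private = (counts[gi] == total) & (counts[gi] >= min_carriers) \
                      & (total > 0)
            for j in np.flatnonzero(private):
                frames[g].append(
                    {"site_index": int(j),
                     "chrom": sub.sites.iloc[j]["chrom"],
                     "pos": int(sub.sites.iloc[j]["pos"]),
                     "allele": allele,
                     "n_carriers": int(counts[gi, j])}
                )
    n_snps = gm.n_sites
    for g in groups:
        df = pd.DataFrame(
            frames[g],
            columns=["site_index", "chrom", "pos", "allele", "n_carriers"],
        )
        result[g] = PrivateAlleleSet(
            group=g, sites=df, n_private=len(df),
            pct_of_snps=100.0 * len(df) / n_snps if n_snps else 0.0,
        )
    return result


def individual_private_counts(
    gm: GenotypeMatrix,
    assignments: pd.DataFrame,
    private_sets: dict[str, PrivateAlleleSet],
) -> pd.DataFrame:
    """Per-sample count of its own group's private alleles it carries.

    Carrying means >= 1 copy of the private allele at that site; samples
    with all-missing genotypes count zero.
    """
    assign = dict(zip(assignments["unit"], assignments["group"]))
    rows = []
    sample_index = {s: i for i, s in enumerate(gm.samples)}
    for g, pset in private_sets.items():
        members = [s for s in gm.samples if assign.get(s) == g]
        alt_sites = pset.sites.loc[pset.sites["allele"] == "alt", ["chrom", "pos"]]
        ref_sites = pset.sites.loc[pset.sites["allele"] == "ref", ["chrom", "pos"]]
        key = gm.sites.set_index(["chrom", "pos"]).index
        alt_j = np.flatnonzero(key.isin(list(alt_sites.itertuples(index=False))))
        ref_j = np.flatnonzero(key.isin(list(ref_sites.itertuples(index=False))))
        for s in members:
            i = sample_index[s]
            n = int((_carrier_row(gm.geno[i, alt_j], "alt")).sum()) \
                + int((_carrier_row(gm.geno[i, ref_j], "ref")).sum())
            rows.append({"sample": s, "group": g, "n_private_carried": n})
    return pd.DataFrame(rows, columns=["sample", "group", "n_private_carried"])


def _carrier_row(geno_row: np.ndarray, allele: str) -> np.ndarray:
    if allele == "alt":
        return (geno_row == 1) | (geno_row == 2)
    return (geno_row == 0) | (geno_row == 1)
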