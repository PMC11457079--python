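"""Core in-memory containers for the resequencing analysis pipeline.

The central object is :class:`GenotypeMatrix`: a samples x biallelic-SNP
matrix of ALT-allele counts with per-cell read depth and per-site quality.
Genotypes are coded 0/1/2 (count of ALT alleles); missing calls use the
distinct sentinel :data:`MISSING` and are never conflated with 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel genotype code for a missing (or half-) call.
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]


@dataclass(frozen=True)
class VariantSite:
    """A single biallelic SNP.

    Positions are 1-based (VCF convention); exactly one ALT allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """Samples x sites genotype matrix with depth and site metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample ids.
    sites : pandas.DataFrame
        One row per site with columns chrom, pos, ref, alt, qual,
        sorted by (chrom, pos).
    geno : ndarray of int8, shape (n_samples, n_sites)
        ALT-allele counts in {0, 1, 2} or MISSING.
    depth : ndarray of int32, shape (n_samples, n_sites) or None
        Per-cell read depth (nonnegative).
    haplotypes : ndarray of int8, shape (2*n_samples, n_sites) or None
        Phased view, present only when every GT in the source was phased.
        Row 2i / 2i+1 are the two haplotypes of sample i.
    """

    samples: list[str]
    sites: pd.DataFrame
    geno: np.ndarray
    depth: np.ndarray | None = None
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n, m = len(self.samples), len(self.sites)
        if self.geno.shape != (n, m):
            raise ValueError(
                f"geno shape {self.geno.shape} != (samples, sites) = ({n}, {m})"
            )
        if self.depth is not None and self.depth.shape != (n, m):
            raise ValueError("depth shape does not match geno")
        if self.haplotypes is not None and self.haplotypes.shape != (2 * n, m):
            raise ValueError("haplotypes shape must be (2*n_samples, n_sites)")
        missing = list(set(SITE_COLUMNS) - set(self.sites.columns))
        if missing:
            raise ValueError(f"sites table missing columns: {missing}")
        if m > 1:
            order = self.sites.sort_values(["chrom", "pos"], kind="stable")
            if not (order.index == np.arange(m)).all():
                raise ValueError("sites must be sorted by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    def site(self, j: int) -> VariantSite:
        row = self.sites.iloc[j]
        return VariantSite(row["chrom"], int(row["pos"]), row["ref"], row["alt"],
                           float(row["qual"]))

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype cells."""
        return self.geno != MISSING

    def alt_freq(self) -> np.ndarray:
        """Per-site ALT allele frequency from non-missing genotypes.

        Sites with no called genotypes yield NaN.
        """
        called = self.called()
        alt = np.where(called, self.geno, 0).sum(axis=0)
        n_alleles = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def take_samples(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        hap = None
        if self.haplotypes is not None:
            hidx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
            hap = self.haplotypes[hidx]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites.copy(),
            geno=self.geno[idx],
            depth=None if self.depth is None else self.depth[idx],
            haplotypes=hap,
        )

    def take_sites(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            geno=self.geno[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
        )


@dataclass
class SampleMeta:
    """Per-sample metadata: id, sampling location, optional group and study."""

    sample: str
    location: str
    group: str | None = None
    study: str | None = None


def meta_table(rows: list[SampleMeta]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample": [r.sample for r in rows],
            "location": [r.location for r in rows],
            "group": [r.group for r in rows],
            "study": [r.study for r in rows],
        }
    )
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id in metadata: {dup}")
    return df


@dataclass
class AlignmentRecord:
    """One pairwise local alignment (12-column tabular, outfmt-6 style).

    Coordinates are normalized to ascending 1-based inclusive intervals on
    both sequences; a subject interval given descending in the source file
    is flipped and flagged ``strand == '-'``.
    """

    query: str
    subject: str
    pct_identity: float
    length: int
    mismatches: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def is_self_hit(self) -> bool:
        return (
            self.query == self.subject
            and self.strand == "+"
            and self.qstart == self.sstart
            and self.qend == self.send
        )
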