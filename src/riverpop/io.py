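"""Readers and writers for VCF, tabular alignments and metadata, plus window QC.

VCF ingestion keeps only biallelic SNP rows (multi-allelic rows and indels
are dropped and counted), encodes genotypes as ALT-allele counts with a
missing sentinel, and retains a phased-haplotype view when every genotype
in the file is phased.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import MISSING, AlignmentRecord, GenotypeMatrix

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass
class VcfIngestLog:
    """Counts of rows dropped during VCF ingestion, by reason."""

    multiallelic: int = 0
    indel_or_other: int = 0

    @property
    def dropped(self) -> int:
        return self.multiallelic + self.indel_or_other


def read_vcf(
    path: str,
    require_fields: tuple[str, ...] = ("GT",),
    return_log: bool = False,
) -> GenotypeMatrix | tuple[GenotypeMatrix, VcfIngestLog]:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str
        VCF 4.x file (plain or bgzipped). GT is mandatory; include
        ``"DP"`` in *require_fields* to require per-genotype depth.
    require_fields : tuple of str
        Fields that must be present; missing DP raises when required,
        otherwise the depth matrix is None.
    return_log : bool
        Also return the per-reason drop counts.

    Notes
    -----
    Only biallelic SNPs survive: rows with zero or more than one ALT
    allele, or with any non-single-base allele, are dropped and counted.
    Half-calls (``./1``) become missing. Non-diploid genotypes raise.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    want_dp = "DP" in require_fields

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    geno_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    log = VcfIngestLog()
    all_phased = True

    for var in vcf:
        if len(var.ALT) != 1:
            log.multiallelic += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if ref not in _BASES or alt not in _BASES:
            log.indel_or_other += 1
            continue
        gts = var.genotype.array()  # (n, ploidy+1); last column = phased flag
        if gts.shape[1] != 3:
            raise ValueError(
                f"{path}: non-diploid genotype at {var.CHROM}:{var.POS}"
            )
        a, b = gts[:, 0], gts[:, 1]
        row = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        phased = gts[:, 2].astype(bool)
        if not phased.all():
            all_phased = False
        if want_dp:
            dp = var.format("DP")
            if dp is None:
                raise ValueError(
                    f"{path}: DP required but absent at {var.CHROM}:{var.POS}"
                )
            depth_rows.append(np.maximum(dp[:, 0], 0).astype(np.int32))
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(ref)
        alts.append(alt)
        quals.append(var.QUAL if var.QUAL is not None else math.nan)
        geno_rows.append(row)
        hap_rows.append(np.stack([a, b], axis=1).astype(np.int8))

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "qual": quals}
    )
    geno = (
        np.array(geno_rows, dtype=np.int8).T
        if geno_rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depth = np.array(depth_rows, dtype=np.int32).T if want_dp and depth_rows else None
    haplotypes = None
    if all_phased and hap_rows:
        # (sites, n, 2) -> (2n, sites)
        h = np.stack(hap_rows)  # (m, n, 2)
        haplotypes = h.transpose(1, 2, 0).reshape(2 * len(samples), -1)
        if (haplotypes < 0).any():
            haplotypes = None  # missing calls: no usable phased view
    if log.dropped:
        logger.info("read_vcf: dropped %d rows (%d multi-allelic, %d indel/other)",
                    log.dropped, log.multiallelic, log.indel_or_other)
    gm = GenotypeMatrix(samples=samples, sites=sites, geno=geno, depth=depth,
                        haplotypes=haplotypes)
    return (gm, log) if return_log else gm


def write_vcf(gm: GenotypeMatrix, path: str, phased: bool = False) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file with GT[:DP]."""
    has_dp = gm.depth is not None
    fmt = "GT:DP" if has_dp else "GT"
    sep = "|" if phased else "/"
    if phased and gm.haplotypes is None:
        raise ValueError("phased output requested but no haplotype view present")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in gm.sites["chrom"].unique():
            end = int(gm.sites.loc[gm.sites["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={end + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            qual = "." if math.isnan(row["qual"]) else f"{row['qual']:g}"
            cells = []
            for i in range(gm.n_samples):
                g = gm.geno[i, j]
                if phased:
                    a, b = gm.haplotypes[2 * i, j], gm.haplotypes[2 * i + 1, j]
                    gt = f"{a}{sep}{b}" if g != MISSING else f".{sep}."
                elif g == MISSING:
                    gt = f".{sep}."
                else:
                    gt = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}[int(g)]
                if has_dp:
                    gt = f"{gt}:{int(gm.depth[i, j])}"
                cells.append(gt)
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def window_qc(gm: GenotypeMatrix, window_size: int = 100_000) -> pd.DataFrame:
    """Count variants and average their QUAL in fixed windows per chromosome.

    Windows are 1-based inclusive ``[k*W + 1, (k+1)*W]`` anchored at
    position 1, covering ``[1, max pos]`` of each chromosome; empty windows
    spanned by the data get count 0 and NaN mean QUAL.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        qual = sub["qual"].to_numpy()
        n_win = int((pos.max() - 1) // window_size) + 1 if len(pos) else 0
        win_idx = (pos - 1) // window_size
        for k in range(n_win):
            mask = win_idx == k
            count = int(mask.sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": k * window_size + 1,
                    "end": (k + 1) * window_size,
                    "count": count,
                    "mean_qual": float(np.nanmean(qual[mask])) if count else math.nan,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "mean_qual"])


def read_alignment_table(path: str, min_identity: float = 0.0) -> list[AlignmentRecord]:
    """Parse 12-column tabular pairwise alignments (BLAST outfmt-6 style).

    Subject intervals listed descending (sstart > send) indicate a minus-
    strand hit; coordinates are normalized to ascending with a strand flag.
    Records below *min_identity* percent identity are skipped.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            (query, subject, ident, length, mism, gapo,
             qstart, qend, sstart, send, evalue, bits) = parts
            ident = float(ident)
            if not 0.0 <= ident <= 100.0:
                raise ValueError(
                    f"{path}:{lineno}: percent identity {ident} outside [0, 100]"
                )
            qstart, qend = int(qstart), int(qend)
            sstart, send = int(sstart), int(send)
            strand = "+"
            if sstart > send:
                strand = "-"
                sstart, send = send, sstart
            if qstart > qend:
                raise ValueError(f"{path}:{lineno}: query interval reversed")
            if ident < min_identity:
                continue
            records.append(
                AlignmentRecord(
                    query=query, subject=subject, pct_identity=ident,
                    length=int(length), mismatches=int(mism), gapopen=int(gapo),
                    qstart=qstart, qend=qend, sstart=sstart, send=send,
                    evalue=float(evalue), bitscore=float(bits), strand=strand,
                )
            )
    return records


def read_metadata(path: str) -> pd.DataFrame:
    """Read a sample metadata TSV with at least `sample` and `location`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "location"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata missing required column '{col}'")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    for col in ("group", "study"):
        if col not in df.columns:
            df[col] = None
    return df
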