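"""Cross-assembly variant mapping: chain co-linear pairwise alignments
(homeolog discovery, lift-over scaffolding) and lift variant coordinates
and alleles onto a new assembly.

Chaining is greedy per (query, subject, strand): alignments sorted by
query start are extended while both axes stay monotone and the start gap
on each axis is at most ``gap``; chains spanning at least ``min_len`` on
the query are emitted and trivial self-hits are discarded.

Lift-over extracts a flanking sequence window around each variant, finds
its unique best placement on the target assembly (edit-distance search on
both strands), and reconciles alleles: identity, strand-complement, or a
recorded REF/ALT swap. Variants without a confidently unique, allele-
consistent placement are reported unmapped with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .datamodel import AlignmentRecord, GenotypeMatrix
from .io import write_vcf

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AlignmentChain:
    query: str
    subject: str
    strand: str
    members: list[AlignmentRecord]

    @property
    def query_span(self) -> tuple[int, int]:
        return self.members[0].qstart, self.members[-1].qend

    @property
    def subject_span(self) -> tuple[int, int]:
        lo = min(m.sstart for m in self.members)
        hi = max(m.send for m in self.members)
        return lo, hi

    @property
    def query_length(self) -> int:
        s, e = self.query_span
        return e - s + 1

    @property
    def aligned_length(self) -> int:
        return sum(m.length for m in self.members)


def chain_linear(
    alignments: list[AlignmentRecord],
    gap: int = 100_000,
    min_len: int = 10_000,
) -> list[AlignmentChain]:
    """Greedily chain co-linear alignments into blocks.

    Emits chains whose query span is at least ``min_len``. Full self-hits
    (a sequence aligned to itself at identical coordinates) are dropped
    before chaining.
    """
    usable = [a for a in alignments if not a.is_self_hit()]
    chains: list[AlignmentChain] = []
    keyed: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for a in usable:
        keyed.setdefault((a.query, a.subject, a.strand), []).append(a)
    for (q, s, strand), recs in keyed.items():
        recs = sorted(recs, key=lambda r: (r.qstart, r.qend))
        current: list[AlignmentRecord] = []
        for rec in recs:
            if not current:
                current = [rec]
                continue
            prev = current[-1]
            q_gap = rec.qstart - prev.qend
            if strand == "+":
                s_monotone = rec.sstart > prev.sstart and rec.send > prev.send
                s_gap = rec.sstart - prev.send
            else:
                # minus strand: subject runs backwards as query advances
                s_monotone = rec.sstart < prev.sstart and rec.send < prev.send
                s_gap = prev.sstart - rec.send
            if rec.qstart > prev.qstart and s_monotone \
                    and 0 <= q_gap <= gap and s_gap <= gap:
                current.append(rec)
            else:
                chains.append(AlignmentChain(q, s, strand, current))
                current = [rec]
        if current:
            chains.append(AlignmentChain(q, s, strand, current))
    return [c for c in chains if c.query_length >= min_len]


def chain_table(chains: list[AlignmentChain]) -> pd.DataFrame:
    rows = []
    for c in chains:
        qs, qe = c.query_span
        ss, se = c.subject_span
        rows.append(
            {"query": c.query, "q_start": qs, "q_end": qe,
             "subject": c.subject, "s_start": ss, "s_end": se,
             "strand": c.strand, "n_members": len(c.members),
             "aligned_length": c.aligned_length}
        )
    return pd.DataFrame(
        rows, columns=["query", "q_start", "q_end", "subject", "s_start",
                       "s_end", "strand", "n_members", "aligned_length"]
    )


@dataclass
class LiftResult:
    """Per-variant lift-over outcome table plus the remapped matrix."""

    table: pd.DataFrame
    lifted: GenotypeMatrix | None

    @property
    def n_mapped(self) -> int:
        return int((self.table["status"] == "mapped").sum())


def _best_placements(window: str, targets: Fasta, max_frac_dist: float):
    """Best and runner-up placements of *window* over all target sequences
    and strands. Returns list of (dist, seq_name, strand, start0, end0)
    sorted by distance, keeping at most the two best distinct placements."""
    hits = []
    max_dist = int(max_frac_dist * len(window))
    for name in targets.keys():
        tseq = str(targets[name][:]).upper()
        for strand, query in (("+", window), ("-", revcomp(window))):
            res = edlib.align(query, tseq, mode="HW", task="locations",
                              k=max_dist)
            if res["editDistance"] < 0:
                continue
            locs = res["locations"]
            # distinct placements within one sequence count separately
            seen = []
            for (s0, e0) in locs:
                if any(abs(s0 - p) < len(window) // 2 for p in seen):
                    continue
                seen.append(s0)
                hits.append((res["editDistance"], name, strand, s0, e0))
    hits.sort(key=lambda h: h[0])
    return hits


def lift_variants(
    gm: GenotypeMatrix,
    source_fasta: str,
    target_fasta: str,
    flank: int = 150,
    max_frac_dist: float = 0.10,
    uniqueness_margin: float = 1.1,
) -> LiftResult:
    """Map variant coordinates and alleles onto a new assembly.

    For each variant a ``2*flank + 1`` bp window centred on it is extracted
    from the source assembly and searched against both strands of every
    target sequence by edit distance. A variant maps when a placement
    exists with score (window length minus edit distance) at least
    ``uniqueness_margin`` times the runner-up's, and the target base at
    the variant position equals REF (identity), ALT (REF/ALT swap,
    recorded), or their complements on the minus strand. Otherwise it is
    unmapped with reason no_hit, ambiguous, allele_mismatch or edge.
    """
    src = Fasta(source_fasta)
    tgt = Fasta(target_fasta)
    wlen = 2 * flank + 1

    # source consistency check up front
    offenders = []
    for j in range(gm.n_sites):
        row = gm.sites.iloc[j]
        chrom, pos = row["chrom"], int(row["pos"])
        base = str(src[chrom][pos - 1]).upper()
        if base != row["ref"]:
            offenders.append(f"{chrom}:{pos} REF={row['ref']} fasta={base}")
            if len(offenders) >= 10:
                break
    if offenders:
        raise ValueError(
            "VCF REF disagrees with source FASTA at: " + "; ".join(offenders)
        )

    rows = []
    for j in range(gm.n_sites):
        row = gm.sites.iloc[j]
        chrom, pos, ref, alt = row["chrom"], int(row["pos"]), row["ref"], row["alt"]
        out = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
               "target_chrom": None, "target_pos": None, "target_strand": None,
               "transform": None, "status": None}
        seqlen = len(src[chrom])
        if pos - 1 < flank or pos + flank > seqlen:
            out["status"] = "unmapped:edge"
            rows.append(out)
            continue
        window = str(src[chrom][pos - 1 - flank:pos + flank]).upper()
        hits = _best_placements(window, tgt, max_frac_dist)
        if not hits:
            out["status"] = "unmapped:no_hit"
            rows.append(out)
            continue
        best = hits[0]
        best_score = wlen - best[0]
        if len(hits) > 1:
            runner_score = wlen - hits[1][0]
            if best_score < uniqueness_margin * runner_score:
                out["status"] = "unmapped:ambiguous"
                rows.append(out)
                continue
        _, tname, strand, s0, e0 = best
        if (e0 - s0 + 1) != wlen:
            # indel-containing placement: centre offset not trustworthy
            out["status"] = "unmapped:no_hit"
            rows.append(out)
            continue
        if strand == "+":
            tpos = s0 + flank + 1          # 1-based
            tbase = str(tgt[tname][tpos - 1]).upper()
            exp_ref, exp_alt = ref, alt
        else:
            tpos = s0 + flank + 1
            tbase = str(tgt[tname][tpos - 1]).upper()
            exp_ref, exp_alt = revcomp(ref), revcomp(alt)
        if tbase == exp_ref:
            transform = "identity" if strand == "+" else "strand-complement"
            new_ref, new_alt = exp_ref, exp_alt
        elif tbase == exp_alt:
            transform = "ref/alt-swap" if strand == "+" else \
                "strand-complement+ref/alt-swap"
            new_ref, new_alt = exp_alt, exp_ref
        else:
            out["status"] = "unmapped:allele_mismatch"
            rows.append(out)
            continue
        out.update(
            {"target_chrom": tname, "target_pos": tpos, "target_strand": strand,
             "transform": transform, "status": "mapped",
             "target_ref": new_ref, "target_alt": new_alt}
        )
        rows.append(out)

    table = pd.DataFrame(rows)
    mapped_idx = np.flatnonzero((table["status"] == "mapped").to_numpy())
    lifted = None
    if len(mapped_idx):
        sub = gm.take_sites(mapped_idx)
        tab = table.iloc[mapped_idx]
        swap = tab["transform"].str.contains("swap").to_numpy()
        geno = sub.geno.copy()
        flip = np.flatnonzero(swap)
        for jj in flip:
            g = geno[:, jj]
            geno[:, jj] = np.where(g == 0, 2, np.where(g == 2, 0, g))
        sites = pd.DataFrame(
            {"chrom": tab["target_chrom"].to_numpy(),
             "pos": tab["target_pos"].astype(int).to_numpy(),
             "ref": tab["target_ref"].to_numpy(),
             "alt": tab["target_alt"].to_numpy(),
             "qual": sub.sites["qual"].to_numpy()}
        )
        order = sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        lifted = GenotypeMatrix(
            samples=list(sub.samples),
            sites=sites.iloc[order].reset_index(drop=True),
            geno=geno[:, order],
            depth=None if sub.depth is None else sub.depth[:, order],
        )
    return LiftResult(table=table, lifted=lifted)


def write_lifted_vcf(result: LiftResult, path: str) -> None:
    if result.lifted is None:
        raise ValueError("no mapped variants to write")
    write_vcf(result.lifted, path)
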