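"""Synthetic multi-population cohorts with known truth.

Population divergence follows the Balding–Nichols model: each population's
allele frequency at a site is Beta-distributed around a shared ancestral
frequency with spread controlled by that population's F (the expected
Fst against the ancestral pool). Haplotypes are drawn with a first-order
copying process so linkage decays with physical distance, which gives the
extended-haplotype statistics something real to measure. On top of the
neutral background, the generator can inject group-private alleles,
autozygous (ROH) segments, and a selective-sweep core haplotype, recording
everything in a :class:`TruthBundle`.

The observation layer models moderate-coverage short-read genotyping:
per-cell depth is Poisson around a per-sample mean, a true heterozygote is
called homozygous when all reads sample the same allele (probability
``2 * 0.5**d`` at depth d), low-depth cells are missing, and an independent
genotype error can be added. This reproduces the depth-dependent
heterozygote dropout that motivates the 15x depth threshold downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeMatrix


@dataclass
class PopulationModel:
    """Demography of the simulated cohort.

    Defaults mirror the study conditions downstream modules are exercised
    under: three diverged river populations of 20 diploids each with
    pairwise-divergence parameter F = 0.1 on one chromosome.
    """

    n_pops: int = 3
    samples_per_pop: int | list[int] = 20
    n_sites: int = 5000
    chrom_length: int = 50_000_000
    fst: float | list[float] = 0.10
    #: Beta(a, b) law for ancestral allele frequencies, truncated.
    ancestral_beta: tuple[float, float] = (0.8, 0.8)
    ancestral_bounds: tuple[float, float] = (0.02, 0.98)
    #: exponential LD decay length in bp for the haplotype copying process
    ld_decay_bp: float = 25_000.0
    chrom: str = "chr1"
    seed: int = 0

    def pop_sizes(self) -> list[int]:
        if isinstance(self.samples_per_pop, int):
            return [self.samples_per_pop] * self.n_pops
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError("samples_per_pop list length must equal n_pops")
        return list(self.samples_per_pop)

    def pop_fst(self) -> list[float]:
        fst = [self.fst] * self.n_pops if np.isscalar(self.fst) else list(self.fst)
        if len(fst) != self.n_pops:
            raise ValueError("fst list length must equal n_pops")
        for f in fst:
            if not 0.0 <= f < 1.0:
                raise ValueError(f"F must be in [0, 1), got {f}")
        return fst

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if min(self.pop_sizes()) < 1:
            raise ValueError("each population needs at least one sample")
        self.pop_fst()


@dataclass
class ObservationModel:
    """Sequencing-depth observation model for genotype calls."""

    mean_depth: float | list[float] = 16.0
    #: calls with depth below this are missing
    min_call_depth: int = 3
    #: independent probability a called genotype is corrupted
    error_rate: float = 0.002
    #: QUAL ~ qual_per_depth * mean site depth + Normal(0, qual_noise_sd)
    qual_per_depth: float = 3.0
    qual_noise_sd: float = 5.0

    def validate(self, n_samples: int) -> None:
        means = self.sample_means(n_samples)
        if (means <= 0).any():
            raise ValueError("mean depth must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    def sample_means(self, n_samples: int) -> np.ndarray:
        if np.isscalar(self.mean_depth):
            return np.full(n_samples, float(self.mean_depth))
        means = np.asarray(self.mean_depth, dtype=float)
        if len(means) != n_samples:
            raise ValueError("per-sample mean depth list has wrong length")
        return means


@dataclass
class PrivateAlleleInjection:
    group: int          # population index
    n_loci: int
    carriers_per_locus: int


@dataclass
class RohInjection:
    sample: int         # cohort-wide sample index
    start: int          # bp, inclusive
    end: int            # bp, inclusive


@dataclass
class SweepInjection:
    pop: int
    focal_pos: int      # bp; snapped to the nearest simulated site
    core_freq: float = 0.9
    span: int = 1_000_000


@dataclass
class InjectionSpec:
    """Ground-truth signals layered onto the neutral cohort."""

    private: list[PrivateAlleleInjection] = field(default_factory=list)
    roh: list[RohInjection] = field(default_factory=list)
    sweep: SweepInjection | None = None


@dataclass
class TruthBundle:
    """Everything the generator knows, for recovery tests downstream."""

    haplotypes: np.ndarray          # (2N, n_sites) in {0,1}
    genotypes: np.ndarray           # (N, n_sites) in {0,1,2}
    positions: np.ndarray           # bp, strictly increasing
    chrom: str
    pop_labels: np.ndarray          # (N,) population index per sample
    sample_ids: list[str]
    private_sites: pd.DataFrame     # columns: site_index, pos, group, n_carriers
    roh_segments: pd.DataFrame      # columns: sample, start, end
    sweep_site: int | None          # site index of the sweep focal SNP
    pop_freqs: np.ndarray | None = None   # (n_pops, n_sites) B-N frequencies

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]


def _draw_balding_nichols(rng, p_anc: np.ndarray, f: float) -> np.ndarray:
    if f == 0.0:
        return p_anc.copy()
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def _copying_haplotypes(rng, freqs: np.ndarray, n_hap: int,
                        positions: np.ndarray, decay_bp: float) -> np.ndarray:
    """First-order copying process: adjacent sites share latent quantiles
    with probability exp(-distance / decay), producing LD that decays with
    physical distance while marginals stay Bernoulli(freq)."""
    m = len(freqs)
    hap = np.empty((n_hap, m), dtype=np.int8)
    u = rng.random(n_hap)
    hap[:, 0] = u < freqs[0]
    if m == 1:
        return hap
    gaps = np.diff(positions)
    keep_p = np.exp(-gaps / decay_bp) if decay_bp > 0 else np.zeros(m - 1)
    for j in range(1, m):
        fresh = rng.random(n_hap) >= keep_p[j - 1]
        u = np.where(fresh, rng.random(n_hap), u)
        hap[:, j] = u < freqs[j]
    return hap


def simulate_haplotypes(
    pm: PopulationModel, inj: InjectionSpec | None = None
) -> TruthBundle:
    """Simulate phased haplotypes for all populations and apply injections.

    Returns the full truth: haplotypes, genotypes, labels and the injected
    signal coordinates. All randomness derives from ``pm.seed``.
    """
    pm.validate()
    inj = inj or InjectionSpec()
    rng = np.random.default_rng(pm.seed)
    sizes = pm.pop_sizes()
    fsts = pm.pop_fst()
    n_total = sum(sizes)

    positions = np.sort(
        rng.choice(np.arange(1, pm.chrom_length + 1), size=pm.n_sites, replace=False)
    )
    a, b = pm.ancestral_beta
    lo, hi = pm.ancestral_bounds
    p_anc = np.clip(rng.beta(a, b, size=pm.n_sites), lo, hi)

    pop_freqs = np.stack([_draw_balding_nichols(rng, p_anc, f) for f in fsts])
    hap_blocks = [
        _copying_haplotypes(rng, pop_freqs[k], 2 * sizes[k], positions, pm.ld_decay_bp)
        for k in range(pm.n_pops)
    ]
    hap = np.concatenate(hap_blocks, axis=0)
    pop_labels = np.repeat(np.arange(pm.n_pops), sizes)
    sample_ids = [f"P{k}_S{i:03d}" for k in range(pm.n_pops) for i in range(sizes[k])]
    pop_start = np.concatenate([[0], np.cumsum(sizes)])

    # --- injections (applied last, recorded in truth) ---
    used_sites: set[int] = set()
    priv_rows = []
    for spec in inj.private:
        if spec.carriers_per_locus > sizes[spec.group]:
            raise ValueError(
                f"private-allele injection: {spec.carriers_per_locus} carriers "
                f"> group size {sizes[spec.group]}"
            )
        candidates = [j for j in range(pm.n_sites) if j not in used_sites]
        sites_j = rng.choice(candidates, size=spec.n_loci, replace=False)
        grp_samples = np.arange(pop_start[spec.group], pop_start[spec.group + 1])
        for j in sites_j:
            used_sites.add(int(j))
            hap[:, j] = 0
            carriers = rng.choice(grp_samples, size=spec.carriers_per_locus,
                                  replace=False)
            for s in carriers:
                hap[2 * s + rng.integers(2), j] = 1
            priv_rows.append(
                {"site_index": int(j), "pos": int(positions[j]),
                 "group": spec.group, "n_carriers": spec.carriers_per_locus}
            )

    roh_rows = []
    for seg in inj.roh:
        if not (1 <= seg.start < seg.end <= pm.chrom_length):
            raise ValueError("ROH injection interval outside chromosome")
        in_seg = (positions >= seg.start) & (positions <= seg.end)
        hap[2 * seg.sample + 1, in_seg] = hap[2 * seg.sample, in_seg]
        roh_rows.append({"sample": seg.sample, "start": seg.start, "end": seg.end})

    sweep_site = None
    if inj.sweep is not None:
        sw = inj.sweep
        sweep_site = int(np.argmin(np.abs(positions - sw.focal_pos)))
        half = sw.span // 2
        in_span = np.abs(positions - positions[sweep_site]) <= half
        grp_haps = np.arange(2 * pop_start[sw.pop], 2 * pop_start[sw.pop + 1])
        n_core = int(round(sw.core_freq * len(grp_haps)))
        core = rng.choice(grp_haps, size=n_core, replace=False)
        template = hap[core[0], in_span].copy()
        for h in core:
            hap[h, in_span] = template
        hap[grp_haps, sweep_site] = 0
        hap[core, sweep_site] = 1

    genotypes = (hap[0::2] + hap[1::2]).astype(np.int8)
    return TruthBundle(
        haplotypes=hap,
        genotypes=genotypes,
        positions=positions,
        chrom=pm.chrom,
        pop_labels=pop_labels,
        sample_ids=sample_ids,
        private_sites=pd.DataFrame(
            priv_rows, columns=["site_index", "pos", "group", "n_carriers"]
        ),
        roh_segments=pd.DataFrame(roh_rows, columns=["sample", "start", "end"]),
        sweep_site=sweep_site,
        pop_freqs=pop_freqs,
    )


def observe(
    truth: TruthBundle, om: ObservationModel, seed: int = 0
) -> GenotypeMatrix:
    """Pass true genotypes through the sequencing-depth observation model.

    A true heterozygote at depth d is called the matching homozygote with
    probability ``2 * 0.5**d`` (all reads drew one allele); cells with depth
    below ``om.min_call_depth`` are missing; with probability
    ``om.error_rate`` a called genotype is replaced by a different one.
    """
    n, m = truth.genotypes.shape
    om.validate(n)
    rng = np.random.default_rng(seed)
    means = om.sample_means(n)
    depth = rng.poisson(means[:, None], size=(n, m)).astype(np.int32)

    geno = truth.genotypes.astype(np.int8).copy()
    het = geno == 1
    # all-d-reads-one-allele collapse for heterozygotes
    with np.errstate(over="ignore"):
        p_collapse = np.where(depth > 0, 2.0 * 0.5 ** depth.astype(float), 1.0)
    collapse = het & (rng.random((n, m)) < p_collapse)
    to_hom = np.where(rng.random((n, m)) < 0.5, 0, 2).astype(np.int8)
    geno = np.where(collapse, to_hom, geno)

    if om.error_rate > 0:
        err = rng.random((n, m)) < om.error_rate
        # corrupt to one of the two other genotype codes, uniformly
        shift = rng.integers(1, 3, size=(n, m))
        geno = np.where(err, (geno + shift) % 3, geno).astype(np.int8)

    geno = np.where(depth < om.min_call_depth, MISSING, geno).astype(np.int8)

    site_mean_depth = depth.mean(axis=0)
    qual = np.maximum(
        om.qual_per_depth * site_mean_depth
        + rng.normal(0.0, om.qual_noise_sd, size=m),
        1.0,
    )
    sites = pd.DataFrame(
        {
            "chrom": truth.chrom,
            "pos": truth.positions.astype(int),
            "ref": "A",
            "alt": "G",
            "qual": qual,
        }
    )
    return GenotypeMatrix(
        samples=list(truth.sample_ids),
        sites=sites,
        geno=geno,
        depth=depth,
        haplotypes=None,
    )


def truth_genotype_matrix(truth: TruthBundle, qual: float = 100.0) -> GenotypeMatrix:
    """Wrap the true (error-free, fully observed, phased) cohort."""
    sites = pd.DataFrame(
        {
            "chrom": truth.chrom,
            "pos": truth.positions.astype(int),
            "ref": "A",
            "alt": "G",
            "qual": qual,
        }
    )
    return GenotypeMatrix(
        samples=list(truth.sample_ids),
        sites=sites,
        geno=truth.genotypes.astype(np.int8),
        depth=None,
        haplotypes=truth.haplotypes,
    )


def write_truth_tables(truth: TruthBundle, prefix: str) -> None:
    """Emit truth as TSV: genotypes, group labels, injection coordinates."""
    pd.DataFrame(
        truth.genotypes,
        index=truth.sample_ids,
        columns=[f"{truth.chrom}:{p}" for p in truth.positions],
    ).to_csv(f"{prefix}.genotypes.tsv", sep="\t")
    pd.DataFrame(
        {"sample": truth.sample_ids, "pop": truth.pop_labels}
    ).to_csv(f"{prefix}.groups.tsv", sep="\t", index=False)
    truth.private_sites.to_csv(f"{prefix}.private.tsv", sep="\t", index=False)
    truth.roh_segments.to_csv(f"{prefix}.roh.tsv", sep="\t", index=False)
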