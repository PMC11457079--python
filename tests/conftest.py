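"""Shared fixtures: hand-built genotype matrices and session-scoped
synthetic cohorts reused by unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riverpop.datamodel import GenotypeMatrix
from riverpop.synthetic import (
    InjectionSpec,
    PopulationModel,
    PrivateAlleleInjection,
    RohInjection,
    SweepInjection,
    simulate_haplotypes,
)


def make_gm(
    geno,
    positions=None,
    chrom="chr1",
    qual=50.0,
    depth=None,
    samples=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain genotype array."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    positions = np.arange(1, m + 1) * 100 if positions is None else np.asarray(positions)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions.astype(int), "ref": "A", "alt": "G",
         "qual": qual}
    )
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        sites=sites,
        geno=geno,
        depth=None if depth is None else np.asarray(depth),
    )


@pytest.fixture(scope="session")
def cohort3():
    """Three diverged populations (F = 0.1), 20 diploids each: the standard
    structured cohort for structure/diversity/private-allele tests."""
    pm = PopulationModel(
        n_pops=3, samples_per_pop=20, n_sites=2000,
        chrom_length=20_000_000, fst=0.10, seed=42,
    )
    return pm, simulate_haplotypes(pm)


@pytest.fixture(scope="session")
def sweep_cohort():
    """Two populations with a selective sweep injected in population 0:
    150 kb core haplotype at frequency 0.9 on a 30 Mb / 6000-SNP map, so
    the swept region holds well under 1% of markers."""
    pm = PopulationModel(
        n_pops=2, samples_per_pop=25, n_sites=6000,
        chrom_length=30_000_000, fst=0.05, ld_decay_bp=20_000, seed=11,
    )
    inj = InjectionSpec(
        sweep=SweepInjection(pop=0, focal_pos=15_000_000, core_freq=0.9,
                             span=150_000)
    )
    return pm, inj, simulate_haplotypes(pm, inj)


@pytest.fixture(scope="session")
def private_cohort():
    """Three populations with 200 group-private alleles injected, each
    with exactly 4 heterozygous carriers, plus 30 below-threshold loci
    with 2 carriers."""
    pm = PopulationModel(
        n_pops=3, samples_per_pop=25, n_sites=2500,
        chrom_length=25_000_000, fst=0.05,
        ancestral_bounds=(0.15, 0.85), seed=77,
    )
    inj = InjectionSpec(
        private=[
            PrivateAlleleInjection(group=0, n_loci=70, carriers_per_locus=4),
            PrivateAlleleInjection(group=1, n_loci=70, carriers_per_locus=4),
            PrivateAlleleInjection(group=2, n_loci=60, carriers_per_locus=4),
            PrivateAlleleInjection(group=0, n_loci=30, carriers_per_locus=2),
        ]
    )
    return pm, inj, simulate_haplotypes(pm, inj)


@pytest.fixture(scope="session")
def roh_cohort():
    """One population with a 2 Mb autozygous segment injected in sample 2,
    observed at 30x mean depth."""
    from riverpop.synthetic import ObservationModel, observe

    pm = PopulationModel(
        n_pops=1, samples_per_pop=10, n_sites=4000,
        chrom_length=20_000_000, fst=0.02, seed=4,
    )
    inj = InjectionSpec(roh=[RohInjection(sample=2, start=5_000_000,
                                          end=7_000_000)])
    truth = simulate_haplotypes(pm, inj)
    gm = observe(truth, ObservationModel(mean_depth=30.0), seed=1)
    return truth, gm


def truth_assignments(truth) -> pd.DataFrame:
    """Sample-level group assignments straight from generator truth."""
    return pd.DataFrame(
        {
            "unit": truth.sample_ids,
            "group": [f"G{p + 1}" for p in truth.pop_labels],
            "max_ancestry": 1.0,
            "runner_up": [f"G{p + 1}" for p in truth.pop_labels],
            "below_threshold": False,
        }
    )
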