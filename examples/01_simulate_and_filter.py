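"""Simulate a three-population cohort at 16x coverage and run the QC stage.

Prints per-sample statistics and the per-criterion site-removal counts,
then the LD-pruned site count. The MAF filter removes alleles carried by
too few individuals: at this cohort size the minimum surviving carrier
counts are also printed.
"""

from riverpop import (
    ObservationModel,
    PopulationModel,
    apply_site_filters,
    maf_carrier_bounds,
    observe,
    prune_ld,
    sample_stats,
    simulate_haplotypes,
)

pm = PopulationModel(n_pops=3, samples_per_pop=20, n_sites=3000,
                     chrom_length=30_000_000, fst=0.10, seed=1)
truth = simulate_haplotypes(pm)
gm = observe(truth, ObservationModel(mean_depth=16.0), seed=1)

stats = sample_stats(gm)
print(stats.head())
print(f"\ncohort: {gm.n_samples} samples x {gm.n_sites} sites, "
      f"mean depth {stats['mean_depth'].mean():.1f}x, "
      f"mean %het {stats['pct_het'].mean():.1f}")

filtered, log = apply_site_filters(gm, return_log=True)
print(f"\nsite filters removed {log['total_removed']} sites "
      f"(missingness {log['missingness']}, depth {log['mean_depth']}, "
      f"MAF {log['maf']})")

c_het, c_hom = maf_carrier_bounds(gm.n_samples, 0.01)
print(f"MAF 0.01 at n={gm.n_samples}: alleles need >= {c_het} het "
      f"(or {c_hom} hom) carriers to survive")

pruned = prune_ld(filtered)
print(f"LD pruning: {filtered.n_sites} -> {pruned.n_sites} sites "
      "(r^2 <= 0.4, <= 2 per 20 kb)")
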