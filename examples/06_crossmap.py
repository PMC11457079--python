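"""Chain pairwise alignments into co-linear blocks and lift variants
between two small assemblies, including a reverse-complemented chromosome.
"""

import numpy as np
import pandas as pd

from riverpop import GenotypeMatrix
from riverpop.crossmap import chain_linear, chain_table, lift_variants, revcomp
from riverpop.datamodel import AlignmentRecord

# --- chaining: two co-linear 6 kb / 5 kb alignments, 50 kb apart ---
a = AlignmentRecord("q", "s", 95.0, 6000, 10, 1, 1, 6000, 1, 6000, 1e-60, 900)
b = AlignmentRecord("q", "s", 94.0, 5000, 12, 1, 56_000, 61_000, 56_000,
                    61_000, 1e-50, 800)
chains = chain_linear([a, b], gap=100_000, min_len=10_000)
print("chained blocks:")
print(chain_table(chains).to_string(index=False))

# --- lift-over: target has chr2 reverse-complemented ---
rng = np.random.default_rng(0)
c1 = "".join(rng.choice(list("ACGT"), 5000))
c2 = "".join(rng.choice(list("ACGT"), 5000))
open("/tmp/src.fa", "w").write(f">chr1\n{c1}\n>chr2\n{c2}\n")
open("/tmp/tgt.fa", "w").write(f">new1\n{c1}\n>new2\n{revcomp(c2)}\n")

rows = []
for chrom, seq in (("chr1", c1), ("chr2", c2)):
    for p in range(400, 4600, 300):
        ref = seq[p - 1]
        alt = rng.choice([x for x in "ACGT" if x != ref])
        rows.append((chrom, p, ref, alt, 60.0))
sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
gm = GenotypeMatrix(samples=["s1"], sites=sites,
                    geno=rng.integers(0, 3, (1, len(sites))).astype(np.int8))

res = lift_variants(gm, "/tmp/src.fa", "/tmp/tgt.fa")
print(f"\nlifted {res.n_mapped}/{len(res.table)} variants")
print(res.table.groupby(["chrom", "target_strand", "transform"])
      .size().to_string())
print("\nchr2 variants map to the minus strand with complemented alleles.")
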