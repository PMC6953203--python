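#!/usr/bin/env python
"""Simulate the red x green cross: F2 of 218 and the contrasting pools.

Writes the phenotyped F2 population, the pool memberships and the pooled
allele-count table under results/, and prints the class composition
(expected near green : light_red : red : dark_red ~ 0.35 : 0.06 : 0.33 :
0.25, with the green fraction slightly below the independence expectation
because the two qualitative loci are linked on chromosome 5).
"""

import sys
from pathlib import Path

import pandas as pd

from redleaf import io as rio
from redleaf import study
from redleaf.simulate import sample_pool_reads, select_pools, simulate_f2

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

arch, mmap = study.default_setup()
f2 = simulate_f2(218, mmap, arch, seed=study.substream(SEED, "f2"))
print(f"F2 of {f2.n} (seed {SEED}):")
print(f2.class_counts().to_string())

rng = study.substream(SEED, "scan")
high, low = select_pools(
    f2, 50, 50, mode="extreme_vs_random", seed=rng,
    ranking_noise_sd=study.STUDY_RANKING_NOISE,
)
counts = sample_pool_reads(f2, high, low, mean_depth=50, error_rate=0.001, seed=rng)

rio.write_population_tsv(f2, OUT / "f2_population.tsv")
pd.DataFrame({"pool": ["high"] * len(high) + ["low"] * len(low),
              "individual": list(high) + list(low)}).to_csv(
    OUT / "f2_pools.tsv", sep="\t", index=False)
rio.write_allele_counts(counts, OUT / "f2_pool_counts.tsv")
print(f"\nwrote population, pools and {len(counts)} SNP counts under {OUT}/")
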