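#!/usr/bin/env python
"""Recessive-class fine mapping: interval width versus class size.

Replays the intensifier fine-mapping campaign on the causal chromosome
with a dense marker grid: recessive-class F2 individuals are genotyped,
recombinants delimit the candidate interval, and the interval width is
tracked as the class grows from 50 to 864 individuals (nested subsets,
20 replicates).  With perfect phenotyping the interval always contains
the causal locus; at 864 individuals the median interval is a few
hundred kb.  Writes the width table under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from redleaf import study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
REPS = 20
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

sizes = (50, 100, 200, 400, 864)
widths, covered = [], 0
for i in range(REPS):
    out = study.fine_map_widths(SEED * 1000 + i, sizes=sizes)
    widths.append(out["widths"])
    covered += all(out["covered"])
widths = np.asarray(widths)

table = pd.DataFrame({
    "n_recessive": sizes,
    "median_width_kb": np.median(widths, axis=0) / 1e3,
    "q25_width_kb": np.quantile(widths, 0.25, axis=0) / 1e3,
    "q75_width_kb": np.quantile(widths, 0.75, axis=0) / 1e3,
})
print(table.to_string(index=False))
print(f"\ncausal locus inside the interval in {covered}/{REPS} replicates")
table.to_csv(OUT / "fine_map_widths.tsv", sep="\t", index=False)
print(f"wrote {OUT / 'fine_map_widths.tsv'}")
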