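#!/usr/bin/env python
"""Sequential fixed-background mapping: recover each locus one at a time.

For each locus, select a plant whose genotype fixes the already-known
loci (screening the F2 first, then selfed descendants, as the study did
through its F2:3 and F4 families), self it into a family of 600, scan the
two segregating colour classes against each other and call candidate
regions.  Each round should yield exactly one region containing its
target locus -- including the two intensifiers that the genome-wide F2
scan leaves undetected.  Writes one BED per round under results/.
"""

import sys
from pathlib import Path

from redleaf import io as rio
from redleaf import study
from redleaf.simulate import simulate_f2

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

arch, mmap = study.default_setup()
f2 = simulate_f2(218, mmap, arch, seed=study.substream(SEED, "f2"))
bands = study.study_bands(seed=study.substream(SEED, "bands"))

for target, constraints in study.SEQUENTIAL_ROUNDS:
    rng = study.substream(SEED, f"round-{target}")
    res = study.run_sequential_round(f2, target, constraints, bands, rng)
    loc = arch.locus(target)
    if not res["family_found"]:
        print(f"{target}: no family with the required background found")
        continue
    ok = "yes" if (res["n_regions"] == 1 and res["contains_causal"]) else "NO"
    print(
        f"{target} round ({res['family_generation']} family): "
        f"{res['n_regions']} region(s); unique region containing "
        f"chr{loc.chromosome}:{loc.position_bp/1e6:.1f} Mb: {ok}"
    )
    if len(res["regions"]):
        print(res["regions"].to_string(index=False))
        rio.write_regions_bed(res["regions"], OUT / f"round_{target.lower()}_regions.bed")
print(f"\nwrote per-round region BEDs under {OUT}/")
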