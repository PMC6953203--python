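"""End-to-end emulation of the red x green mapping study.

Drivers that chain the library modules into the study's campaigns: the
initial F2 bulked-segregant scan (which finds the two qualitative loci and
misses the two intensifiers hidden by epistasis), the fixed-background
family rounds that recover each masked locus one at a time, the
single-family reproductions used for segregation statistics, and the
analytic-limit scan of a monogenic recessive trait.

All scenario defaults are the study's own conditions: an F2 of 218, pools
of 50 against 50, mean read depth 50x per pool, selfed families of a few
hundred plants.  The simulated marker grid is sparser than an RNA-seq SNP
catalogue (200 markers per chromosome, one per ~1-2 Mb), so the scan
windows used on simulated data are correspondingly wider (10 Mb windows,
2.5 Mb step, >= 3 SNPs) than the defaults intended for dense data.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from . import mapping, scan
from .simulate import (
    MarkerMap,
    Population,
    sample_pool_reads,
    select_pools,
    self_generation,
    simulate_f2,
    single_seed_descent,
)
from .trait import GeneticArchitecture, LOCUS_NAMES

__all__ = [
    "substream",
    "default_setup",
    "make_parent",
    "q16_green_count",
    "q54_dark_red_count",
    "monogenic_delta",
    "study_bands",
    "scan_pools",
    "causal_window_exceeds",
    "find_background_parent",
    "SEQUENTIAL_ROUNDS",
    "run_sequential_round",
    "end_to_end_replicate",
    "SIM_SCAN",
]

#: Scan settings matched to the simulated marker density.
SIM_SCAN = {"min_depth": 10, "window_bp": 10_000_000, "step_bp": 2_500_000,
            "min_snps": 3, "min_consecutive": 3, "merge_gap": 25}

#: Within-class visual ranking noise (latent-score units) used when the
#: "50 most intense red" plants are picked for the F2 red pool: red
#: intensity varies continuously with plant age and environment, so the
#: visual ranking only loosely separates plants one score class apart.
STUDY_RANKING_NOISE = 0.75

#: Fixed-background rounds of the sequential campaign, in study order:
#: (target locus, functional-dosage constraints on the family parent).
#: The RLL1 round fixes RLL2 functional (an "S9"-type family segregating
#: 3:1 red:green); the RLL2 round fixes RLL1 ("Q16"); the RLL3 round uses a
#: family with functional RLL1, null RLL2, segregating RLL3 and functional
#: RLL4 (3:1 green:light-red); the RLL4 round fixes the other three
#: ("Q54", segregating red vs dark-red 3:1).
SEQUENTIAL_ROUNDS: tuple[tuple[str, dict[str, int]], ...] = (
    ("RLL1", {"RLL1": 1, "RLL2": 2}),
    ("RLL2", {"RLL1": 2, "RLL2": 1}),
    ("RLL3", {"RLL1": 2, "RLL2": 0, "RLL3": 1, "RLL4": 2}),
    ("RLL4", {"RLL1": 2, "RLL2": 2, "RLL3": 2, "RLL4": 1}),
)

_STATE = {0: "homozygous_null", 1: "heterozygous", 2: "homozygous_functional"}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage, derived from one
    master seed (the stage name is hashed into the spawn key)."""
    key = zlib.crc32(stage.encode("utf8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def default_setup(n_per_chrom: int = 200) -> tuple[GeneticArchitecture, MarkerMap]:
    arch = GeneticArchitecture.default()
    return arch, MarkerMap.regular(arch, n_per_chrom=n_per_chrom)


def make_parent(
    marker_map: MarkerMap,
    arch: GeneticArchitecture,
    causal_genotype: dict[str, tuple[int, int]],
    generation: str = "F2",
) -> Population:
    """A single plant with an F1-like background (heterozygous at every
    marker, one red and one green haplotype) whose causal loci are set to
    the requested phased functional alleles, e.g. ``{"RLL2": (1, 0)}`` for
    a heterozygote.  Used to reproduce specific families of the study."""
    haps = np.zeros((1, 2, len(marker_map)), dtype=np.uint8)
    haps[0, 0, :] = 1  # red-parent haplotype
    idx = marker_map.causal_indices(arch)
    for name, func_alleles in causal_genotype.items():
        loc = arch.locus(name)
        for h, func in enumerate(func_alleles):
            red = func if loc.functional_allele_source == "red_parent" else 1 - func
            haps[0, h, idx[name]] = red
    pop = Population(generation, marker_map, arch, haps)
    pop.assign_phenotypes()
    return pop


def q16_green_count(seed: int, n_offspring: int = 5430, setup=None) -> int:
    """Green plants among the selfed progeny of a plant heterozygous at
    RLL2 only (functional RLL1, suppressors intact): the Q16-type family
    segregating red : green 3:1."""
    arch, mmap = setup or default_setup()
    parent = make_parent(
        mmap, arch,
        {"RLL1": (1, 1), "RLL2": (1, 0), "RLL3": (1, 1), "RLL4": (1, 1)},
    )
    fam = self_generation(parent, 0, n_offspring, seed=substream(seed, "q16"), family="Q16")
    return int((fam.colour == "green").sum())


def q54_dark_red_count(seed: int, n_offspring: int = 270, setup=None) -> int:
    """Dark-red plants among the selfed progeny of a plant heterozygous at
    the RLL4 intensifier only (all other loci fixed functional): the
    Q54-type family segregating red (printed "light red") : dark red 3:1."""
    arch, mmap = setup or default_setup()
    parent = make_parent(
        mmap, arch,
        {"RLL1": (1, 1), "RLL2": (1, 1), "RLL3": (1, 1), "RLL4": (1, 0)},
        generation="F2:3",
    )
    fam = self_generation(parent, 0, n_offspring, seed=substream(seed, "q54"), family="Q54")
    return int((fam.colour == "dark_red").sum())


def monogenic_delta(
    seed: int,
    n_population: int = 20_000,
    depth: float = 10_000.0,
    setup=None,
) -> float:
    """Delta-index at a fully linked marker of a monogenic recessive green
    trait with perfect phenotyping: all recessive homozygotes in the low
    pool, everything else in the high pool.  The Mendelian limit is
    ``2/3 - 0 = 2/3`` (the high pool is 1 RR : 2 Rr)."""
    arch, mmap = setup or default_setup(n_per_chrom=20)
    parent = make_parent(
        mmap, arch,
        {"RLL1": (1, 0), "RLL2": (1, 1), "RLL3": (1, 1), "RLL4": (1, 1)},
        generation="F1",
    )
    pop = self_generation(parent, 0, n_population, seed=substream(seed, "monogenic"))
    green = pop.colour == "green"
    counts = sample_pool_reads(
        pop,
        np.flatnonzero(~green),
        np.flatnonzero(green),
        mean_depth=depth,
        error_rate=0.0,
        seed=substream(seed, "monogenic-reads"),
    )
    track = scan.delta_from_counts(counts, min_depth=10)
    at_locus = track[
        (track["chrom"] == arch.locus("RLL1").chromosome)
        & (track["pos"] == arch.locus("RLL1").position_bp)
    ]
    return float(at_locus["delta"].iloc[0])


def study_bands(
    pool_high: int = 50,
    pool_low: int = 50,
    mean_depth: float = 50.0,
    n_reps: int = 10_000,
    seed=0,
    generation: str = "F2",
) -> scan.CIBands:
    """Null confidence bands at the study's pool sizes, over a depth
    schedule spanning the Poisson spread around the mean depth."""
    depths = sorted({max(1, int(round(mean_depth * f))) for f in (0.4, 0.7, 1.0, 1.3, 1.7, 2.2)})
    return scan.simulate_null_ci(
        pool_high, pool_low, generation=generation, depths=depths, n_reps=n_reps, seed=seed
    )


def scan_pools(
    pop: Population,
    rng: np.random.Generator,
    k_high: int = 50,
    k_low: int = 50,
    mode: str = "extreme_vs_random",
    mean_depth: float = 50.0,
    error_rate: float = 0.001,
    scan_params: dict | None = None,
    ranking_noise_sd: float = 0.0,
) -> dict:
    """Pool a population, sample pooled reads and compute per-SNP and
    windowed delta-index tracks.  Returns the pools, counts and tracks."""
    p = {**SIM_SCAN, **(scan_params or {})}
    high, low = select_pools(
        pop, k_high, k_low, mode=mode, seed=rng, ranking_noise_sd=ranking_noise_sd
    )
    counts = sample_pool_reads(
        pop, high, low, mean_depth=mean_depth, error_rate=error_rate, seed=rng
    )
    track = scan.delta_from_counts(counts, min_depth=p["min_depth"])
    windows = scan.window_smooth(
        track,
        window_bp=p["window_bp"],
        step_bp=p["step_bp"],
        min_snps=p["min_snps"],
        chrom_lengths=pop.marker_map.chrom_lengths,
    )
    return {"high": high, "low": low, "counts": counts, "track": track, "windows": windows}


def causal_window_exceeds(
    windows: pd.DataFrame,
    bands: scan.CIBands,
    arch: GeneticArchitecture,
    locus: str,
    level: float,
) -> bool:
    """Does any supported window containing the locus position fall outside
    the null band at ``level``?"""
    loc = arch.locus(locus)
    w = windows[
        (windows["chrom"] == loc.chromosome)
        & (windows["start"] <= loc.position_bp)
        & (windows["end"] >= loc.position_bp)
        & ~windows["low_support"]
    ]
    if len(w) == 0:
        return False
    lo, hi = bands.band(level, w["depth_mean"].to_numpy())
    d = w["delta_mean"].to_numpy()
    return bool(((d > hi) | (d < lo)).any())


def find_background_parent(
    pop: Population,
    constraints: dict[str, int],
    rng: np.random.Generator,
    max_descents: int = 2,
) -> tuple[Population, int] | None:
    """Find an individual satisfying the causal-background constraints,
    screening the given generation first and then advancing all lines by
    selfing (single-seed descent, as the study did through F3/F4) up to
    ``max_descents`` times.  Returns (population, index) or None."""
    state_constraints = {k: _STATE[v] for k, v in constraints.items()}
    current = pop
    for _ in range(max_descents + 1):
        genos = pd.DataFrame(current.causal_dosage(), columns=list(LOCUS_NAMES))
        hits = mapping.select_fixed_background(genos, state_constraints)
        if hits:
            return current, int(rng.choice(hits))
        current = single_seed_descent(current, seed=rng)
    return None


def run_sequential_round(
    f2: Population,
    target: str,
    constraints: dict[str, int],
    bands: scan.CIBands,
    rng: np.random.Generator,
    family_size: int = 600,
    mean_depth: float = 50.0,
    k_pool: int = 50,
    level: float = 0.01,
    scan_params: dict | None = None,
) -> dict:
    """One fixed-background mapping round: select a family parent with the
    requested background, self it, scan contrasting pools within the family
    and call candidate regions against the null bands."""
    p = {**SIM_SCAN, **(scan_params or {})}
    found = find_background_parent(f2, constraints, rng)
    loc = f2.arch.locus(target)
    if found is None:
        return {"target": target, "family_found": False, "n_regions": 0, "contains_causal": False}
    parent_pop, idx = found
    fam = self_generation(parent_pop, idx, family_size, seed=rng, family=f"{target}-round")
    # within-family pools contrast the two segregating colour classes, as in
    # the family experiments (e.g. red vs green, or red vs dark red)
    res = scan_pools(
        fam, rng, k_high=k_pool, k_low=k_pool, mode="class_vs_class",
        mean_depth=mean_depth, scan_params=p,
    )
    regions = scan.call_regions(
        res["windows"], bands, level=level, min_consecutive=p["min_consecutive"],
        merge_gap=p.get("merge_gap", 0),
    )
    contains = (
        (regions["chrom"] == loc.chromosome)
        & (regions["start"] <= loc.position_bp)
        & (regions["end"] >= loc.position_bp)
    )
    return {
        "target": target,
        "family_found": True,
        "family_generation": fam.generation,
        "n_regions": int(len(regions)),
        "contains_causal": bool(contains.any()),
        "regions": regions,
    }


def fine_map_widths(
    seed: int,
    sizes: tuple[int, ...] = (50, 100, 200, 400, 864),
    locus: str = "RLL3",
    n_per_chrom: int = 2000,
) -> dict:
    """One fine-mapping replicate mirroring the intensifier campaign:
    recessive-class F2 individuals genotyped along the causal chromosome.

    Simulates the causal chromosome only, collects the first
    ``max(sizes)`` individuals homozygous for the recessive (red-parent)
    allele at the locus, and delimits the candidate interval from nested
    subsets of growing size.  Returns the interval per size and whether
    each contains the causal position (with zero phenotyping error the
    recessive class is exactly the donor-homozygote class, so coverage is
    the structural guarantee being checked).
    """
    arch = GeneticArchitecture.default()
    loc = arch.locus(locus)
    from .simulate import CHROM_LENGTHS_MB

    mmap = MarkerMap.regular(
        arch, n_per_chrom=n_per_chrom,
        chrom_lengths_mb={loc.chromosome: CHROM_LENGTHS_MB[loc.chromosome]},
    )
    n_max = max(sizes)
    rng = substream(seed, f"finemap-{locus}")
    causal_idx = mmap.index_of(locus)
    dosages = []
    collected = 0
    while collected < n_max:
        pop = simulate_f2(int(4.6 * n_max) + 200, mmap, arch, seed=rng)
        dos = pop.dosage()
        recessive = dos[:, causal_idx] == 2  # homozygous for the red-parent allele
        dosages.append(dos[recessive])
        collected += int(recessive.sum())
    dos = np.concatenate(dosages)[:n_max]
    positions = mmap.markers["pos_bp"].to_numpy()
    out = {"sizes": sizes, "widths": [], "covered": []}
    for k in sizes:
        res = mapping.fine_map_recessive(
            dos[:k], positions, max_errors=0, chrom=loc.chromosome,
            chrom_length_bp=mmap.chrom_lengths[loc.chromosome][0],
        )
        out["widths"].append(res.width_bp)
        out["covered"].append(res.start_bp <= loc.position_bp <= res.end_bp)
    return out


def end_to_end_replicate(
    seed: int,
    bands: scan.CIBands,
    n_f2: int = 218,
    k_pool: int = 50,
    mean_depth: float = 50.0,
    family_size: int = 600,
    setup=None,
) -> dict:
    """One full replicate of the study: F2 scan (epistatic-masking check:
    do the qualitative loci exceed the 0.01 band while the intensifiers
    stay inside the 0.05 band?) followed by the four sequential
    fixed-background rounds."""
    arch, mmap = setup or default_setup()
    f2 = simulate_f2(n_f2, mmap, arch, seed=substream(seed, "f2"))
    rng = substream(seed, "scan")
    res = scan_pools(
        f2, rng, k_high=k_pool, k_low=k_pool, mode="extreme_vs_random",
        mean_depth=mean_depth, ranking_noise_sd=STUDY_RANKING_NOISE,
    )
    masking = {
        "rll1_detected": causal_window_exceeds(res["windows"], bands, arch, "RLL1", 0.01),
        "rll2_detected": causal_window_exceeds(res["windows"], bands, arch, "RLL2", 0.01),
        "rll3_masked": not causal_window_exceeds(res["windows"], bands, arch, "RLL3", 0.05),
        "rll4_masked": not causal_window_exceeds(res["windows"], bands, arch, "RLL4", 0.05),
    }
    rounds = {}
    for target, constraints in SEQUENTIAL_ROUNDS:
        rng_round = substream(seed, f"round-{target}")
        rounds[target] = run_sequential_round(
            f2, target, constraints, bands, rng_round,
            family_size=family_size, mean_depth=mean_depth, k_pool=k_pool,
        )
    masking["all"] = all(masking.values())
    sequential_ok = all(
        r["family_found"] and r["n_regions"] == 1 and r["contains_causal"]
        for r in rounds.values()
    )
    return {
        "masking": masking,
        "rounds": rounds,
        "sequential_ok": sequential_ok,
        "windows": res["windows"],
    }
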