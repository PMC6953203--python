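"""Pedigree and pooled-read simulator for the red x green lettuce cross.

Simulates the biparental cross on a nine-chromosome map: an F1 that is
heterozygous everywhere, an F2 from selfing it, and selfed F2:3 / F4
families, with recombination driven by a map function (Haldane by default,
i.e. no crossover interference).  Haplotypes are stored as 0/1 indicators
of the *red-parent* allele, so a genome is an ``(n, 2, M)`` array over the
``M`` markers of the genome-wide map; causal loci are ordinary (named)
markers on this map, and phenotypes are assigned through
:mod:`redleaf.trait`.

Contrasting pools are drawn from a population by phenotype, and pooled
sequencing is emulated per SNP by sampling a read depth (negative binomial,
Poisson in the limit) and an alternate-allele read count (binomial around
the pool allele frequency, with a symmetric base-error rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trait import GeneticArchitecture, LOCUS_NAMES, classify_colour, latent_score

__all__ = [
    "CHROM_LENGTHS_MB",
    "MarkerMap",
    "Population",
    "haldane",
    "kosambi",
    "simulate_f2",
    "self_generation",
    "single_seed_descent",
    "select_pools",
    "sample_pool_reads",
    "POOL_COUNT_COLUMNS",
]

#: Chromosome sizes (Mb) on the scale of the v8 lettuce assembly.
CHROM_LENGTHS_MB = {1: 225, 2: 230, 3: 260, 4: 370, 5: 360, 6: 185, 7: 195, 8: 310, 9: 205}

#: Default map expansion: ~0.6 cM per Mb (a compact genetic map relative to
#: the large assembly, typical of lettuce).
CM_PER_MB = 0.6

POOL_COUNT_COLUMNS = (
    "CHROM",
    "POS",
    "REF",
    "ALT",
    "HIGH_REF",
    "HIGH_ALT",
    "LOW_REF",
    "LOW_ALT",
)

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))

_NEXT_GENERATION = {"F1": "F2", "F2": "F2:3", "F2:3": "F4", "F4": "F5", "F5": "F6"}


def haldane(d_cM):
    """Recombination fraction for a map distance in cM, no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def kosambi(d_cM):
    """Kosambi map function (partial interference); provided as the
    pluggable alternative."""
    return 0.5 * np.tanh(2.0 * np.asarray(d_cM, dtype=float) / 100.0)


_MAP_FUNCTIONS = {"haldane": haldane, "kosambi": kosambi}


@dataclass
class MarkerMap:
    """Ordered biallelic markers on the nine chromosomes.

    ``markers`` columns: ``chrom`` (1..9), ``pos_bp`` (1-based), ``pos_cM``,
    ``id``, ``ref``/``alt`` allele letters (REF is the green-parent /
    reference allele, ALT the red-parent allele), ``locus`` (causal-locus
    name or empty).  Rows are sorted by (chrom, pos_bp); bp and cM positions
    must increase together within a chromosome.
    """

    markers: pd.DataFrame
    chrom_lengths: dict[int, tuple[int, float]]  # chrom -> (bp, cM)
    map_function: str = "haldane"
    _rec: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        m = self.markers
        if len(m) == 0:
            raise ValueError("marker map is empty")
        required = {"chrom", "pos_bp", "pos_cM", "id"}
        if not required.issubset(m.columns):
            raise ValueError(f"marker table must have columns {sorted(required)}")
        key = m[["chrom", "pos_bp"]].to_numpy()
        if not (np.lexsort((key[:, 1], key[:, 0])) == np.arange(len(m))).all():
            raise ValueError("markers must be sorted by (chrom, pos_bp)")
        for chrom, grp in m.groupby("chrom"):
            bp_len, cm_len = self.chrom_lengths[int(chrom)]
            if (grp["pos_bp"] < 1).any() or (grp["pos_bp"] > bp_len).any():
                raise ValueError(f"chromosome {chrom}: marker bp positions outside [1, {bp_len}]")
            if (grp["pos_cM"].diff().dropna() < 0).any():
                raise ValueError(f"chromosome {chrom}: cM positions must be non-decreasing")
        if self.map_function not in _MAP_FUNCTIONS:
            raise ValueError(f"unknown map function {self.map_function!r}")
        self.markers = m.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.markers)

    def rec_fractions(self) -> np.ndarray:
        """Recombination fraction between each pair of adjacent markers in
        genome order; 0.5 across chromosome boundaries."""
        if self._rec is None:
            cm = self.markers["pos_cM"].to_numpy(dtype=float)
            chrom = self.markers["chrom"].to_numpy()
            r = _MAP_FUNCTIONS[self.map_function](np.diff(cm))
            r[np.diff(chrom) != 0] = 0.5
            self._rec = r
        return self._rec

    def index_of(self, marker_id: str) -> int:
        idx = np.flatnonzero((self.markers["id"] == marker_id).to_numpy())
        if idx.size == 0:
            raise KeyError(marker_id)
        return int(idx[0])

    def causal_indices(self, arch: GeneticArchitecture) -> dict[str, int]:
        """Row index of each causal locus (loci are carried as markers whose
        ``id`` is the locus name)."""
        return {name: self.index_of(name) for name in LOCUS_NAMES}

    @classmethod
    def regular(
        cls,
        arch: GeneticArchitecture | None = None,
        n_per_chrom: int = 200,
        chrom_lengths_mb: dict[int, int] | None = None,
        cm_per_mb: float = CM_PER_MB,
        map_function: str = "haldane",
    ) -> "MarkerMap":
        """Evenly spaced markers on all nine chromosomes, with the causal
        loci of ``arch`` inserted as named markers."""
        arch = arch or GeneticArchitecture.default()
        lengths = chrom_lengths_mb or CHROM_LENGTHS_MB
        rows = []
        for chrom, mb in lengths.items():
            bp_len = int(mb * 1e6)
            positions = np.round(np.arange(1, n_per_chrom + 1) * bp_len / (n_per_chrom + 1))
            for i, bp in enumerate(positions.astype(int)):
                ref, alt = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
                rows.append((chrom, bp, bp * cm_per_mb * 1e-6, f"c{chrom}_m{i + 1:03d}", ref, alt, ""))
        # a partial map (subset of chromosomes) only carries the causal loci
        # that fall on it; populations on such maps go unphenotyped
        for loc in arch.ordered_loci:
            if loc.chromosome in lengths:
                rows.append(
                    (loc.chromosome, int(loc.position_bp), float(loc.position_cM), loc.name, "G", "A", loc.name)
                )
        df = pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM", "id", "ref", "alt", "locus"])
        df = df.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        chrom_lengths = {int(c): (int(mb * 1e6), mb * cm_per_mb) for c, mb in lengths.items()}
        return cls(df, chrom_lengths, map_function)


@dataclass
class Population:
    """A generation of the cross: phased genomes plus phenotypes.

    ``haplotypes`` has shape ``(n, 2, M)`` with 1 marking the red-parent
    allele.  ``latent`` and ``colour`` are filled by
    :meth:`assign_phenotypes` (done by the simulators).
    """

    generation: str
    marker_map: MarkerMap
    arch: GeneticArchitecture
    haplotypes: np.ndarray
    family: str | None = None
    latent: np.ndarray | None = None
    colour: np.ndarray | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 3 or h.shape[1] != 2 or h.shape[2] != len(self.marker_map):
            raise ValueError(
                f"haplotypes must have shape (n, 2, {len(self.marker_map)}), got {h.shape}"
            )
        if h.size and h.max() > 1:
            raise ValueError("haplotypes are 0/1 indicators of the red-parent allele")
        self.haplotypes = h

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def has_causal_markers(self) -> bool:
        ids = set(self.marker_map.markers["id"])
        return all(name in ids for name in LOCUS_NAMES)

    def dosage(self) -> np.ndarray:
        """(n, M) red-parent allele dosage, 0/1/2."""
        return self.haplotypes.sum(axis=1)

    def causal_dosage(self) -> np.ndarray:
        """(n, 4) functional-allele dosage at RLL1..RLL4."""
        idx = self.marker_map.causal_indices(self.arch)
        cols = []
        for name in LOCUS_NAMES:
            red = self.haplotypes[:, :, idx[name]].sum(axis=1).astype(np.int64)
            loc = self.arch.locus(name)
            cols.append(red if loc.functional_allele_source == "red_parent" else 2 - red)
        return np.stack(cols, axis=1)

    def assign_phenotypes(
        self,
        noise_sd: float = 0.0,
        stress: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        scores = latent_score(self.causal_dosage(), stress=stress, arch=self.arch)
        if self.n == 0:
            self.latent = np.empty(0)
            self.colour = np.empty(0, dtype=object)
            return
        latent, colour = classify_colour(scores, noise_sd=noise_sd, rng=rng, arch=self.arch)
        self.latent = latent
        self.colour = colour

    def class_counts(self) -> pd.Series:
        return pd.Series(self.colour).value_counts()

    def subset(self, indices) -> "Population":
        indices = np.asarray(indices)
        return replace(
            self,
            haplotypes=self.haplotypes[indices],
            latent=None if self.latent is None else self.latent[indices],
            colour=None if self.colour is None else self.colour[indices],
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _meiosis_patterns(n: int, rec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n, M) array of 0/1 labels saying which parental haplotype each
    gamete carries at each marker (Markov walk with switch probabilities
    ``rec`` between adjacent markers)."""
    m = rec.size + 1
    pat = np.empty((n, m), dtype=np.uint8)
    pat[:, 0] = rng.integers(0, 2, size=n, dtype=np.uint8)
    if rec.size:
        pat[:, 1:] = rng.random((n, rec.size)) < rec
    return np.bitwise_xor.accumulate(pat, axis=1)


def _gametes_from_parent(hap_pair: np.ndarray, n: int, rec: np.ndarray, rng) -> np.ndarray:
    """``n`` gametes (n, M) from one parent's two phased haplotypes (2, M)."""
    pat = _meiosis_patterns(n, rec, rng)
    return np.where(pat == 0, hap_pair[0], hap_pair[1]).astype(np.uint8)


def simulate_f2(
    n: int,
    marker_map: MarkerMap,
    arch: GeneticArchitecture | None = None,
    seed=None,
    noise_sd: float = 0.0,
    stress: bool = False,
) -> Population:
    """F2 of the red x green cross: each individual is two independent F1
    gametes.  Parents are opposite homozygotes at every marker, so an F1
    gamete is simply the meiosis pattern itself (1 = red-parent segment)."""
    arch = arch or GeneticArchitecture.default()
    rng = _as_rng(seed)
    rec = marker_map.rec_fractions()
    haps = np.empty((n, 2, len(marker_map)), dtype=np.uint8)
    if n:
        haps[:, 0, :] = _meiosis_patterns(n, rec, rng)
        haps[:, 1, :] = _meiosis_patterns(n, rec, rng)
    pop = Population("F2", marker_map, arch, haps)
    if pop.has_causal_markers():
        pop.assign_phenotypes(noise_sd=noise_sd, stress=stress, rng=rng)
    return pop


def self_generation(
    pop: Population,
    parent_index: int,
    n_offspring: int,
    seed=None,
    noise_sd: float = 0.0,
    stress: bool = False,
    family: str | None = None,
) -> Population:
    """Selfed family of one individual: every offspring is two independent
    gametes from the parent's own haplotype pair."""
    rng = _as_rng(seed)
    rec = pop.marker_map.rec_fractions()
    parent = pop.haplotypes[parent_index]
    haps = np.empty((n_offspring, 2, len(pop.marker_map)), dtype=np.uint8)
    if n_offspring:
        haps[:, 0, :] = _gametes_from_parent(parent, n_offspring, rec, rng)
        haps[:, 1, :] = _gametes_from_parent(parent, n_offspring, rec, rng)
    child = Population(
        _NEXT_GENERATION.get(pop.generation, "selfed"),
        pop.marker_map,
        pop.arch,
        haps,
        family=family or f"{pop.generation}[{parent_index}]",
    )
    if child.has_causal_markers():
        child.assign_phenotypes(noise_sd=noise_sd, stress=stress, rng=rng)
    return child


def single_seed_descent(pop: Population, seed=None, noise_sd: float = 0.0) -> Population:
    """Advance every line by one selfing, keeping a single offspring per
    individual (used to emulate the F2 -> F2:3 -> F4 line maintenance)."""
    rng = _as_rng(seed)
    rec = pop.marker_map.rec_fractions()
    n = pop.n
    haps = np.empty_like(pop.haplotypes)
    if n:
        idx = np.arange(n)
        pat0 = _meiosis_patterns(n, rec, rng)
        pat1 = _meiosis_patterns(n, rec, rng)
        a = pop.haplotypes[idx, 0, :]
        b = pop.haplotypes[idx, 1, :]
        haps[:, 0, :] = np.where(pat0 == 0, a, b)
        haps[:, 1, :] = np.where(pat1 == 0, a, b)
    child = Population(
        _NEXT_GENERATION.get(pop.generation, "selfed"), pop.marker_map, pop.arch, haps
    )
    if child.has_causal_markers():
        child.assign_phenotypes(noise_sd=noise_sd, rng=rng)
    return child


def select_pools(
    pop: Population,
    k_high: int = 50,
    k_low: int = 50,
    mode: str = "extreme_vs_random",
    seed=None,
    ranking_noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Contrasting pools from a phenotyped population.

    ``extreme_vs_random`` (the design of the original F2 experiment): the
    high pool is the ``k_high`` most intensely red plants by latent score
    (ties broken by a seeded shuffle) and the low pool a random draw from
    the green class.  ``extreme_vs_extreme``: bottom ``k_low`` by score
    instead.  ``class_vs_class`` (the within-family design): a random draw
    from the lowest colour class present against a random draw from the
    classes above it.

    ``ranking_noise_sd`` adds seeded Gaussian noise to the scores before
    ranking in the two extreme modes, emulating the imperfect visual
    ranking of red intensity; 0 ranks by the true latent score.
    """
    if mode not in ("extreme_vs_random", "extreme_vs_extreme", "class_vs_class"):
        raise ValueError(f"unknown mode {mode!r}")
    if pop.latent is None or pop.colour is None:
        raise ValueError("population has no phenotypes; call assign_phenotypes first")
    if ranking_noise_sd < 0:
        raise ValueError("ranking_noise_sd must be >= 0")
    rng = _as_rng(seed)
    green = pop.colour == "green"
    if mode == "class_vs_class":
        from .trait import COLOUR_CLASSES

        rank = {c: i for i, c in enumerate(COLOUR_CLASSES)}
        levels = np.vectorize(rank.get)(pop.colour)
        lowest = levels.min()
        low_ids = np.flatnonzero(levels == lowest)
        high_ids = np.flatnonzero(levels > lowest)
        if len(high_ids) < k_high:
            raise ValueError(
                f"cannot fill the high pool: need {k_high} plants above the "
                f"lowest class, only {len(high_ids)} available"
            )
        if len(low_ids) < k_low:
            raise ValueError(
                f"cannot fill the low pool: need {k_low} lowest-class plants, "
                f"only {len(low_ids)} available"
            )
        high = np.sort(rng.choice(high_ids, size=k_high, replace=False))
        low = np.sort(rng.choice(low_ids, size=k_low, replace=False))
        return high, low
    score = pop.latent + (
        rng.normal(0.0, ranking_noise_sd, pop.n) if ranking_noise_sd > 0 else 0.0
    )
    tiebreak = rng.random(pop.n)
    order = np.lexsort((tiebreak, -score))  # descending score, shuffled ties
    high_candidates = order[~green[order]]
    if mode == "extreme_vs_extreme":
        high_candidates = order  # rank everyone; classes only matter for the random mode
    if len(high_candidates) < k_high:
        raise ValueError(
            f"cannot fill the high pool: need {k_high} non-green plants, "
            f"only {len(high_candidates)} available"
        )
    high = np.sort(high_candidates[:k_high])
    if mode == "extreme_vs_random":
        greens = np.flatnonzero(green)
        if len(greens) < k_low:
            raise ValueError(
                f"cannot fill the low pool: need {k_low} green plants, only {len(greens)} available"
            )
        low = np.sort(rng.choice(greens, size=k_low, replace=False))
    else:
        low = np.sort(order[::-1][:k_low])
    if np.intersect1d(high, low).size:
        raise ValueError("high and low pools overlap; population too small for these pool sizes")
    return high, low


def sample_pool_reads(
    pop: Population,
    high_ids,
    low_ids,
    mean_depth: float = 50.0,
    dispersion: float | None = None,
    error_rate: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Pooled sequencing counts at every marker for two pools.

    Per SNP and pool: the pool's alternate (red-parent) allele frequency is
    ``p = sum(dosage) / (2 n)``; the read depth is negative binomial with
    mean ``mean_depth`` and shape ``dispersion`` (Poisson when dispersion is
    None, emulating even coverage) and the alternate read count is
    ``Binomial(depth, p (1 - e) + (1 - p) e)`` with base-error rate ``e``.

    Returns the allele-count table with columns ``CHROM, POS, REF, ALT,
    HIGH_REF, HIGH_ALT, LOW_REF, LOW_ALT``.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    high_ids = np.asarray(high_ids)
    low_ids = np.asarray(low_ids)
    if high_ids.size == 0 or low_ids.size == 0:
        raise ValueError("pools must be non-empty")
    rng = _as_rng(seed)
    m = pop.marker_map.markers
    out = {"CHROM": m["chrom"].to_numpy(), "POS": m["pos_bp"].to_numpy(),
           "REF": m["ref"].to_numpy(), "ALT": m["alt"].to_numpy()}
    for label, ids in (("HIGH", high_ids), ("LOW", low_ids)):
        p = pop.haplotypes[ids].sum(axis=(0, 1)) / (2.0 * ids.size)
        if dispersion is None or not np.isfinite(dispersion):
            depth = rng.poisson(mean_depth, size=len(m))
        else:
            depth = rng.negative_binomial(
                dispersion, dispersion / (dispersion + mean_depth), size=len(m)
            )
        p_read = p * (1.0 - error_rate) + (1.0 - p) * error_rate
        alt = rng.binomial(depth, p_read)
        out[f"{label}_REF"] = depth - alt
        out[f"{label}_ALT"] = alt
    return pd.DataFrame(out, columns=list(POOL_COUNT_COLUMNS))
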