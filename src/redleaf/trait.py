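"""Four-locus epistatic genotype -> leaf-colour model for red lettuce.

Leaf anthocyanin in the red x green lettuce cross modelled here is
controlled by four loci:

* ``RLL1`` -- a bHLH activator.  The defective allele *rll1* is a null and
  is epistatic to everything else: *rll1/rll1* plants are green no matter
  what they carry at the other three loci.
* ``RLL2`` -- a MYB activator.  One functional (red-parent) copy is enough
  to turn the leaves red, i.e. the red allele is fully dominant.
* ``RLL3`` and ``RLL4`` -- dominant suppressors (an R3-MYB competitor and a
  RUP-like WD40).  Plants homozygous for the defective allele lose the
  suppression and the red colour deepens by one step each; these are the
  "recessive intensifier" loci.

Genotypes are written as *functional-allele dosages*: 0, 1 or 2 copies of
the functional allele at each locus, in the fixed order RLL1, RLL2, RLL3,
RLL4.  "Functional" means the allele that does the locus's job (activation
for RLL1/RLL2, suppression for RLL3/RLL4), so at RLL1/RLL2 the functional
allele comes from the red parent while at RLL3/RLL4 it comes from the green
parent.

The phenotype is an integer latent anthocyanin score ``s`` which is
thresholded into the four ordinal colour classes
``green < light_red < red < dark_red``.  Mild abiotic stress (cold or
drought) adds a bonus to the score of any plant with an intact pathway,
mimicking the stress-induced reddening of wild lettuce.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LOCUS_NAMES",
    "COLOUR_CLASSES",
    "CausalLocus",
    "GeneticArchitecture",
    "ColourPhenotype",
    "latent_score",
    "classify_colour",
    "enumerate_phenotype_table",
]

LOCUS_NAMES = ("RLL1", "RLL2", "RLL3", "RLL4")
COLOUR_CLASSES = ("green", "light_red", "red", "dark_red")

_ALLELE_SOURCES = ("red_parent", "green_parent")


@dataclass(frozen=True)
class CausalLocus:
    """One causal locus: where it sits and which parent carries the
    functional allele."""

    name: str
    chromosome: int
    position_bp: int
    position_cM: float
    functional_allele_source: str

    def __post_init__(self) -> None:
        if self.name not in LOCUS_NAMES:
            raise ValueError(f"unknown locus name {self.name!r}; expected one of {LOCUS_NAMES}")
        if not 1 <= int(self.chromosome) <= 9:
            raise ValueError(f"{self.name}: chromosome must be in 1..9, got {self.chromosome}")
        if self.position_bp < 0 or self.position_cM < 0:
            raise ValueError(f"{self.name}: positions must be non-negative")
        if self.functional_allele_source not in _ALLELE_SOURCES:
            raise ValueError(
                f"{self.name}: functional_allele_source must be one of {_ALLELE_SOURCES}"
            )


@dataclass(frozen=True)
class GeneticArchitecture:
    """The four-locus architecture plus the score weights' thresholds.

    Parameters
    ----------
    loci
        Exactly four :class:`CausalLocus`, one per name in
        :data:`LOCUS_NAMES` (any order; looked up by name).
    stress_bonus
        Integer added to the latent score of plants with a functional RLL1
        when grown under stress.  Default 1.
    class_thresholds
        Three strictly increasing integers ``(t1, t2, t3)``; a latent score
        ``s`` maps to green when ``s < t1``, light_red when ``t1 <= s < t2``,
        red when ``t2 <= s < t3`` and dark_red when ``s >= t3``.
    """

    loci: tuple[CausalLocus, ...]
    stress_bonus: int = 1
    class_thresholds: tuple[float, float, float] = (1, 2, 3)

    def __post_init__(self) -> None:
        if len(self.loci) != 4:
            raise ValueError(f"architecture needs exactly four loci, got {len(self.loci)}")
        names = [loc.name for loc in self.loci]
        if sorted(names) != sorted(LOCUS_NAMES):
            raise ValueError(f"loci must cover {LOCUS_NAMES} exactly, got {names}")
        if len(self.class_thresholds) != 3 or not (
            self.class_thresholds[0] < self.class_thresholds[1] < self.class_thresholds[2]
        ):
            raise ValueError("class_thresholds must be three strictly increasing values")

    def locus(self, name: str) -> CausalLocus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    @property
    def ordered_loci(self) -> tuple[CausalLocus, ...]:
        """Loci in canonical RLL1..RLL4 order."""
        return tuple(self.locus(n) for n in LOCUS_NAMES)

    @classmethod
    def default(cls) -> "GeneticArchitecture":
        """Architecture of the red x green cross: RLL1 and RLL2 on
        chromosome 5, RLL3 on chromosome 4, RLL4 on chromosome 9; the
        activators' functional alleles come from the red parent, the
        suppressors' from the green parent."""
        cm = 0.6e-6  # default map expansion used by the simulator (cM per bp)
        mk = lambda name, chrom, bp, src: CausalLocus(name, chrom, bp, bp * cm, src)
        return cls(
            loci=(
                mk("RLL1", 5, 336_800_000, "red_parent"),
                mk("RLL2", 5, 160_000_000, "red_parent"),
                mk("RLL3", 4, 200_000_000, "green_parent"),
                mk("RLL4", 9, 120_000_000, "green_parent"),
            )
        )


@dataclass(frozen=True)
class ColourPhenotype:
    """Latent anthocyanin score (possibly noisy) and its ordinal class."""

    latent_score: float
    colour_class: str


def _as_dosage_array(dosages) -> np.ndarray:
    """Accept a mapping {locus: dosage} or an array-like (..., 4) ordered
    RLL1..RLL4, return an integer array of shape (..., 4)."""
    if isinstance(dosages, dict):
        try:
            dosages = [dosages[n] for n in LOCUS_NAMES]
        except KeyError as exc:
            raise KeyError(f"missing dosage for locus {exc.args[0]!r}") from None
    arr = np.asarray(dosages)
    if arr.shape[-1] != 4:
        raise ValueError(f"expected dosages for 4 loci on the last axis, got shape {arr.shape}")
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError("dosages must be 0, 1 or 2 functional-allele copies")
    return arr.astype(np.int64)


def latent_score(dosages, stress: bool = False, arch: GeneticArchitecture | None = None):
    """Integer anthocyanin score of one or many genotypes.

    ``dosages`` holds functional-allele dosages ordered RLL1..RLL4 (last
    axis), or a mapping from locus name to dosage.  The rules:

    * ``rll1/rll1`` (RLL1 dosage 0) scores 0 -- epistatic over everything;
    * otherwise ``s = 2*[RLL2 >= 1] + [RLL3 == 0] + [RLL4 == 0]``, plus the
      architecture's stress bonus when ``stress`` is set.

    Returns a scalar ``int`` for a single genotype, else an integer array.
    """
    arch = arch or GeneticArchitecture.default()
    d = _as_dosage_array(dosages)
    s = (
        2 * (d[..., 1] >= 1).astype(np.int64)
        + (d[..., 2] == 0)
        + (d[..., 3] == 0)
        + (arch.stress_bonus if stress else 0)
    )
    s = np.where(d[..., 0] == 0, 0, s)
    return int(s) if s.ndim == 0 else s


def classify_colour(
    s,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    arch: GeneticArchitecture | None = None,
):
    """Threshold a latent score into a colour class, optionally after adding
    Gaussian phenotyping noise.

    With ``noise_sd = 0`` the map is a pure function of ``s``.  Returns a
    :class:`ColourPhenotype` for scalar input, else a pair of arrays
    ``(latent, colour)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    arch = arch or GeneticArchitecture.default()
    latent = np.asarray(s, dtype=float)
    scalar = latent.ndim == 0
    if noise_sd > 0:
        if rng is None:
            raise ValueError("a seeded rng is required when noise_sd > 0")
        latent = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    thresholds = np.asarray(arch.class_thresholds, dtype=float)
    idx = np.searchsorted(thresholds, latent, side="right")
    colour = np.asarray(COLOUR_CLASSES, dtype=object)[idx]
    if scalar:
        return ColourPhenotype(float(latent), str(colour))
    return latent, colour


def enumerate_phenotype_table(arch: GeneticArchitecture | None = None) -> pd.DataFrame:
    """Exhaustive genotype -> class table: all 3^4 dosage combinations
    crossed with {no stress, stress} (162 rows), noise-free."""
    arch = arch or GeneticArchitecture.default()
    rows = []
    for combo in itertools.product((0, 1, 2), repeat=4):
        for stress in (False, True):
            s = latent_score(combo, stress=stress, arch=arch)
            pheno = classify_colour(s, arch=arch)
            rows.append((*combo, stress, s, pheno.colour_class))
    return pd.DataFrame(rows, columns=[*LOCUS_NAMES, "stress", "score", "colour"])
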