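"""Segregation statistics, family screening and recessive-class fine mapping.

Covers the classical-genetics half of the mapping campaign: chi-square
goodness-of-fit of phenotype counts against a hypothesized Mendelian ratio,
chi-square independence tests of marker-trait association, calling whether
a family segregates, selecting families whose genetic background fixes the
already-cloned loci (the trick that unmasks loci hidden by epistasis), and
delimiting a candidate interval from recombinants observed among
recessive-class individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegregationResult",
    "FineMapResult",
    "chisq_ratio",
    "marker_association",
    "classify_segregating",
    "select_fixed_background",
    "fine_map_recessive",
]

_CONSTRAINT_DOSAGE = {"homozygous_functional": 2, "heterozygous": 1, "homozygous_null": 0}


class SegregationResult(NamedTuple):
    chi2: float
    df: int
    pvalue: float


def chisq_ratio(counts, ratio, yates: bool = False) -> SegregationResult:
    """Chi-square goodness of fit of observed class counts against a
    hypothesized segregation ratio (e.g. ``(4058, 1372)`` vs ``(3, 1)``).

    No continuity correction by default (``yates=True`` enables it for
    two-class tables).  Expected counts below 1 are an error; below 5 a
    warning, as the chi-square approximation degrades.
    """
    obs = np.asarray(counts, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("counts must be a flat vector of at least two classes")
    if ratio.shape != obs.shape:
        raise ValueError(f"ratio arity {ratio.size} does not match {obs.size} classes")
    if (ratio <= 0).any():
        raise ValueError("ratio terms must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = total * ratio / ratio.sum()
    if (expected < 1).any():
        raise ValueError("expected count below 1 in some class; test invalid")
    if (expected < 5).any():
        warnings.warn("expected count below 5; chi-square approximation is rough", stacklevel=2)
    if yates and obs.size == 2:
        chi2 = float((((np.abs(obs - expected) - 0.5).clip(min=0)) ** 2 / expected).sum())
        pvalue = float(stats.chi2.sf(chi2, df=obs.size - 1))
        return SegregationResult(chi2, obs.size - 1, pvalue)
    chi2, pvalue = stats.chisquare(obs, expected)
    return SegregationResult(float(chi2), obs.size - 1, float(pvalue))


def marker_association(genotypes, phenotypes=None) -> SegregationResult:
    """Chi-square test of independence between marker genotype and
    phenotype class.

    Either pass two per-individual vectors, or a prebuilt genotype x
    phenotype contingency table (2-D array / DataFrame).  Degenerate tables
    (a single row or column, or an all-zero row/column) are an error.
    """
    if phenotypes is None:
        table = np.asarray(genotypes, dtype=float)
        if table.ndim != 2:
            raise ValueError("a contingency table must be two-dimensional")
    else:
        table = pd.crosstab(pd.Series(genotypes), pd.Series(phenotypes)).to_numpy(dtype=float)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least two genotype and two phenotype classes")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty row or column")
    res = stats.chi2_contingency(table, correction=False)
    return SegregationResult(float(res.statistic), int(res.dof), float(res.pvalue))


def classify_segregating(
    counts, min_minor_count: int = 3, min_minor_freq: float = 0.05
) -> bool:
    """Is a family's phenotype segregating?  True iff at least two classes
    each reach both minor-class thresholds (absolute count and frequency),
    making the call robust to the odd misphenotyped plant."""
    if isinstance(counts, dict):
        counts = list(counts.values())
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    qualifying = (c >= min_minor_count) & (c / total >= min_minor_freq)
    return int(qualifying.sum()) >= 2


def select_fixed_background(genotypes: pd.DataFrame, constraints: dict[str, str]) -> list:
    """Families (or individuals) whose genotype at each named locus
    satisfies the requested state.

    ``genotypes`` is indexed by family id with one column per locus holding
    the functional-allele dosage (0/1/2); ``constraints`` maps locus name
    to ``homozygous_functional | heterozygous | homozygous_null``.  Returns
    matching ids in input order.
    """
    mask = np.ones(len(genotypes), dtype=bool)
    for locus, state in constraints.items():
        if locus not in genotypes.columns:
            raise KeyError(f"unknown locus {locus!r}; genotype table has {list(genotypes.columns)}")
        try:
            want = _CONSTRAINT_DOSAGE[state]
        except KeyError:
            raise ValueError(
                f"unknown constraint {state!r}; expected one of {sorted(_CONSTRAINT_DOSAGE)}"
            ) from None
        mask &= genotypes[locus].to_numpy() == want
    return list(genotypes.index[mask])


@dataclass(frozen=True)
class FineMapResult:
    """Candidate interval from recessive-class recombinant screening.

    1-based inclusive bp interval delimited by the innermost markers at
    which recombinants exceed the error tolerance (the causal locus cannot
    lie beyond a marker where a recessive-class plant is not homozygous for
    the donor allele, barring phenotyping error)."""

    start_bp: int
    end_bp: int
    core_start_index: int
    core_end_index: int
    recombinants: np.ndarray
    chrom: int | None = None

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def fine_map_recessive(
    donor_dosage: np.ndarray,
    positions_bp,
    max_errors: int = 0,
    chrom: int | None = None,
    chrom_length_bp: int | None = None,
) -> FineMapResult:
    """Delimit the locus from recessive-phenotype individuals genotyped at
    ordered markers.

    ``donor_dosage`` is an ``(individuals, markers)`` matrix of dosages of
    the donor (recessive-parent) allele; a recessive-class individual
    should be homozygous donor (dosage 2) at the causal locus, so any
    marker where it is not marks a recombination breakpoint.  The interval
    is the longest run of markers with at most ``max_errors`` recombinant
    individuals, extended outward to the nearest flanking markers where
    recombinants exceed the tolerance (or to the chromosome/marker ends).
    """
    d = np.asarray(donor_dosage)
    if d.ndim != 2 or d.shape[0] < 1:
        raise ValueError("need a (individuals, markers) dosage matrix with >= 1 individual")
    positions = np.asarray(positions_bp, dtype=np.int64)
    if positions.size != d.shape[1]:
        raise ValueError("positions do not match the number of markers")
    if (np.diff(positions) <= 0).any():
        raise ValueError("markers must be strictly ordered by position")
    recomb = (d != 2).sum(axis=0)
    ok = recomb <= max_errors
    if not ok.any():
        raise ValueError(
            "every marker carries recombinants beyond the tolerance; "
            "the phenotype and genotypes are inconsistent"
        )
    # longest run of consistent markers; ties -> fewest recombinants, then leftmost
    best = None
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            key = (-(j - i + 1), recomb[i : j + 1].sum())
            if best is None or key < best[0]:
                best = (key, i, j)
            i = j + 1
        else:
            i += 1
    _, i, j = best
    if i > 0:
        start = int(positions[i - 1])
    else:
        start = 1 if chrom_length_bp is not None else int(positions[0])
    if j < ok.size - 1:
        end = int(positions[j + 1])
    else:
        end = int(chrom_length_bp) if chrom_length_bp is not None else int(positions[-1])
    return FineMapResult(
        start_bp=start,
        end_bp=end,
        core_start_index=i,
        core_end_index=j,
        recombinants=recomb,
        chrom=chrom,
    )
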