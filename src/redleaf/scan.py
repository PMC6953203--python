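"""Pooled-segregant scan statistic: SNP-index, delta-index, window smoothing,
Monte-Carlo null confidence bands and candidate-region calling.

The SNP-index of a pool at a SNP is the fraction of reads carrying the
alternate (red-parent) allele.  The delta-index is the signed difference
``index(high pool) - index(low pool)``; it hovers around zero genome-wide
and deviates near a locus that the pooled phenotypes segregate for.
Significance is assessed against empirical null quantiles obtained by
simulating pools of the same sizes drawn from the same generation with no
trait locus, at matched read depths (the resampling construction used by
QTL-seq style pipelines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "snp_index",
    "delta_index",
    "delta_from_counts",
    "window_smooth",
    "CIBands",
    "simulate_null_ci",
    "call_regions",
]


def snp_index(counts: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Per-SNP, per-pool allele-frequency track from an allele-count table.

    Returns a long table with columns ``chrom, pos, pool, depth, alt,
    index, filtered``; SNPs with depth below ``min_depth`` are flagged
    ``filtered`` (their index is NaN) and are excluded downstream.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    frames = []
    for pool, label in (("high", "HIGH"), ("low", "LOW")):
        depth = (counts[f"{label}_REF"] + counts[f"{label}_ALT"]).to_numpy(dtype=np.int64)
        alt = counts[f"{label}_ALT"].to_numpy(dtype=np.int64)
        filtered = depth < min_depth
        with np.errstate(divide="ignore", invalid="ignore"):
            index = np.where(filtered, np.nan, alt / np.maximum(depth, 1))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": counts["CHROM"].to_numpy(),
                    "pos": counts["POS"].to_numpy(),
                    "pool": pool,
                    "depth": depth,
                    "alt": alt,
                    "index": index,
                    "filtered": filtered,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def delta_index(high: pd.DataFrame, low: pd.DataFrame) -> pd.DataFrame:
    """Signed per-SNP delta-index (high - low) at SNPs unfiltered in both
    pools.  The two tracks must share SNP coordinates row-for-row."""
    for df in (high, low):
        if not {"chrom", "pos", "index", "depth", "filtered"}.issubset(df.columns):
            raise ValueError("tracks must come from snp_index()")
    if len(high) != len(low) or not (
        (high["chrom"].to_numpy() == low["chrom"].to_numpy()).all()
        and (high["pos"].to_numpy() == low["pos"].to_numpy()).all()
    ):
        raise ValueError("high and low tracks do not share SNP coordinates")
    keep = ~(high["filtered"].to_numpy() | low["filtered"].to_numpy())
    out = pd.DataFrame(
        {
            "chrom": high["chrom"].to_numpy()[keep],
            "pos": high["pos"].to_numpy()[keep],
            "delta": high["index"].to_numpy()[keep] - low["index"].to_numpy()[keep],
            "depth_high": high["depth"].to_numpy()[keep],
            "depth_low": low["depth"].to_numpy()[keep],
        }
    )
    out["depth_mean"] = 0.5 * (out["depth_high"] + out["depth_low"])
    return out


def delta_from_counts(counts: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Convenience: allele counts -> per-SNP delta-index track."""
    track = snp_index(counts, min_depth=min_depth)
    return delta_index(
        track[track["pool"] == "high"].reset_index(drop=True),
        track[track["pool"] == "low"].reset_index(drop=True),
    )


def window_smooth(
    track: pd.DataFrame,
    window_bp: int = 2_000_000,
    step_bp: int = 500_000,
    min_snps: int = 5,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window mean of the per-SNP delta-index.

    Windows of ``window_bp`` tile each chromosome from position 1 at
    ``step_bp`` intervals (1-based inclusive coordinates); windows holding
    fewer than ``min_snps`` SNPs are flagged ``low_support``.
    """
    if not window_bp >= step_bp > 0:
        raise ValueError("need window_bp >= step_bp > 0")
    rows = []
    for chrom, grp in track.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        delta = grp["delta"].to_numpy()
        depth = grp["depth_mean"].to_numpy()
        if chrom_lengths is not None:
            length = chrom_lengths[chrom][0] if isinstance(chrom_lengths[chrom], tuple) else chrom_lengths[chrom]
        else:
            length = int(pos.max())
        starts = np.arange(1, max(length - window_bp + 2, 2), step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        csum_d = np.concatenate([[0.0], np.cumsum(delta)])
        csum_dep = np.concatenate([[0.0], np.cumsum(depth)])
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean_delta = np.where(n > 0, (csum_d[hi] - csum_d[lo]) / np.maximum(n, 1), np.nan)
            mean_depth = np.where(n > 0, (csum_dep[hi] - csum_dep[lo]) / np.maximum(n, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_snps": n,
                    "delta_mean": mean_delta,
                    "depth_mean": mean_depth,
                    "low_support": n < min_snps,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class CIBands:
    """Empirical two-sided null quantiles of the delta-index, per depth.

    ``lower``/``upper`` map a confidence level (e.g. 0.05) to arrays of
    quantiles aligned with ``depths``; :meth:`band` interpolates between
    the simulated depths (flat beyond the ends).
    """

    depths: np.ndarray
    levels: tuple[float, ...]
    lower: dict[float, np.ndarray]
    upper: dict[float, np.ndarray]
    params: dict

    def band(self, level: float, depth) -> tuple[np.ndarray, np.ndarray]:
        if level not in self.lower:
            raise KeyError(f"no band simulated at level {level}")
        depth = np.asarray(depth, dtype=float)
        lo = np.interp(depth, self.depths, self.lower[level])
        hi = np.interp(depth, self.depths, self.upper[level])
        return lo, hi

    def halfwidth(self, level: float, depth) -> np.ndarray:
        lo, hi = self.band(level, depth)
        return 0.5 * (np.asarray(hi) - np.asarray(lo))


def _null_pool_freq(
    n_pool: int, generation: str, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Null alternate-allele frequency of a pool of ``n_pool`` individuals
    drawn from an F2 (dosages 1:2:1) or from a single selfed F2:3 family
    (the F2 parent's genotype is drawn first; a homozygous parent fixes the
    family, a heterozygous one segregates 1:2:1)."""
    if generation == "F2":
        counts = rng.multinomial(n_pool, [0.25, 0.5, 0.25], size=n_reps)
        return (counts[:, 1] + 2 * counts[:, 2]) / (2.0 * n_pool)
    if generation == "F2:3-pooled":
        parent = rng.choice(3, size=n_reps, p=[0.25, 0.5, 0.25])
        counts = rng.multinomial(n_pool, [0.25, 0.5, 0.25], size=n_reps)
        het_freq = (counts[:, 1] + 2 * counts[:, 2]) / (2.0 * n_pool)
        return np.where(parent == 0, 0.0, np.where(parent == 2, 1.0, het_freq))
    raise ValueError(f"unknown generation {generation!r}")


def simulate_null_ci(
    pool_n_high: int,
    pool_n_low: int,
    generation: str = "F2",
    depths=(20, 35, 50, 65, 80, 100),
    n_reps: int = 10_000,
    levels: tuple[float, ...] = (0.05, 0.01),
    seed=None,
) -> CIBands:
    """Monte-Carlo null confidence bands for the delta-index.

    For each scheduled depth and each of ``n_reps`` replicates, both pools'
    individuals are drawn from the generation's Mendelian dosage
    distribution at a locus with no effect, reads are sampled binomially at
    that depth, and the delta-index is recorded; the bands are the
    empirical two-sided quantiles (``level/2`` and ``1 - level/2``) per
    depth, interpolated in between.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000 for stable quantiles")
    if pool_n_high < 1 or pool_n_low < 1:
        raise ValueError("pool sizes must be >= 1")
    depths = np.asarray(sorted(depths), dtype=int)
    if (depths <= 0).any():
        raise ValueError("depth schedule must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lower = {lv: np.empty(depths.size) for lv in levels}
    upper = {lv: np.empty(depths.size) for lv in levels}
    for j, d in enumerate(depths):
        p_high = _null_pool_freq(pool_n_high, generation, n_reps, rng)
        p_low = _null_pool_freq(pool_n_low, generation, n_reps, rng)
        idx_high = rng.binomial(d, p_high) / d
        idx_low = rng.binomial(d, p_low) / d
        delta = idx_high - idx_low
        for lv in levels:
            lower[lv][j], upper[lv][j] = np.quantile(delta, [lv / 2.0, 1.0 - lv / 2.0])
    return CIBands(
        depths=depths.astype(float),
        levels=tuple(levels),
        lower=lower,
        upper=upper,
        params={
            "pool_n_high": pool_n_high,
            "pool_n_low": pool_n_low,
            "generation": generation,
            "n_reps": n_reps,
            "seed": repr(seed),
        },
    )


def call_regions(
    windows: pd.DataFrame,
    bands: CIBands,
    level: float = 0.01,
    min_consecutive: int = 3,
    merge_gap: int = 0,
) -> pd.DataFrame:
    """Candidate regions: maximal runs of at least ``min_consecutive``
    consecutive supported windows whose delta-mean falls outside the null
    band at ``level``, merged into one region per run.

    ``merge_gap`` additionally merges qualifying runs on the same
    chromosome that are separated by at most that many non-exceeding
    windows.  A strong qualitative locus drags a long linkage shoulder
    whose windowed delta hovers around the band and crosses it
    intermittently; a merge gap sized to that shoulder keeps one locus
    from being reported as several fragments while leaving well-separated
    loci distinct.  0 disables merging.

    Returns columns ``chrom, start, end, n_windows, peak_delta, level``
    (1-based inclusive coordinates; ``peak_delta`` is the largest |delta|).
    """
    regions = []
    for chrom, grp in windows.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        delta = grp["delta_mean"].to_numpy()
        depth = grp["depth_mean"].to_numpy()
        ok = ~grp["low_support"].to_numpy() & np.isfinite(delta)
        lo, hi = bands.band(level, np.where(np.isfinite(depth), depth, bands.depths[0]))
        exceed = ok & ((delta > hi) | (delta < lo))
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        runs = []  # (first window idx, last window idx) of qualifying runs
        i = 0
        while i < len(exceed):
            if exceed[i]:
                j = i
                while j + 1 < len(exceed) and exceed[j + 1]:
                    j += 1
                if j - i + 1 >= min_consecutive:
                    runs.append([i, j])
                i = j + 1
            else:
                i += 1
        if merge_gap > 0:
            merged = []
            for run in runs:
                if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
                    merged[-1][1] = run[1]
                else:
                    merged.append(run)
            runs = merged
        for i, j in runs:
            seg = slice(i, j + 1)
            peak = np.abs(delta[seg])[exceed[seg]].max()
            regions.append((chrom, int(starts[i]), int(ends[j]), j - i + 1, float(peak), level))
    return pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_windows", "peak_delta", "level"]
    )
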