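"""Delta-index scan: index arithmetic, window smoothing against a brute
force oracle, Monte-Carlo band behaviour and region calling."""

import numpy as np
import pandas as pd
import pytest

from redleaf import scan
from redleaf.simulate import sample_pool_reads, simulate_f2


def make_counts(rows):
    """rows: (chrom, pos, high_ref, high_alt, low_ref, low_alt)"""
    df = pd.DataFrame(rows, columns=["CHROM", "POS", "HIGH_REF", "HIGH_ALT", "LOW_REF", "LOW_ALT"])
    df["REF"], df["ALT"] = "G", "A"
    return df


def test_snp_index_values_and_filter():
    counts = make_counts([(1, 100, 0, 30, 30, 0), (1, 200, 3, 5, 2, 4)])
    track = scan.snp_index(counts, min_depth=10)
    high = track[track["pool"] == "high"].set_index("pos")
    assert high.loc[100, "index"] == 1.0
    assert bool(high.loc[200, "filtered"]) is True
    low = track[track["pool"] == "low"].set_index("pos")
    assert low.loc[100, "index"] == 0.0
    with pytest.raises(ValueError):
        scan.snp_index(counts, min_depth=0)


def test_delta_index_arithmetic_and_mismatch():
    counts = make_counts([(1, 100, 10, 90, 90, 10), (1, 200, 50, 50, 50, 50)])
    track = scan.delta_from_counts(counts, min_depth=10)
    assert track.set_index("pos").loc[100, "delta"] == pytest.approx(0.8)
    assert track.set_index("pos").loc[200, "delta"] == pytest.approx(0.0)
    high = scan.snp_index(counts, 10)
    high = high[high["pool"] == "high"].reset_index(drop=True)
    other = high.copy()
    other["pos"] = other["pos"] + 1
    with pytest.raises(ValueError, match="coordinates"):
        scan.delta_index(high, other)


def test_identical_pools_give_zero_delta():
    rng = np.random.default_rng(0)
    ref = rng.integers(5, 50, 200)
    alt = rng.integers(5, 50, 200)
    counts = make_counts(
        [(1, 10 * i + 10, ref[i], alt[i], ref[i], alt[i]) for i in range(200)]
    )
    track = scan.delta_from_counts(counts, min_depth=10)
    assert (track["delta"] == 0).all()


def test_pool_swap_negates_delta(small_map, arch):
    pop = simulate_f2(100, small_map, arch, seed=0)
    counts = sample_pool_reads(pop, np.arange(30), np.arange(40, 70), mean_depth=60, seed=1)
    swapped = counts.rename(
        columns={"HIGH_REF": "LOW_REF", "HIGH_ALT": "LOW_ALT",
                 "LOW_REF": "HIGH_REF", "LOW_ALT": "HIGH_ALT"}
    )
    d1 = scan.delta_from_counts(counts)
    d2 = scan.delta_from_counts(swapped)
    assert np.allclose(d1["delta"].to_numpy(), -d2["delta"].to_numpy())


def test_window_smooth_against_brute_force():
    rng = np.random.default_rng(42)
    pos = np.sort(rng.choice(np.arange(1, 10_000_001), size=100, replace=False))
    delta = rng.uniform(-1, 1, 100)
    track = pd.DataFrame(
        {"chrom": 1, "pos": pos, "delta": delta,
         "depth_high": 50, "depth_low": 50, "depth_mean": 50.0}
    )
    window, step = 2_000_000, 500_000
    win = scan.window_smooth(track, window, step, min_snps=5,
                             chrom_lengths={1: 10_000_000})
    for row in win.itertuples(index=False):
        inside = (pos >= row.start) & (pos <= row.end)
        assert row.n_snps == inside.sum()
        if inside.any():
            assert row.delta_mean == pytest.approx(delta[inside].mean())
        assert row.low_support == (inside.sum() < 5)
    # constant track: every supported window mean equals the constant
    track["delta"] = 0.37
    win = scan.window_smooth(track, window, step, min_snps=1)
    assert np.allclose(win["delta_mean"].dropna(), 0.37)
    with pytest.raises(ValueError):
        scan.window_smooth(track, 1000, 2000, 1)


def test_null_ci_normal_approximation_at_high_depth():
    """At depth 10,000 read noise vanishes; the 95% band half-width for
    50/50 F2 pools approaches 1.96 * sqrt(2/(8*50)) ~ 0.139."""
    bands = scan.simulate_null_ci(50, 50, "F2", depths=(10_000,), n_reps=20_000, seed=1)
    hw = float(bands.halfwidth(0.05, 10_000))
    assert hw == pytest.approx(1.96 * np.sqrt(2 / (8 * 50)), abs=0.008)


def test_null_ci_nesting_determinism_and_validation():
    bands = scan.simulate_null_ci(50, 50, depths=(20, 50), n_reps=2000, seed=3)
    again = scan.simulate_null_ci(50, 50, depths=(20, 50), n_reps=2000, seed=3)
    for lv in (0.05, 0.01):
        assert np.allclose(bands.upper[lv], again.upper[lv])
    for j in range(len(bands.depths)):
        assert bands.upper[0.01][j] >= bands.upper[0.05][j]
        assert bands.lower[0.01][j] <= bands.lower[0.05][j]
    with pytest.raises(ValueError):
        scan.simulate_null_ci(50, 50, depths=(0, 10), n_reps=2000)
    with pytest.raises(ValueError):
        scan.simulate_null_ci(50, 50, n_reps=10)
    with pytest.raises(ValueError):
        scan.simulate_null_ci(0, 50, n_reps=2000)


def test_f23_pooled_null_wider_than_f2():
    f2 = scan.simulate_null_ci(50, 50, "F2", depths=(100,), n_reps=10_000, seed=5)
    f23 = scan.simulate_null_ci(50, 50, "F2:3-pooled", depths=(100,), n_reps=10_000, seed=5)
    assert float(f23.halfwidth(0.05, 100)) > 2 * float(f2.halfwidth(0.05, 100))


def test_call_regions_null_and_signal(arch):
    from redleaf.simulate import MarkerMap
    from redleaf.study import SIM_SCAN

    mmap = MarkerMap.regular(arch, n_per_chrom=200)
    bands = scan.simulate_null_ci(40, 40, depths=(30, 60, 90), n_reps=5000, seed=7)
    pop = simulate_f2(400, mmap, arch, seed=8)
    rng = np.random.default_rng(9)

    def windows(counts):
        track = scan.delta_from_counts(counts)
        return scan.window_smooth(
            track, SIM_SCAN["window_bp"], SIM_SCAN["step_bp"], SIM_SCAN["min_snps"],
            chrom_lengths=pop.marker_map.chrom_lengths,
        )

    # random pools: no locus differentiates them, so no regions.  With a
    # 4x window overlap one extreme SNP sits in 4 consecutive windows, so
    # a meaningful run must outlast the overlap (min_consecutive = 5).
    ids = rng.permutation(pop.n)
    counts = sample_pool_reads(pop, ids[:40], ids[40:80], mean_depth=60, seed=10)
    null_regions = scan.call_regions(windows(counts), bands, level=0.05, min_consecutive=5)
    assert len(null_regions) == 0
    # phenotype-contrasted pools: one region, on the RLL1 chromosome,
    # containing the causal position (merge gap sized to the shoulder)
    green = np.flatnonzero(pop.colour == "green")
    red = np.flatnonzero(pop.colour != "green")
    counts = sample_pool_reads(pop, red[:40], green[:40], mean_depth=60, seed=11)
    win = windows(counts)
    regions = scan.call_regions(win, bands, level=0.01, min_consecutive=3,
                                merge_gap=SIM_SCAN["merge_gap"])
    loc = arch.locus("RLL1")
    hit = regions[(regions["chrom"] == loc.chromosome)
                  & (regions["start"] <= loc.position_bp)
                  & (regions["end"] >= loc.position_bp)]
    assert len(hit) == 1
    # empty input: no regions
    empty = win.copy()
    empty["delta_mean"] = 0.0
    assert len(scan.call_regions(empty, bands, level=0.05)) == 0


def test_call_regions_merge_gap():
    # two 3-window runs separated by a 2-window dip merge only with a gap
    delta = [0.9, 0.9, 0.9, 0.0, 0.0, 0.9, 0.9, 0.9]
    win = pd.DataFrame(
        {"chrom": 1,
         "start": np.arange(8) * 100 + 1, "end": np.arange(8) * 100 + 100,
         "n_snps": 5, "delta_mean": delta, "depth_mean": 50.0,
         "low_support": False}
    )
    bands = scan.CIBands(
        depths=np.array([50.0]), levels=(0.05,),
        lower={0.05: np.array([-0.5])}, upper={0.05: np.array([0.5])}, params={}
    )
    split = scan.call_regions(win, bands, level=0.05, min_consecutive=3)
    merged = scan.call_regions(win, bands, level=0.05, min_consecutive=3, merge_gap=2)
    assert len(split) == 2
    assert len(merged) == 1
    assert merged.iloc[0]["start"] == 1 and merged.iloc[0]["end"] == 800
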