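"""Segregation statistics, family selection and recessive-class fine
mapping, cross-checked against closed forms and independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from redleaf import mapping
from redleaf.simulate import simulate_f2
from redleaf.trait import LOCUS_NAMES


class TestChisqRatio:
    def test_printed_family_counts(self):
        # the large red:green family: 4058:1372 fits 3:1 with p > 0.5
        res = mapping.chisq_ratio((4058, 1372), (3, 1))
        assert res.chi2 == pytest.approx(0.20654, abs=1e-4)
        assert res.df == 1
        assert res.pvalue == pytest.approx(0.6495, abs=1e-3)
        assert res.pvalue > 0.5
        # the intensifier family: 195:75 light:dark red
        res = mapping.chisq_ratio((195, 75), (3, 1))
        assert res.chi2 == pytest.approx(10 / 9, abs=1e-4)
        assert res.pvalue == pytest.approx(0.2918, abs=1e-3)

    def test_exact_fit_and_corrections(self):
        res = mapping.chisq_ratio((75, 25), (3, 1))
        assert res.chi2 == 0.0 and res.pvalue == 1.0
        plain = mapping.chisq_ratio((160, 40), (3, 1))
        yates = mapping.chisq_ratio((160, 40), (3, 1), yates=True)
        assert yates.chi2 < plain.chi2

    def test_validation(self):
        with pytest.raises(ValueError):
            mapping.chisq_ratio((0, 0), (3, 1))
        with pytest.raises(ValueError):
            mapping.chisq_ratio((10, 10), (3, 1, 1))
        with pytest.raises(ValueError):
            mapping.chisq_ratio((2, 1), (9, 1))  # expected count < 1
        with pytest.warns(UserWarning):
            mapping.chisq_ratio((30, 3), (9, 1))  # expected 3.3 < 5

    def test_pvalue_against_numerical_cdf(self, rng):
        """chi-square survival probabilities agree to 1e-8 with direct
        numerical integration of the chi-square density."""

        def sf_numeric(x, k):
            dens = lambda t: t ** (k / 2 - 1) * math.exp(-t / 2) / (
                2 ** (k / 2) * math.gamma(k / 2)
            )
            val, _ = integrate.quad(dens, x, np.inf, epsabs=1e-12, limit=200)
            return val

        for _ in range(100):
            k = int(rng.integers(2, 6))
            counts = rng.integers(50, 500, size=k)
            res = mapping.chisq_ratio(counts, np.ones(k))
            assert res.pvalue == pytest.approx(sf_numeric(res.chi2, k - 1), abs=1e-8)

    def test_pvalues_uniform_under_true_ratio(self):
        """Families truly segregating 3:1 give uniform p-values."""
        rng = np.random.default_rng(99)
        n, reps = 2000, 5000
        obs = rng.binomial(n, 0.75, size=reps)
        chi2 = (obs - n * 0.75) ** 2 / (n * 0.75) + ((n - obs) - n * 0.25) ** 2 / (n * 0.25)
        pvals = stats.chi2.sf(chi2, df=1)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001
        # and the package path agrees with the vectorized computation
        res = mapping.chisq_ratio((int(obs[0]), int(n - obs[0])), (3, 1))
        assert res.pvalue == pytest.approx(float(pvals[0]), abs=1e-12)


class TestMarkerAssociation:
    def test_cosegregating_marker_is_significant(self):
        # 200 F2 plants, marker perfectly tracking a recessive trait
        genotypes = ["aa"] * 50 + ["Aa"] * 100 + ["AA"] * 50
        phenotypes = ["green"] * 50 + ["red"] * 150
        res = mapping.marker_association(genotypes, phenotypes)
        assert res.df == 2
        assert res.pvalue < 1e-6

    def test_type_one_error_calibrated(self):
        """An unlinked marker rejects at ~5% across simulated tables."""
        rng = np.random.default_rng(7)
        reps, n = 10_000, 500
        p_geno = np.array([0.25, 0.5, 0.25])
        p_joint = np.outer(p_geno, [0.5, 0.5]).ravel()
        tables = rng.multinomial(n, p_joint, size=reps).reshape(reps, 3, 2)
        rejected = 0
        for t in tables:
            res = mapping.marker_association(t)
            rejected += res.pvalue < 0.05
        assert 0.04 <= rejected / reps <= 0.06

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            mapping.marker_association(np.array([[10, 5]]))  # one genotype row
        with pytest.raises(ValueError):
            mapping.marker_association(np.array([[10, 0], [5, 0]]))  # empty column
        with pytest.raises(ValueError):
            mapping.marker_association(["Aa"] * 10, ["red"] * 10)


def test_classify_segregating_thresholds():
    assert mapping.classify_segregating({"light_red": 195, "dark_red": 75})
    assert not mapping.classify_segregating((270, 0))
    assert not mapping.classify_segregating((99, 1))  # below both minor thresholds
    assert not mapping.classify_segregating((990, 10))  # count ok, frequency not
    assert mapping.classify_segregating((95, 5))
    with pytest.raises(ValueError):
        mapping.classify_segregating((0, 0))


class TestSelectFixedBackground:
    def test_selected_f2_plants_give_3_to_1_families(self, small_map, arch):
        from redleaf.simulate import self_generation

        pop = simulate_f2(300, small_map, arch, seed=17)
        genos = pd.DataFrame(pop.causal_dosage(), columns=list(LOCUS_NAMES))
        picked = mapping.select_fixed_background(
            genos, {"RLL1": "heterozygous", "RLL2": "homozygous_functional"}
        )
        assert picked, "a 300-plant F2 should contain RLL1-het RLL2-fixed plants"
        assert (genos.loc[picked, "RLL1"] == 1).all()
        # a family from such a plant segregates green 1:3 within 3 SD
        fam = self_generation(pop, picked[0], 2000, seed=18)
        n_green = (fam.colour == "green").sum()
        assert abs(n_green - 500) < 3 * np.sqrt(2000 * 0.25 * 0.75)

    def test_order_unknown_locus_and_empty(self):
        genos = pd.DataFrame(
            {"RLL1": [2, 1, 2], "RLL2": [1, 1, 0], "RLL3": [0, 1, 2], "RLL4": [2, 2, 2]},
            index=["famA", "famB", "famC"],
        )
        assert mapping.select_fixed_background(genos, {"RLL1": "homozygous_functional"}) == [
            "famA", "famC",
        ]
        assert mapping.select_fixed_background(
            genos, {"RLL1": "homozygous_null"}
        ) == []
        with pytest.raises(KeyError):
            mapping.select_fixed_background(genos, {"RLL9": "heterozygous"})
        with pytest.raises(ValueError):
            mapping.select_fixed_background(genos, {"RLL1": "sometimes"})


class TestFineMapRecessive:
    def test_flank_extension_rule(self):
        # recombinant counts (2, 1, 0, 0, 3): zero-recombinant core is
        # markers 3-4, the interval extends to flanking markers 2 and 5
        positions = np.array([100, 200, 300, 400, 500])
        d = np.full((3, 5), 2)
        d[0, 0] = 1
        d[1, 0] = 0
        d[2, 1] = 1
        d[0, 4] = d[1, 4] = d[2, 4] = 1
        res = mapping.fine_map_recessive(d, positions, max_errors=0)
        assert list(res.recombinants) == [2, 1, 0, 0, 3]
        assert (res.start_bp, res.end_bp) == (200, 500)
        assert (res.core_start_index, res.core_end_index) == (2, 3)

    def test_all_donor_homozygous_spans_chromosome(self):
        d = np.full((10, 4), 2)
        res = mapping.fine_map_recessive(
            d, [10, 20, 30, 40], chrom=4, chrom_length_bp=1000
        )
        assert (res.start_bp, res.end_bp) == (1, 1000)

    def test_inconsistent_genotypes_error_and_max_errors(self):
        d = np.zeros((4, 3), dtype=int)
        with pytest.raises(ValueError, match="recombinants"):
            mapping.fine_map_recessive(d, [1, 2, 3])
        # one tolerated error re-admits a marker
        d = np.full((5, 3), 2)
        d[0, 1] = 1
        strict = mapping.fine_map_recessive(d, [100, 200, 300], max_errors=0)
        lax = mapping.fine_map_recessive(d, [100, 200, 300], max_errors=1)
        assert strict.width_bp <= lax.width_bp
        assert (lax.core_start_index, lax.core_end_index) == (0, 2)

    def test_validation(self):
        with pytest.raises(ValueError):
            mapping.fine_map_recessive(np.full((3, 2), 2), [5, 5])  # unordered
        with pytest.raises(ValueError):
            mapping.fine_map_recessive(np.full((0, 2), 2), [1, 2])

    def test_coverage_and_median_shrinkage(self):
        """With perfect phenotyping and a dense marker grid the interval
        contains the causal locus, and the median width falls as
        individuals are added (nested subsets per replicate)."""
        from redleaf.study import fine_map_widths

        widths = []
        for seed in range(6):
            out = fine_map_widths(seed, sizes=(25, 50, 100, 200))
            assert all(out["covered"])
            widths.append(out["widths"])
        medians = np.median(np.array(widths), axis=0)
        assert all(a >= b for a, b in zip(medians, medians[1:]))
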