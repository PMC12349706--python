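"""Tests of Perkins distance, CoC/interference and the genotype Z-tests."""

import numpy as np
import pytest

import meiocross as mc
from meiocross.classify import TetradClassCounts, tabulate
from meiocross.errors import DataError, DegenerateTestError, UndefinedCoCError
from meiocross.interference import (
    _coc_bootstrap_se,
    coc_interference,
    per_plant_and_pooled,
    perkins_distance,
    recombinant_frequencies,
    ztest_interference,
    ztest_proportions,
)


def counts_from(**kw):
    return TetradClassCounts(genotype=kw.pop("genotype", "g"), counts=kw)


class TestPerkinsDistance:
    def test_all_tetratype_is_50_cM(self):
        c = counts_from(B=100)
        assert perkins_distance(c, 1).distance == pytest.approx(50.0)

    def test_all_parental_is_zero(self):
        c = counts_from(A=500)
        est = perkins_distance(c, 1)
        assert est.distance == 0.0
        assert est.se == 0.0

    def test_direct_formula_arithmetic(self):
        # T = 120, NPD = 2, n = 1000 -> 100*(60 + 6)/1000 = 6.6 cM
        c = counts_from(A=878, B=120, D=2)
        est = perkins_distance(c, 1)
        assert est.distance == pytest.approx(6.6)
        assert (est.t_count, est.npd_count) == (120, 2)

    def test_zero_tetrads_rejected(self):
        with pytest.raises(DataError):
            perkins_distance(counts_from(), 1)

    def test_invariant_to_relabeling_within_ditypes(self):
        """Moving counts between classes with the same ditype pair (letter
        presentation) cannot change the distance."""
        a = counts_from(A=800, F=60, B=140)
        b = counts_from(A=800, G=25, H=20, I=15, B=140)
        for iv in (1, 2):
            assert perkins_distance(a, iv).distance == pytest.approx(
                perkins_distance(b, iv).distance
            )

    def test_delta_method_se_against_binomial_limit(self):
        """With NPD = 0 the SE reduces to the binomial SE of T/2."""
        c = counts_from(A=900, B=100)
        est = perkins_distance(c, 1)
        t = 0.1
        expected = 100 * np.sqrt(t * (1 - t) / 4 / 1000)
        assert est.se == pytest.approx(expected)


class TestRecombinantFrequencies:
    def test_all_parental(self):
        assert recombinant_frequencies(counts_from(A=10)) == (0.0, 0.0, 0.0)

    def test_direct_counting(self):
        # 100 tetrads: 20 recombinant only in I1, 10 only in I2, 2 in both
        c = counts_from(A=68, B=20, C=10, F=2)
        assert recombinant_frequencies(c) == pytest.approx((0.22, 0.12, 0.02))

    def test_npd_not_double_weighted(self):
        c = counts_from(A=90, D=10)
        f1, f2, f12 = recombinant_frequencies(c)
        assert f1 == pytest.approx(0.10)
        f1w, _, _ = recombinant_frequencies(c, weight_by_co=True)
        assert f1w == pytest.approx(0.20)  # the optional CO-number weighting

    def test_independence_under_poisson(self, poisson_50k_counts):
        """Non-interfering crossovers: f12 = f1*f2 within Monte-Carlo error."""
        f1, f2, f12 = recombinant_frequencies(poisson_50k_counts)
        n = poisson_50k_counts.n
        se = np.sqrt(f12 * (1 - f12) / n)
        assert abs(f12 - f1 * f2) < 3 * se


class TestCoCInterference:
    def test_exact_independence_gives_zero_interference(self):
        # f1 = 0.2, f2 = 0.1, f12 = 0.02 -> CoC = 1
        c = counts_from(A=720, B=180, C=80, F=20)
        est = coc_interference(c)
        assert est.coc == pytest.approx(1.0)
        assert est.interference == pytest.approx(0.0)

    def test_undefined_without_recombinants(self):
        with pytest.raises(UndefinedCoCError):
            coc_interference(counts_from(A=50, C=10))  # f1 = 0

    def test_no_doubles_is_flagged_interference_one(self):
        est = coc_interference(counts_from(A=80, B=10, C=10))
        assert est.interference == 1.0
        assert est.no_doubles

    def test_interference_bounds_and_monotonicity(self):
        """interference <= 1, equals 1 iff f12 = 0, and decreases as f12
        grows at fixed marginal recombinant counts."""
        values = []
        for f in (0, 5, 10, 20):
            c = counts_from(A=740 - f, B=180, C=80, F=f)
            est = coc_interference(c)
            assert est.interference <= 1.0
            values.append(est.interference)
        assert values[0] == 1.0
        assert all(hi < lo for lo, hi in zip(values, values[1:]))

    def test_delta_se_matches_bootstrap(self, ten_cm_map):
        """Delta-method SE within 15% of a 10,000-replicate tetrad bootstrap
        on a simulated 2,000-tetrad sample."""
        s = mc.simulate_sample(2000, ten_cm_map, mc.PathwayParams(), seed=77)
        counts = tabulate(s, genotype="sim")
        delta = coc_interference(counts).se_interference
        n11, n10, n01, n00 = counts.recombinant_table()
        boot = _coc_bootstrap_se(n11, n10, n01, n00, n_boot=10_000, seed=1)
        assert delta == pytest.approx(boot, rel=0.15)

    def test_estimates_near_zero_on_poisson(self, poisson_50k_counts):
        est = coc_interference(poisson_50k_counts)
        assert abs(est.interference) < 3 * est.se_interference

    def test_strictly_positive_under_interference(self, interfering_50k_counts):
        est = coc_interference(interfering_50k_counts)
        assert est.interference > 0.3
        assert est.interference > 3 * est.se_interference

    def test_monotone_in_gamma_shape(self, ten_cm_map):
        """Estimated interference is non-decreasing in nu (2 SE slack)."""
        results = []
        for i, nu in enumerate((1, 2, 4, 8, 16)):
            params = mc.PathwayParams(nu=nu, frac_class2=0.0)
            s = mc.simulate_sample(50_000, ten_cm_map, params, seed=900 + i)
            results.append(coc_interference(tabulate(s)))
        for lo, hi in zip(results, results[1:]):
            slack = 2 * np.hypot(lo.se_interference, hi.se_interference)
            assert hi.interference >= lo.interference - slack


class TestZtestProportions:
    def test_equal_proportions(self):
        res = ztest_proportions(30, 100, 60, 200)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_pooled_formula_value(self):
        """30/100 vs 10/100 under the pooled two-proportion Z; value
        cross-checked against statsmodels proportions_ztest."""
        from statsmodels.stats.proportion import proportions_ztest

        res = ztest_proportions(30, 100, 10, 100)
        assert res.statistic == pytest.approx(3.5355, abs=5e-5)
        z_sm, p_sm = proportions_ztest([30, 10], [100, 100])
        assert res.statistic == pytest.approx(z_sm)
        assert res.p_value == pytest.approx(p_sm)

    def test_group_swap_flips_sign(self):
        a = ztest_proportions(30, 100, 10, 100)
        b = ztest_proportions(10, 100, 30, 100)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_pooled_proportion(self):
        with pytest.raises(DegenerateTestError):
            ztest_proportions(0, 50, 0, 80)

    def test_input_validation(self):
        with pytest.raises(DataError):
            ztest_proportions(5, 0, 1, 10)
        with pytest.raises(DataError):
            ztest_proportions(11, 10, 1, 10)


class TestZtestInterference:
    def test_identical_tables_give_null(self):
        c = counts_from(A=720, B=180, C=80, F=20)
        res = ztest_interference(c, c)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_detects_strong_interference_difference(
        self, poisson_50k_counts, interfering_50k_counts
    ):
        res = ztest_interference(poisson_50k_counts, interfering_50k_counts)
        assert res.p_value < 1e-6

    def test_undefined_coc_propagates(self):
        good = counts_from(A=720, B=180, C=80, F=20)
        bad = counts_from(A=90, C=10)
        with pytest.raises(UndefinedCoCError):
            ztest_interference(good, bad)

    def test_power_against_interference_shift(self, ten_cm_map):
        """nu = 1 vs nu = 8 genotypes, 5,000 tetrads each: p < 0.01 in at
        least 95% of 200 replicate experiments."""
        hits = 0
        for rep in range(200):
            a = mc.simulate_sample(
                5000, ten_cm_map, mc.PathwayParams(nu=1.0, frac_class2=0.0),
                seed=10_000 + rep,
            )
            b = mc.simulate_sample(
                5000, ten_cm_map, mc.PathwayParams(nu=8.0, frac_class2=0.0),
                seed=20_000 + rep,
            )
            res = ztest_interference(tabulate(a), tabulate(b))
            hits += res.p_value < 0.01
        assert hits >= 190


class TestPerPlantAndPooled:
    def make_plants(self, n_plants, seed=0):
        imap = mc.IntervalPairMap(d1=10.0, d2=10.0)
        return [
            tabulate(
                mc.simulate_sample(600, imap, mc.PathwayParams(), seed=seed + i),
                genotype="g", plant=f"p{i}",
            )
            for i in range(n_plants)
        ]

    def test_single_plant_equals_pooled(self):
        plants = self.make_plants(1)
        s = per_plant_and_pooled(plants)
        assert s.mean_distance[0] == pytest.approx(s.pooled_distance[0].distance)
        assert s.mean_interference == pytest.approx(s.pooled_coc.interference)

    def test_identical_plants_mean_equals_pooled(self):
        c = counts_from(A=720, B=180, C=80, F=20)
        p1 = TetradClassCounts(genotype="g", counts=dict(c.counts), plant="p1")
        p2 = TetradClassCounts(genotype="g", counts=dict(c.counts), plant="p2")
        s = per_plant_and_pooled([p1, p2])
        assert s.mean_interference == pytest.approx(s.pooled_coc.interference)
        assert s.mean_distance[0] == pytest.approx(s.pooled_distance[0].distance)

    def test_pooled_within_bootstrap_error_of_plant_mean(self):
        """8 simulated plants x 600 tetrads: pooled interference within 2
        bootstrap SE of the per-plant mean."""
        plants = self.make_plants(8, seed=40)
        s = per_plant_and_pooled(plants)
        pooled = s.pooled_coc
        boot = coc_interference(
            sum(plants[1:], plants[0]), se_method="bootstrap", seed=5
        )
        assert abs(pooled.interference - s.mean_interference) < \
            2 * boot.se_interference

    def test_undefined_plants_excluded_and_logged(self):
        ok = TetradClassCounts(
            genotype="g", counts={"A": 720, "B": 180, "C": 80, "F": 20},
            plant="ok",
        )
        bad = TetradClassCounts(genotype="g", counts={"A": 100}, plant="bad")
        s = per_plant_and_pooled([ok, bad])
        assert s.excluded == ["bad"]
        assert s.mean_interference == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            per_plant_and_pooled([])
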