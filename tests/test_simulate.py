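"""Tests of the two-pathway crossover and tetrad simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import meiocross as mc
from meiocross.errors import ParameterError
from meiocross.simulate import CrossoverEvent, assign_chromatids


class TestClass1Placement:
    def test_zero_rate_gives_no_events(self, rng):
        assert mc.place_class1_crossovers(5.0, 4.0, 0.0, rng).size == 0

    @pytest.mark.parametrize(
        "span,nu,rate", [(0.0, 2.0, 1.0), (-1.0, 2.0, 1.0), (1.0, 0.0, 1.0),
                         (1.0, -3.0, 1.0), (1.0, 2.0, -0.5)]
    )
    def test_invalid_parameters_rejected(self, span, nu, rate, rng):
        with pytest.raises(ParameterError):
            mc.place_class1_crossovers(span, nu, rate, rng)

    def test_positions_ordered_within_span(self, rng):
        for _ in range(200):
            pos = mc.place_class1_crossovers(0.8, 3.0, 5.0, rng)
            assert np.all(np.diff(pos) > 0)
            assert np.all((pos >= 0) & (pos < 0.8))

    def test_poisson_special_case_mean_count(self, rng):
        """With nu = 1 the process is Poisson: mean count = rate * span."""
        counts = [
            len(mc.place_class1_crossovers(1.0, 1.0, 2.0, rng))
            for _ in range(10_000)
        ]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 2.0) < 3 * se

    def test_poisson_special_case_gaps_exponential(self, rng):
        """nu = 1 inter-event distances pass a KS test against Exp(rate)."""
        pos = mc.place_class1_crossovers(2000.0, 1.0, 2.0, rng)
        gaps = np.diff(pos)
        assert stats.kstest(gaps, "expon", args=(0, 0.5)).pvalue > 0.01

    def test_gap_coefficient_of_variation_matches_gamma(self, rng):
        """Interior gaps of the nu = 10 process have CV ~= 1/sqrt(10)."""
        pos = mc.place_class1_crossovers(5000.0, 10.0, 2.0, rng)
        gaps = np.diff(pos)
        assert len(gaps) > 9000
        cv = gaps.std() / gaps.mean()
        assert cv == pytest.approx(1 / np.sqrt(10), abs=0.01)

    def test_stationarity_mean_count_high_interference(self, rng):
        """Equilibrium first-event draw keeps E[count] = rate * span at any nu."""
        counts = [
            len(mc.place_class1_crossovers(1.0, 10.0, 2.0, rng))
            for _ in range(10_000)
        ]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 2.0) < 3 * se


class TestClass2Placement:
    def test_zero_rate_or_span(self, rng):
        assert mc.place_class2_crossovers(1.0, 0.0, rng).size == 0
        assert mc.place_class2_crossovers(0.0, 2.0, rng).size == 0

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ParameterError):
            mc.place_class2_crossovers(1.0, -1.0, rng)

    def test_poisson_mean_count(self, rng):
        counts = [
            len(mc.place_class2_crossovers(0.5, 2.0, rng))
            for _ in range(10_000)
        ]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_disjoint_subspan_counts_independent(self, rng):
        """Counts in [0, .5) and [.5, 1) are uncorrelated (Poisson property)."""
        left, right = [], []
        for _ in range(10_000):
            pos = mc.place_class2_crossovers(1.0, 3.0, rng)
            left.append(np.sum(pos < 0.5))
            right.append(np.sum(pos >= 0.5))
        r = np.corrcoef(left, right)[0, 1]
        assert abs(r) < 0.05


class TestChromatidAssignment:
    def test_no_events_unchanged(self, rng):
        assert assign_chromatids([], rng) == []

    def test_four_pairings_equiprobable(self, rng):
        draws = [
            assign_chromatids([CrossoverEvent(0.1, "class1")], rng)[0].chromatids
            for _ in range(100_000)
        ]
        values, counts = np.unique(draws, axis=0, return_counts=True)
        assert len(values) == 4
        for c in counts:
            assert c / 100_000 == pytest.approx(0.25, abs=0.005)

    def test_pairings_independent_across_events(self, rng):
        """Chi-square on the 4x4 joint table of two events is not rejected."""
        evs = [CrossoverEvent(0.1, "class1"), CrossoverEvent(0.2, "class1")]
        table = np.zeros((4, 4))
        code = {(0, 2): 0, (0, 3): 1, (1, 2): 2, (1, 3): 3}
        for _ in range(100_000):
            e1, e2 = assign_chromatids(evs, rng)
            table[code[e1.chromatids], code[e2.chromatids]] += 1
        assert stats.chi2_contingency(table).pvalue > 0.01


class TestTetradGeneration:
    def test_zero_rate_yields_parental_ditype(self, ten_cm_map, rng):
        params = mc.PathwayParams(nu=1.0, frac_class2=0.0, total_rate=0.0)
        t = mc.generate_tetrad(ten_cm_map, params, rng)
        spores = sorted(t.spores)
        assert spores == [(0, 0, 0), (0, 0, 0), (1, 1, 1), (1, 1, 1)]

    @given(st.integers(0, 10_000))
    def test_two_to_two_segregation_always(self, seed):
        imap = mc.IntervalPairMap(d1=12.0, d2=7.0, flank_left=5.0)
        rng = np.random.default_rng(seed)
        t = mc.generate_tetrad(imap, mc.PathwayParams(nu=3.0), rng)
        assert t.segregates_2to2()

    def test_sample_segregation_invariant(self, mixed_10k):
        assert (mixed_10k.spores.sum(axis=1) == 2).all()

    def test_recombinant_spore_fraction_matches_haldane(self):
        """Poisson crossovers: spore recombinant fraction between markers 1-2
        equals Haldane's r = (1 - exp(-2d))/2, d in Morgans."""
        imap = mc.IntervalPairMap(d1=6.0, d2=6.0)
        params = mc.PathwayParams(nu=1.0, frac_class2=1.0)
        s = mc.simulate_sample(20_000, imap, params, seed=7)
        rec = (s.spores[:, :, 0] != s.spores[:, :, 1]).mean(axis=1)
        expected = (1 - np.exp(-2 * 0.06)) / 2
        se = rec.std() / np.sqrt(len(rec))
        assert abs(rec.mean() - expected) < 3 * se


class TestSimulateSample:
    def test_deterministic_under_seed(self, ten_cm_map):
        p = mc.PathwayParams()
        a = mc.simulate_sample(500, ten_cm_map, p, seed=42)
        b = mc.simulate_sample(500, ten_cm_map, p, seed=42)
        assert np.array_equal(a.spores, b.spores)
        assert np.array_equal(a.class1_counts, b.class1_counts)

    def test_sample_size_validation(self, ten_cm_map):
        with pytest.raises(ParameterError):
            mc.simulate_sample(0, ten_cm_map, mc.PathwayParams(), seed=1)

    def test_class_counts_track_pathway_split(self, ten_cm_map):
        """Expected events per pathway follow the frac_class2 split."""
        p = mc.PathwayParams(nu=2.0, frac_class2=0.25, total_rate=2.0)
        s = mc.simulate_sample(30_000, ten_cm_map, p, seed=5)
        span = ten_cm_map.span_morgans
        for counts, rate in [(s.class1_counts, p.rate1),
                             (s.class2_counts, p.rate2)]:
            se = counts.std() / np.sqrt(len(counts))
            assert abs(counts.mean() - rate * span) < 3 * se

    def test_matches_scalar_generator_distribution(self, ten_cm_map):
        """The batched and per-tetrad paths draw from the same process:
        chi-square on their tetrad-class tables is not rejected."""
        from meiocross.classify import classify_sample, classify_tetrad

        params = mc.PathwayParams(nu=1.0, frac_class2=1.0)
        rng = np.random.default_rng(11)
        n = 8000
        scalar = [classify_tetrad(mc.generate_tetrad(ten_cm_map, params, rng)).label
                  for _ in range(n)]
        vector = classify_sample(mc.simulate_sample(n, ten_cm_map, params, seed=12))
        letters = sorted(set(scalar) | set(vector))
        obs = np.array([
            [scalar.count(k) for k in letters],
            [np.sum(vector == k) for k in letters],
        ])
        obs = obs[:, obs.sum(axis=0) >= 5]  # chi-square validity
        assert stats.chi2_contingency(obs).pvalue > 0.01


class TestMetaphaseSimulator:
    def test_zero_rate_all_univalents(self, rng):
        cells = mc.simulate_metaphase_cells(50, 0.0, rng)
        assert all(c.ring == c.rod == 0 and c.univalent_pairs == 5
                   for c in cells)

    def test_high_rate_all_rings_and_undercount(self, rng):
        cells = mc.simulate_metaphase_cells(200, 15.0, rng)
        assert all(c.ring == 5 for c in cells)
        est = np.mean([mc.chiasma_count(c) for c in cells])
        truth = np.mean([c.true_chiasmata for c in cells])
        assert est == 10.0
        assert est < truth

    def test_estimator_never_exceeds_truth(self, rng):
        cells = mc.simulate_metaphase_cells(500, 0.9, rng)
        assert all(mc.chiasma_count(c) <= c.true_chiasmata for c in cells)

    def test_intermediate_rate_mixes_shapes(self, rng):
        """Rates giving ~9 true chiasmata/cell produce both rings and rods."""
        cells = mc.simulate_metaphase_cells(300, 0.9, rng)
        truth = np.mean([c.true_chiasmata for c in cells])
        assert 8.0 < truth < 10.0
        assert any(c.ring > 0 for c in cells)
        assert any(c.rod > 0 for c in cells)

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ParameterError):
            mc.simulate_metaphase_cells(5, -1.0, rng)


class TestFociSimulator:
    def test_empty_and_errors(self):
        assert mc.simulate_foci(0, "poisson", {"mean": 3}, seed=1).size == 0
        with pytest.raises(ParameterError):
            mc.simulate_foci(10, "lognormal", {}, seed=1)

    def test_poisson_mean(self):
        x = mc.simulate_foci(10_000, "poisson", {"mean": 8.4}, seed=2)
        assert abs(x.mean() - 8.4) < 3 * x.std() / 100

    def test_negative_binomial_overdispersed(self):
        x = mc.simulate_foci(
            10_000, "negative_binomial", {"mean": 10.0, "dispersion": 2.0},
            seed=3,
        )
        se = x.std() / 100
        assert abs(x.mean() - 10.0) < 3 * se
        assert x.var() > 2 * x.mean()  # variance = mean + mean^2/k = 60

    def test_zero_inflated_zero_mass(self):
        x = mc.simulate_foci(
            10_000, "zero_inflated_poisson", {"pi": 0.9, "lam": 20}, seed=4
        )
        assert (x == 0).mean() >= 0.85


class TestPathwayParams:
    @pytest.mark.parametrize("kwargs", [
        {"nu": 0.0}, {"nu": -1.0}, {"frac_class2": -0.1},
        {"frac_class2": 1.2}, {"total_rate": -2.0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            mc.PathwayParams(**kwargs)

    def test_rate_split(self):
        p = mc.PathwayParams(nu=4.0, frac_class2=0.3, total_rate=2.0)
        assert p.rate1 == pytest.approx(1.4)
        assert p.rate2 == pytest.approx(0.6)


class TestIntervalPairMap:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ParameterError):
            mc.IntervalPairMap(d1=0.0)
        with pytest.raises(ParameterError):
            mc.IntervalPairMap(flank_left=-1.0)

    def test_units_and_positions(self):
        imap = mc.IntervalPairMap(d1=10.0, d2=5.0, flank_left=20.0)
        assert imap.span_morgans == pytest.approx(0.35)
        assert imap.marker_positions_morgans == pytest.approx((0.2, 0.3, 0.35))
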