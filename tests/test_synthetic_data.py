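import numpy as np
import pytest
from scipy import stats

from meiocross import genotype_blocks as gb
from meiocross import landscape as ls
from meiocross import synthetic_data as sd
from meiocross import tetrad_ftl as tf
from meiocross import coverage_profiles as cp


@pytest.fixture(scope="module")
def flat_map():
    return sd.ChromosomeMap.uniform(10_000_000, 1.0)


class TestChromosomeMap:
    def test_uniform_inversion_is_linear(self, flat_map):
        assert flat_map.genetic_to_physical(0.5) == pytest.approx(5_000_000)

    def test_intensity_integrates_to_map_length(self):
        m = sd.ChromosomeMap.from_intensity(2_000_000, [0, 1_000_000, 2_000_000], [10.0, 30.0])
        assert m.total_morgans == pytest.approx(0.4)

    def test_telomere_bias_preserves_map_length(self):
        m = sd.ChromosomeMap.telomere_biased(10_000_000, 0.8, bias=3.0)
        assert m.total_morgans == pytest.approx(0.8)
        # terminal megabase holds 3x the per-bp genetic mass of the interior
        g_end = np.interp(1_000_000, m.edges_bp, m.cum_morgans)
        g_mid = np.interp(5_500_000, m.edges_bp, m.cum_morgans) - np.interp(
            4_500_000, m.edges_bp, m.cum_morgans
        )
        assert g_end / g_mid == pytest.approx(3.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            sd.ChromosomeMap.from_intensity(100, [0, 100], [-1.0])


class TestSimulateBivalentCos:
    def test_poisson_count_at_shape_one(self, flat_map):
        rng = np.random.default_rng(0)
        counts = [len(sd.simulate_bivalent_cos(rng, flat_map, nu=1.0)) for _ in range(5000)]
        mean = np.mean(counts)
        se = np.sqrt(2.0 / 5000)  # Poisson(2) variance
        assert abs(mean - 2.0) < 3 * se
        assert np.var(counts) == pytest.approx(2.0, rel=0.15)

    def test_large_shape_is_underdispersed(self, flat_map):
        rng = np.random.default_rng(1)
        counts = [len(sd.simulate_bivalent_cos(rng, flat_map, nu=20.0)) for _ in range(3000)]
        assert np.mean(counts) == pytest.approx(2.0, abs=0.15)
        assert np.var(counts) < 0.5 * np.mean(counts)

    def test_zero_map_length_gives_no_events(self):
        empty = sd.ChromosomeMap.uniform(1_000_000, 0.0)
        rng = np.random.default_rng(2)
        assert len(sd.simulate_bivalent_cos(rng, empty, nu=1.0)) == 0

    def test_obligate_flag_guarantees_an_event(self):
        short = sd.ChromosomeMap.uniform(1_000_000, 0.05)
        rng = np.random.default_rng(3)
        for _ in range(200):
            assert len(sd.simulate_bivalent_cos(rng, short, nu=1.0, obligate=True)) >= 1

    def test_non_integer_shape_supported(self, flat_map):
        rng = np.random.default_rng(4)
        counts = [len(sd.simulate_bivalent_cos(rng, flat_map, nu=2.5)) for _ in range(800)]
        assert np.mean(counts) == pytest.approx(2.0, abs=0.2)

    def test_shape_below_one_rejected(self, flat_map):
        with pytest.raises(ValueError):
            sd.simulate_bivalent_cos(np.random.default_rng(0), flat_map, nu=0.5)


class TestMakeGametes:
    def test_no_crossovers_gives_two_of_each_parent(self):
        mei = sd.make_gametes(np.array([]), np.random.default_rng(0))
        origins = sorted(mei.gamete_origin_at(g, [500.0])[0] for g in range(4))
        assert origins == [0, 0, 1, 1]

    def test_single_crossover_makes_two_recombinants(self):
        for seed in range(20):
            mei = sd.make_gametes(np.array([100.0]), np.random.default_rng(seed))
            rec = sum(
                mei.gamete_origin_at(g, [50.0])[0] != mei.gamete_origin_at(g, [150.0])[0]
                for g in range(4)
            )
            assert rec == 2

    def test_two_crossovers_pd_tt_npd_is_1_2_1(self):
        import itertools
        from collections import Counter

        tally = Counter()
        for a in itertools.product(range(2), repeat=4):
            mei = sd.make_gametes(
                np.array([100.0, 200.0]),
                np.random.default_rng(0),
                chromatids=np.array(a).reshape(2, 2),
            )
            rec = sum(
                mei.gamete_origin_at(g, [50.0])[0] != mei.gamete_origin_at(g, [250.0])[0]
                for g in range(4)
            )
            tally[rec] += 1
        assert (tally[0], tally[2], tally[4]) == (4, 8, 4)

    def test_each_co_appears_in_exactly_two_gametes(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.uniform(0, 1000, 6))
        mei = sd.make_gametes(pos, rng)
        for p in pos:
            carriers = sum(
                mei.gamete_origin_at(g, [p - 1e-6])[0] != mei.gamete_origin_at(g, [p + 1e-6])[0]
                for g in range(4)
            )
            assert carriers == 2


class TestTetradPatterns:
    def test_no_crossover_meiosis_is_class_a(self):
        mei = sd.make_gametes(np.array([]), np.random.default_rng(0))
        pattern = sd.make_tetrad_pattern(mei, [100.0, 200.0, 300.0])
        assert tf.classify_tetrad(pattern) == "A"

    def test_co_between_first_two_colors_is_class_c(self):
        mei = sd.make_gametes(np.array([150.0]), np.random.default_rng(1))
        pattern = sd.make_tetrad_pattern(mei, [100.0, 200.0, 300.0])
        assert tf.classify_tetrad(pattern) == "C"

    def test_ftl_position_outside_chromosome_rejected(self, flat_map):
        with pytest.raises(ValueError):
            sd.simulate_tetrads(1, flat_map, [1.0, 2.0, 99_000_000.0])

    def test_poisson_class_frequencies_match_closed_form(self):
        # independent Poisson intervals: P(class A) = product of per-interval
        # PD probabilities from the chromatid Markov chain
        cmap = sd.ChromosomeMap.uniform(3_000_000, 0.3)
        ftl = (0.0, 1_000_000.0, 2_000_000.0)  # two intervals of 10 cM each
        pats = sd.simulate_tetrads(8000, cmap, ftl, nu=1.0, seed=42)
        counts = tf.classify_patterns(pats)

        T = np.array([[0, 0.25, 0], [1, 0.5, 1], [0, 0.25, 0]])
        lam = 2 * 0.1  # bivalent events per interval

        def ditype_probs():
            v = np.array([1.0, 0.0, 0.0])
            probs = np.zeros(3)
            term = np.exp(-lam)
            for k in range(60):
                probs += term * v
                term *= lam / (k + 1)
                v = T @ v
            return probs  # P(PD), P(TT), P(NPD)

    # the third color locus is independent of the first interval at nu=1
        pd_, tt, npd = ditype_probs()
        n = counts.total
        for cls, expected in [("A", pd_ * pd_), ("B", pd_ * tt), ("C", tt * pd_)]:
            obs = counts[cls]
            se = np.sqrt(n * expected * (1 - expected))
            assert abs(obs - n * expected) < 3.5 * se, cls


class TestF2Population:
    def test_zero_map_gives_single_block_per_chromosome(self, layout):
        cfg = sd.SimConfig.uniform(layout, 0.0, n_individuals=5, seed=0)
        blocks = sd.make_f2_population(cfg)
        per = blocks.df.groupby(["indiv", "chrom"]).size()
        assert (per == 1).all()
        assert set(blocks.df["state"]).issubset({"P1", "HET", "P2"})

    def test_mean_crossovers_matches_twice_map_length(self, layout):
        cfg = sd.SimConfig.uniform(layout, 4.0, n_individuals=200, seed=1)
        blocks = sd.make_f2_population(cfg)
        events = gb.crossovers_from_blocks(blocks)
        pc = gb.population_counts(events, 200, layout)
        se = np.sqrt(8.0 / 200)  # count is a sum of Poissons at nu=1
        assert abs(pc.mean - 8.0) < 3 * se

    def test_seed_determinism(self, layout):
        cfg = sd.SimConfig.uniform(layout, 2.0, n_individuals=10, seed=9)
        a = sd.make_f2_population(cfg)
        b = sd.make_f2_population(cfg)
        assert a.df.equals(b.df)

    def test_telomere_bias_shifts_events_distally(self, layout):
        n = 120
        cfg_b = sd.SimConfig.telomere_biased(layout, 4.0, bias=3.0, n_individuals=n, seed=3)
        ev = gb.crossovers_from_blocks(sd.make_f2_population(cfg_b))
        t = ls.telomere_window_counts(ev, 1_000_000, layout, n)
        density = t.counts / np.maximum(t.footprint_bp, 1)
        assert density[0] > 2 * density[1:5].mean()


class TestGradientTrack:
    def test_noiseless_track_recovers_gradient(self, layout):
        track = sd.make_gradient_track(layout, 0.0, 1.0, noise_sd=0.0, window_bp=10_000)
        prof = ls.scaled_arm_profile(track.values, layout, n_bins=10)
        good = prof.n > 0
        assert np.all(np.diff(prof.mean[good]) > 0)
        assert prof.mean[good][0] < 0.15 and prof.mean[good][-1] > 0.75

    def test_equal_endpoints_give_constant_track(self, layout):
        track = sd.make_gradient_track(layout, 2.0, 2.0, noise_sd=0.0)
        assert all(np.allclose(v, 2.0) for v in track.values.values())

    def test_replicate_tracks_correlate(self, layout):
        a = sd.make_gradient_track(layout, 0.0, 2.0, noise_sd=0.2, seed=1)
        b = sd.make_gradient_track(layout, 0.0, 2.0, noise_sd=0.2, seed=2)
        rs = cp.track_correlation(a, b, layout, "all")
        assert rs > 0.8

    def test_determinism(self, layout):
        a = sd.make_gradient_track(layout, 0.0, 1.0, noise_sd=0.3, seed=5)
        b = sd.make_gradient_track(layout, 0.0, 1.0, noise_sd=0.3, seed=5)
        assert all(np.array_equal(a.values[c], b.values[c]) for c in a.values)
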