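"""Unit and property tests of the forward simulator."""

import numpy as np
import pytest
from scipy import optimize

from idbench.simcore import (SimulationConfig, SimulationError,
                             default_scenario, dominance_rate_for_mean_h,
                             draw_mutation_effects, fitness,
                             founding_population, make_gamete,
                             next_generation, phenotype, run_replicate,
                             variable_dominance, watterson_u)

from conftest import make_population


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestConfig:
    def test_default_run_length_is_ten_n(self):
        assert SimulationConfig(N=100).generations == 1000
        assert SimulationConfig(N=10_000).generations == 50_000

    @pytest.mark.parametrize("bad", [
        dict(N=1), dict(N=50, prop_causal=1.5), dict(N=50, mean_s=0.1),
        dict(N=50, beta=0.0), dict(N=50, rho=0.0), dict(N=50, rho=1.2),
        dict(N=50, h_model="nope"),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)


class TestMutationEffects:
    def test_all_neutral_when_no_causal_fraction(self, rng):
        cfg = SimulationConfig(N=50, prop_causal=0.0)
        is_qtl, s, a, h = draw_mutation_effects(rng, cfg, size=2000)
        assert not is_qtl.any()
        assert (s == 0).all() and (a == 0).all()

    def test_causal_effect_moments_match_exponential(self, rng):
        # mean -0.03 with shape 1 implies variance mean^2 = 9e-4
        cfg = SimulationConfig(N=50, prop_causal=1.0, mean_s=-0.03, beta=1.0)
        _, s, _, _ = draw_mutation_effects(rng, cfg, size=100_000)
        assert s.mean() == pytest.approx(-0.03, rel=0.02)
        assert s.var() == pytest.approx(9e-4, rel=0.05)
        assert (s < 0).all()

    def test_perfect_pleiotropic_correlation_is_proportionality(self, rng):
        cfg = SimulationConfig(N=50, prop_causal=1.0, rho=1.0,
                               trait_scale=3.0)
        _, s, a, _ = draw_mutation_effects(rng, cfg, size=5000)
        np.testing.assert_allclose(a, 3.0 * s, rtol=1e-12)

    def test_partial_correlation_hits_target(self, rng):
        cfg = SimulationConfig(N=50, prop_causal=1.0, rho=0.5)
        _, s, a, _ = draw_mutation_effects(rng, cfg, size=60_000)
        r = np.corrcoef(np.abs(s), np.abs(a))[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)
        # marginal of a is still gamma with the configured mean
        assert a.mean() == pytest.approx(-0.03, rel=0.03)

    def test_scalar_draw_returns_record(self, rng):
        rec = draw_mutation_effects(rng, SimulationConfig(N=50))
        assert rec.s <= 0 and 0 <= rec.h <= 0.5
        assert rec.is_qtl == (rec.s < 0)


class TestVariableDominance:
    def test_neutral_effect_gives_uniform_dominance(self, rng):
        h = variable_dominance(np.zeros(50_000), rng, k=50.0)
        assert h.mean() == pytest.approx(0.5, abs=0.01)
        assert h.max() <= 1.0

    def test_strong_selection_forces_recessivity(self, rng):
        h = variable_dominance(np.full(100, -50.0), rng, k=50.0)
        assert (h < 1e-9).all()

    def test_decay_rate_matches_numeric_root(self, rng):
        # independent oracle: solve E[h] = 0.5 E[exp(-k|s|)] = 0.2 by
        # root-finding on a Monte Carlo estimate of the expectation
        mean_s, beta = -0.03, 1.0
        mags = rng.gamma(beta, abs(mean_s) / beta, size=200_000)

        def mean_h(k):
            return 0.5 * np.exp(-k * mags).mean() - 0.2

        k_oracle = optimize.brentq(mean_h, 1.0, 1e4)
        k_closed = dominance_rate_for_mean_h(mean_s, beta, 0.2)
        assert k_closed == pytest.approx(k_oracle, rel=0.02)
        h = variable_dominance(-mags[:100_000], rng, k_closed)
        assert h.mean() == pytest.approx(0.2, abs=0.005)


class TestFitnessPhenotype:
    def test_no_qtls_gives_unit_fitness_zero_trait(self):
        g = np.zeros((4, 0), dtype=np.int8)
        assert (fitness(g, np.empty(0), np.empty(0)) == 1.0).all()
        assert (phenotype(g, np.empty(0), np.empty(0)) == 0.0).all()

    def test_hand_evaluated_genotypic_values(self):
        s = np.array([-0.1]); h = np.array([0.2]); a = np.array([-1.0])
        het = np.array([[1]]); hom = np.array([[2]])
        assert fitness(het, s, h) == pytest.approx(0.98)
        assert phenotype(het, a, h) == pytest.approx(-0.2)
        assert phenotype(hom, a, h) == pytest.approx(-1.0)
        two_hom = np.array([[2, 2]])
        assert fitness(two_hom, np.array([-0.1, -0.1]),
                       np.array([0.2, 0.2])) == pytest.approx(0.81)

    def test_lethal_genotype_floors_at_zero(self):
        g = np.array([[2]])
        assert fitness(g, np.array([-1.5]), np.array([0.2])) == 0.0


class TestMakeGamete:
    def test_no_crossover_no_mutation_copies_one_strand(self, rng):
        cfg = SimulationConfig(N=10, L=100, c=0.0, U=0.0)
        pair = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        pos = np.array([10, 50, 90])
        picks = set()
        for _ in range(50):
            gamete, recs = make_gamete(pair, pos, rng, cfg)
            assert recs == []
            which = 0 if (gamete == pair[0]).all() else 1
            assert (gamete == pair[which]).all()
            picks.add(which)
        assert picks == {0, 1}  # fair coin reaches both strands

    def test_homozygous_parent_immune_to_crossover(self, rng):
        cfg = SimulationConfig(N=10, L=1000, c=0.01, U=0.0)
        pair = np.tile(np.array([1, 0, 1, 1], dtype=np.uint8), (2, 1))
        gamete, _ = make_gamete(pair, np.array([1, 200, 600, 900]), rng, cfg)
        assert (gamete == pair[0]).all()

    def test_map_length_sets_mean_crossover_count(self, rng):
        # c=1e-8 over 100 Mb is a 1 Morgan map: 1 crossover per gamete
        cfg = SimulationConfig(N=10, c=1e-8, L=100_000_000, U=0.0)
        assert cfg.crossover_rate == pytest.approx(1.0, rel=1e-6)
        counts = rng.poisson(cfg.crossover_rate, size=100_000)
        assert counts.mean() == pytest.approx(1.0, abs=0.02)

    def test_recombination_splices_parental_strands(self, rng):
        cfg = SimulationConfig(N=10, L=1000, c=5e-3, U=0.0)  # ~5 crossovers
        pair = np.vstack([np.ones(40, dtype=np.uint8),
                          np.zeros(40, dtype=np.uint8)])
        pos = np.linspace(5, 995, 40).astype(np.int64)
        gamete, _ = make_gamete(pair, pos, rng, cfg)
        # every site comes from one of the strands
        assert set(np.unique(gamete)) <= {0, 1}
        # with ~5 cuts a mosaic is overwhelmingly likely across repeats
        mosaics = sum(len(np.unique(make_gamete(pair, pos, rng, cfg)[0])) > 1
                      for _ in range(20))
        assert mosaics > 0


class TestNextGeneration:
    def test_single_fit_parent_selfs_everyone(self, rng):
        # one individual carries no lethals, everyone else is mutant-hom
        haps = np.ones((8, 1), dtype=np.uint8)
        haps[0:2] = 0
        pop = make_population(haps, is_qtl=[True], s=[-1.0], a=[-1.0])
        cfg = SimulationConfig(N=4, L=100, c=0.0, U=0.0, generations=1)
        nxt = next_generation(pop, rng, cfg)
        # the lethal allele cannot be transmitted: it is lost and swept
        assert nxt.n_sites == 0

    def test_all_zero_fitness_aborts(self, rng):
        # every individual homozygous for a lethal
        haps = np.ones((4, 1), dtype=np.uint8)
        pop = make_population(haps, is_qtl=[True], s=[-1.0], a=[-1.0])
        with pytest.raises(SimulationError):
            next_generation(pop, rng, SimulationConfig(
                N=2, L=100, c=0.0, U=0.0, generations=1))

    def test_neutral_offspring_frequency_is_unbiased(self, rng):
        # mean offspring frequency equals parental frequency under
        # neutrality (binomial sampling)
        haps = np.zeros((40, 1), dtype=np.uint8)
        haps[:16, 0] = 1  # q = 0.4
        pop = make_population(haps)
        cfg = SimulationConfig(N=20, L=100, c=0.0, U=0.0, generations=1)
        freqs = []
        for _ in range(2000):
            nxt = next_generation(pop, rng, cfg)
            if nxt.n_sites:  # loss/fixation in one step is ~impossible here
                freqs.append(nxt.haplotypes.sum() / 40)
        assert np.mean(freqs) == pytest.approx(0.4, abs=0.02)

    def test_site_bookkeeping_strictly_segregating(self, rng):
        cfg = SimulationConfig(N=20, L=500_000, U=2.0, generations=1)
        pop = founding_population(cfg)
        for _ in range(40):
            pop = next_generation(pop, rng, cfg)
            counts = pop.haplotypes.sum(axis=0)
            assert ((counts > 0) & (counts < 40)).all()
            assert (np.diff(pop.positions) > 0).all()


class TestRunReplicate:
    def test_zero_generations_returns_empty_founder(self):
        cfg = SimulationConfig(N=10, generations=0, U=1.0)
        pop, summary = run_replicate(cfg, seed=5)
        assert pop.n_sites == 0 and summary.n_neutral_snps == 0

    def test_same_seed_bit_identical(self, tiny_config):
        pop1, s1 = run_replicate(tiny_config, seed=7)
        pop2, s2 = run_replicate(tiny_config, seed=7)
        assert np.array_equal(pop1.haplotypes, pop2.haplotypes)
        assert np.array_equal(pop1.positions, pop2.positions)
        assert s1 == s2

    def test_different_seed_differs(self, tiny_config):
        pop1, _ = run_replicate(tiny_config, seed=7)
        pop2, _ = run_replicate(tiny_config, seed=8)
        assert pop1.n_sites != pop2.n_sites or not np.array_equal(
            pop1.haplotypes, pop2.haplotypes)


def test_watterson_initialisation_matches_harmonic_sum():
    # independent harmonic-sum oracle at N=100, S=30,000, all-neutral
    harmonic = sum(1.0 / i for i in range(1, 200))
    assert watterson_u(100, 30_000, 1.0) == pytest.approx(
        30_000 / (400 * harmonic), rel=1e-12)
    assert watterson_u(100, 30_000, 1.0) == pytest.approx(12.76, abs=0.05)
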