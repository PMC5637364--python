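import numpy as np
import pytest
from scipy import stats

from fraglands.connectivity import CostMatrix
from fraglands.genetics import expected_heterozygosity, observed_heterozygosity
from fraglands.landscape import SiteSet, Zone
from fraglands.simulator import (
    FEMALE,
    MALE,
    Population,
    SimulationParams,
    apply_adult_mortality,
    choose_mates,
    dispersal_weights,
    disperse_juveniles,
    init_population,
    reproduce,
    run_replicates,
    step,
)


def line_sites(n, spacing=100.0):
    xy = np.column_stack([np.arange(n) * spacing, np.zeros(n)])
    return SiteSet(np.arange(n), xy, [()] * n)


def euclid_matrix(sites, budget=np.inf):
    xy = sites.xy
    d = np.hypot(xy[:, 0][:, None] - xy[:, 0][None, :],
                 xy[:, 1][:, None] - xy[:, 1][None, :])
    d = np.where(d > budget, np.inf, d)
    np.fill_diagonal(d, 0.0)
    return CostMatrix(sites.ids, d)


SMALL = SimulationParams(n_loci=20, n_runs=2, n_generations=5)


class TestInitPopulation:
    def test_every_site_occupied_once(self, rng):
        pop = init_population(line_sites(50), SMALL, rng)
        assert pop.size == 50
        assert pop.occupied.all()

    def test_single_site(self, rng):
        pop = init_population(line_sites(1), SMALL, rng)
        assert pop.size == 1

    def test_deterministic_given_seed(self):
        a = init_population(line_sites(20), SMALL, 7)
        b = init_population(line_sites(20), SMALL, 7)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.sex, b.sex)

    def test_initial_heterozygosity_near_half(self):
        params = SimulationParams(n_loci=500)
        pop = init_population(line_sites(400), params, 1)
        assert expected_heterozygosity(pop.genotypes) == pytest.approx(0.5, abs=0.01)
        assert observed_heterozygosity(pop.genotypes) == pytest.approx(0.5, abs=0.01)

    def test_empty_sites_rejected(self, rng):
        empty = SiteSet(np.array([], dtype=int), np.zeros((0, 2)), [])
        with pytest.raises(ValueError):
            init_population(empty, SMALL, rng)


class TestDispersalWeights:
    def test_linear_kernel_shape(self):
        p = dispersal_weights(np.array([0.0, 500.0, 1000.0]), budget=1000.0)
        np.testing.assert_allclose(p, np.array([1.0, 0.5, 0.0]) / 1.5)

    def test_single_candidate_at_zero_cost(self):
        np.testing.assert_allclose(dispersal_weights(np.array([0.0]), 100.0), [1.0])

    def test_all_beyond_budget_gives_empty_distribution(self):
        p = dispersal_weights(np.array([2000.0, np.inf]), budget=1000.0)
        assert p.sum() == 0.0

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError):
            dispersal_weights(np.array([-1.0]), 100.0)

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            dispersal_weights(np.array([0.0]), 0.0)


class TestChooseMates:
    def test_single_reachable_male_sires_all(self, rng):
        sires = choose_mates(np.array([100.0]), 1000.0, 10, rng)
        assert (sires == 0).all()

    def test_no_reachable_male_gives_none(self, rng):
        assert choose_mates(np.array([np.inf, 5000.0]), 1000.0, 3, rng) is None

    def test_sire_frequencies_follow_linear_kernel(self, rng):
        # costs 0 and budget/2 -> weights 1 : 0.5 -> 2:1 sire ratio
        sires = choose_mates(np.array([0.0, 500.0]), 1000.0, 30_000, rng)
        frac = (sires == 0).mean()
        assert frac == pytest.approx(2 / 3, abs=0.01)


class TestReproduce:
    def test_homozygous_parents_breed_true(self, rng):
        mother = np.zeros((5, 2), dtype=np.int8)
        fathers = np.zeros((4, 5, 2), dtype=np.int8)
        juvs = reproduce(mother, fathers, natal_site=3, rng=rng)
        assert len(juvs) == 4
        for j in juvs:
            assert (j.genotype == 0).all()
            assert j.natal_site == 3

    def test_het_cross_segregates_1_2_1(self, rng):
        # Aa x Aa at one locus over many offspring
        mother = np.array([[0, 1]], dtype=np.int8)
        n = 100_000
        fathers = np.tile(mother, (n, 1, 1))
        juvs = reproduce(mother, fathers, 0, rng)
        genos = np.array([j.genotype.sum() for j in juvs])  # 0, 1, 2 alt copies
        counts = np.bincount(genos, minlength=3)
        chi2, p = stats.chisquare(counts, f_exp=np.array([0.25, 0.5, 0.25]) * n)
        assert p > 0.001

    def test_mean_surviving_offspring_is_three(self, rng):
        # Poisson(300) eggs thinned by 99% birth mortality -> mean 3
        params = SimulationParams()
        survive = 1 - params.birth_mortality
        n_females = 20_000
        eggs = rng.poisson(params.fecundity_lambda, size=n_females)
        survivors = rng.binomial(eggs, survive)
        expected = params.fecundity_lambda * survive
        se = np.sqrt(expected / n_females)  # thinned Poisson variance
        assert survivors.mean() == pytest.approx(expected, abs=3 * se)


class TestAdultMortality:
    def test_rate_one_kills_all(self, rng):
        pop = init_population(line_sites(30), SMALL, rng)
        assert apply_adult_mortality(pop, 1.0, rng).size == 0

    def test_rate_zero_spares_all(self, rng):
        pop = init_population(line_sites(30), SMALL, rng)
        assert apply_adult_mortality(pop, 0.0, rng).size == 30

    def test_binomial_survivor_count(self, rng):
        pop = init_population(line_sites(10_000), SMALL, rng)
        survivors = apply_adult_mortality(pop, 0.95, rng).size
        sd = np.sqrt(10_000 * 0.95 * 0.05)
        assert survivors == pytest.approx(500, abs=3 * sd)


class TestDisperseJuveniles:
    def _juvenile(self, natal, sex, n_loci=20):
        from fraglands.simulator import Juvenile

        return Juvenile(natal, sex, np.zeros((n_loci, 2), dtype=np.int8))

    def test_single_vacancy_at_zero_cost_filled(self, rng):
        sites = line_sites(2)
        pop = init_population(sites, SMALL, rng)
        pop.occupied[1] = False
        juv = self._juvenile(natal=0, sex=FEMALE)
        disperse_juveniles([juv], pop, euclid_matrix(sites), SMALL, rng)
        assert pop.occupied[1]

    def test_unreachable_vacancy_leaves_juvenile_dead(self, rng):
        sites = line_sites(2, spacing=10_000.0)
        pop = init_population(sites, SMALL, rng)
        pop.occupied[1] = False
        juv = self._juvenile(natal=0, sex=MALE)
        disperse_juveniles([juv], pop, euclid_matrix(sites), SMALL, rng)
        assert not pop.occupied[1]

    def test_capacity_limits_settlement(self, rng):
        sites = line_sites(15, spacing=10.0)
        pop = init_population(sites, SMALL, rng)
        pop.occupied[:10] = False  # 10 vacancies
        juvs = [self._juvenile(12, FEMALE) for _ in range(100)]
        disperse_juveniles(juvs, pop, euclid_matrix(sites), SMALL, rng)
        assert pop.occupied.all()

    def test_natal_site_avoided_unless_only_option(self, rng):
        # two vacancies: natal and another reachable one -> never settles natally
        sites = line_sites(3, spacing=10.0)
        for _ in range(20):
            pop = init_population(sites, SMALL, rng)
            pop.occupied[[0, 1]] = False
            juv = self._juvenile(natal=0, sex=FEMALE)
            disperse_juveniles([juv], pop, euclid_matrix(sites), SMALL, rng)
            assert pop.occupied[1] and not pop.occupied[0]
        # natal vacancy is the only reachable one -> fallback allows it
        pop = init_population(sites, SMALL, rng)
        pop.occupied[0] = False
        juv = self._juvenile(natal=0, sex=MALE)
        m = euclid_matrix(sites, budget=5.0)
        disperse_juveniles([juv], pop, m, SMALL, rng)
        assert pop.occupied[0]


class TestStep:
    def test_empty_population_stays_empty(self, rng):
        sites = line_sites(10)
        pop = init_population(sites, SMALL, rng)
        pop.occupied[:] = False
        nxt = step(pop, euclid_matrix(sites), SMALL, rng)
        assert nxt.size == 0 and nxt.generation == 1

    def test_single_sex_population_only_decays(self, rng):
        sites = line_sites(10)
        pop = init_population(sites, SMALL, rng)
        pop.sex[:] = FEMALE
        nxt = step(pop, euclid_matrix(sites), SMALL, rng)
        assert nxt.size <= pop.size

    def test_well_mixed_landscape_stays_saturated(self, rng):
        sites = line_sites(50, spacing=20.0)
        pop = init_population(sites, SMALL, rng)
        m = euclid_matrix(sites)
        for _ in range(20):
            pop = step(pop, m, SMALL, rng)
        assert pop.size >= 48  # high fecundity saturates capacity

    def test_extinct_stays_extinct_and_occupancy_bounded(self, rng):
        sites = line_sites(8, spacing=50.0)
        pop = init_population(sites, SMALL, rng)
        m = euclid_matrix(sites)
        for _ in range(30):
            pop = step(pop, m, SMALL, rng)
            assert pop.size <= 8
            if pop.size == 0:
                follow = step(pop, m, SMALL, rng)
                assert follow.size == 0
                break


class TestIsolationInvariants:
    def test_no_gene_flow_into_isolated_pair(self, rng):
        # pair (0, 1) mutually reachable but cut off from sites 2..9
        sites = line_sites(10)
        costs = np.full((10, 10), np.inf)
        np.fill_diagonal(costs, 0.0)
        costs[0, 1] = costs[1, 0] = 50.0
        block = np.hypot(*(sites.xy[2:, None, :] - sites.xy[None, 2:, :]).T).T
        costs[2:, 2:] = block
        m = CostMatrix(sites.ids, costs)
        pop = init_population(sites, SMALL, rng)
        pop.genotypes[:2] = 1  # private marker of the pair
        pop.genotypes[2:] = 0
        pop.sex[0], pop.sex[1] = FEMALE, MALE
        for _ in range(15):
            pop = step(pop, m, SMALL, rng)
            occupied_pair = np.nonzero(pop.occupied[:2])[0]
            occupied_rest = np.nonzero(pop.occupied[2:])[0] + 2
            assert all((pop.genotypes[i] == 1).all() for i in occupied_pair)
            assert all((pop.genotypes[i] == 0).all() for i in occupied_rest)

    def test_no_lost_allele_reappears(self, rng):
        sites = line_sites(30, spacing=20.0)
        pop = init_population(sites, SMALL, rng)
        m = euclid_matrix(sites)
        fixed_mask = None
        for _ in range(25):
            occ = pop.genotypes[pop.occupied]
            p = occ.mean(axis=(0, 2))
            now_fixed = (p == 0) | (p == 1)
            if fixed_mask is not None:
                assert (now_fixed | ~fixed_mask).all()  # fixation is absorbing
            fixed_mask = now_fixed if fixed_mask is None else (fixed_mask & now_fixed)
            pop = step(pop, m, SMALL, rng)

    def test_expected_heterozygosity_declines_by_drift(self, rng):
        sites = line_sites(40, spacing=20.0)
        params = SimulationParams(n_loci=100, n_runs=3, n_generations=15, seed=5)
        series = run_replicates(
            sites, [_whole_line_zone(sites)], euclid_matrix(sites), params
        )
        start = series.frame[series.frame.generation == 0].H_exp.mean()
        end = series.frame[series.frame.generation == 15].H_exp.mean()
        assert end <= start + 0.005


def _whole_line_zone(sites):
    zone = Zone("line", "L", "low", azimuth=0.0, start=-1.0,
                end=sites.xy[:, 0].max() + 1.0, width=1e6)
    sites.memberships = [("line",)] * len(sites)
    return zone


class TestBudgetReduction:
    def test_halving_budgets_never_helps_across_corridor(self, rng):
        # two 5-site clusters joined by a corridor costing ~3000: passable
        # at the normal female budget, severed at the reduced one
        xy = np.zeros((10, 2))
        xy[:5, 0] = np.arange(5) * 100.0
        xy[5:, 0] = 3000.0 + np.arange(5) * 100.0
        sites = SiteSet(np.arange(10), xy, [("line",)] * 10)
        d = np.hypot(xy[:, 0][:, None] - xy[:, 0][None, :], 0)
        m = CostMatrix(sites.ids, d)
        zone = Zone("line", "L", "low", azimuth=0.0, start=-1.0, end=4000.0,
                    width=1e6)
        base = SimulationParams(n_loci=30, n_runs=4, n_generations=25, seed=9)
        normal = run_replicates(sites, [zone], m, base)
        reduced = run_replicates(sites, [zone], m, base.reduced())
        n_normal = normal.frame[normal.frame.generation == 25].N.mean()
        n_reduced = reduced.frame[reduced.frame.generation == 25].N.mean()
        assert n_reduced <= n_normal


class TestRunReplicates:
    def test_series_shape_includes_generation_zero(self, rng):
        sites = line_sites(12, spacing=20.0)
        zone = _whole_line_zone(sites)
        params = SimulationParams(n_loci=10, n_runs=3, n_generations=4, seed=2)
        series = run_replicates(sites, [zone], euclid_matrix(sites), params)
        assert len(series.frame) == 3 * 5  # runs x (generations + 1)
        assert set(series.frame.generation) == {0, 1, 2, 3, 4}

    def test_same_master_seed_reproduces_series(self):
        sites = line_sites(12, spacing=20.0)
        zone = _whole_line_zone(sites)
        params = SimulationParams(n_loci=10, n_runs=2, n_generations=3, seed=33)
        a = run_replicates(sites, [zone], euclid_matrix(sites), params)
        b = run_replicates(sites, [zone], euclid_matrix(sites), params)
        assert a.frame.equals(b.frame)

    def test_reduced_params_halve_budgets(self):
        p = SimulationParams()
        r = p.reduced()
        assert (r.female_budget, r.male_budget) == (2000.0, 675.0)
        assert r.mating_budget == 2000.0


class TestGenotypeSnapshotIO:
    def test_round_trip(self, tmp_path, rng):
        from fraglands.io import read_genotype_snapshot, write_genotype_snapshot

        pop = init_population(line_sites(12), SMALL, rng)
        pop.occupied[3] = False
        path = tmp_path / "gen0.csv"
        write_genotype_snapshot(pop, path)
        meta, genotypes = read_genotype_snapshot(path)
        assert len(meta) == 11
        occupied = np.nonzero(pop.occupied)[0]
        np.testing.assert_array_equal(genotypes.data,
                                      pop.genotypes[occupied])
        sexes = np.where(pop.sex[occupied] == FEMALE, "F", "M")
        np.testing.assert_array_equal(meta["sex"].to_numpy(), sexes)
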