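"""Culture dynamics: exponential growth, tau-leap, mutation supply,
bottleneck dilution and wall-biofilm exchange."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from alesim import culture
from alesim.culture import (BiofilmState, MutationModel, Population, dilute,
                            grow_deterministic, grow_stochastic,
                            spawn_mutants, update_biofilm)


# ---------------------------------------------------------------------------
# deterministic growth

class TestDeterministicGrowth:
    def test_doubling_time(self):
        pop = Population.single(100.0, math.log(2))
        assert grow_deterministic(pop, 1.0).total() == pytest.approx(200.0)

    def test_zero_dt_is_identity(self, two_genotype_pop):
        out = grow_deterministic(two_genotype_pop, 0.0)
        np.testing.assert_array_equal(out.counts, two_genotype_pop.counts)

    def test_relative_growth_closed_form(self, two_genotype_pop):
        # N_b/N_a after dt hours is exp((mu_b - mu_a)*dt)
        out = grow_deterministic(two_genotype_pop, 10.0)
        assert out.counts[1] / out.counts[0] == pytest.approx(math.e,
                                                              rel=1e-12)

    def test_negative_dt_rejected(self, two_genotype_pop):
        with pytest.raises(ValueError, match="dt"):
            grow_deterministic(two_genotype_pop, -0.1)

    @given(mu=st.floats(0.0, 1.0), dt1=st.floats(0.0, 5.0),
           dt2=st.floats(0.0, 5.0))
    def test_growth_is_multiplicative(self, mu, dt1, dt2):
        pop = Population.single(123.0, mu)
        split = grow_deterministic(grow_deterministic(pop, dt1), dt2)
        joint = grow_deterministic(pop, dt1 + dt2)
        assert split.total() == pytest.approx(joint.total(), rel=1e-12)


# ---------------------------------------------------------------------------
# stochastic growth

class TestStochasticGrowth:
    def test_zero_rate_leaves_counts_unchanged(self, rng):
        pop = Population.from_arrays(np.array([500, 800], np.int64),
                                     np.zeros(2))
        out = grow_stochastic(pop, 5.0, rng)
        np.testing.assert_array_equal(out.counts, pop.counts)

    def test_cap_violation_instructs_substepping(self, rng):
        pop = Population.single(np.int64(100), 0.6)
        with pytest.raises(ValueError, match="sub-step"):
            grow_stochastic(pop, 0.5, rng)

    def test_mean_increment_matches_yule_expectation(self, rng):
        # 1e4 replicate lineages of 1e4 cells as one vectorised population
        n_rep, n0, mu, dt = 10_000, 10_000, 0.5, 0.02
        pop = Population.from_arrays(np.full(n_rep, n0, np.int64),
                                     np.full(n_rep, mu))
        out = grow_stochastic(pop, dt, rng)
        increments = out.counts - n0
        lam = n0 * math.expm1(mu * dt)
        se = math.sqrt(lam / n_rep)  # Poisson variance
        assert abs(increments.mean() - lam) < 3 * se

    def test_single_lineage_birth_probability_matches_yule(self, rng):
        # exact Yule oracle: P(birth in dt) = 1 - exp(-mu*dt) for one cell
        n_rep, mu, dt = 1_000_000, 0.5, 0.01
        pop = Population.from_arrays(np.ones(n_rep, np.int64),
                                     np.full(n_rep, mu))
        out = grow_stochastic(pop, dt, rng)
        p_hat = float(np.mean(out.counts > 1))
        p_exact = 1.0 - math.exp(-mu * dt)
        se = math.sqrt(p_exact * (1 - p_exact) / n_rep)
        assert abs(p_hat - p_exact) < 3 * se


# ---------------------------------------------------------------------------
# mutation supply

class TestSpawnMutants:
    def test_zero_rate_is_identity(self, rng):
        pop = Population.single(np.int64(10_000), 0.25)
        mm = MutationModel(rate_per_division=0.0)
        out = spawn_mutants(pop, np.array([1e6]), mm, 1.0, rng)
        assert out is pop

    def test_mean_mutant_count_is_poisson_u_D(self, rng):
        # 1e3 replicates with u*D = 10 expected mutants each
        n_rep, u, D = 1000, 1e-5, 1e6
        pop = Population.from_arrays(np.full(n_rep, 10**7, np.int64),
                                     np.full(n_rep, 0.25))
        mm = MutationModel(rate_per_division=u)
        out = spawn_mutants(pop, np.full(n_rep, D), mm, 1.0, rng)
        n_new = out.n_genotypes - n_rep
        se = math.sqrt(u * D / n_rep)
        assert abs(n_new / n_rep - u * D) < 3 * se

    def test_point_mass_effect_and_conservation(self, rng):
        pop = Population.single(np.int64(10**7), 0.25)
        mm = MutationModel(rate_per_division=1e-3, s=0.6)
        out = spawn_mutants(pop, np.array([1e4]), mm, 2.5, rng)
        assert out.n_genotypes > 1
        new = out.growth_rates[1:]
        np.testing.assert_allclose(new, 0.40, rtol=1e-12)
        assert out.total() == pop.total()  # mutants moved, not created
        g = out.genotype(int(out.ids[1]))
        assert g.parent_id == 0 and g.birth_time == 2.5


# ---------------------------------------------------------------------------
# dilution

class TestDilute:
    def test_full_survival_is_identity(self, two_genotype_pop, rng):
        out = dilute(two_genotype_pop, 1.0, None)
        np.testing.assert_array_equal(out.counts, two_genotype_pop.counts)

    @pytest.mark.parametrize("p", [0.0, -0.2, 1.5])
    def test_invalid_survival_rejected(self, two_genotype_pop, p):
        with pytest.raises(ValueError, match="survival_prob"):
            dilute(two_genotype_pop, p)

    def test_mean_survivors_binomial(self, rng):
        n_rep, n0, p = 10_000, 100_000, 0.25
        pop = Population.from_arrays(np.full(n_rep, n0, np.int64),
                                     np.zeros(n_rep))
        out = dilute(pop, p, rng)
        se = math.sqrt(n0 * p * (1 - p) / n_rep)
        assert abs(out.counts.mean() - n0 * p) < 3 * se

    def test_small_n_distribution_matches_exact_binomial_pmf(self, rng):
        # survivor histogram of Binomial(4, 0.5) vs the exact pmf
        n_rep, n0, p = 100_000, 4, 0.5
        pop = Population.from_arrays(np.full(n_rep, n0, np.int64),
                                     np.zeros(n_rep))
        survivors = np.zeros(n_rep, np.int64)
        out = dilute(pop, p, rng)
        alive = np.isin(pop.ids, out.ids)
        survivors[alive] = out.counts
        observed = np.bincount(survivors, minlength=n0 + 1)
        expected = stats.binom.pmf(np.arange(n0 + 1), n0, p) * n_rep
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_extinct_lineages_pruned_but_archived(self, rng):
        pop = Population.from_arrays(np.array([1, 10**6], np.int64),
                                     np.array([0.3, 0.3]))
        out = dilute(pop, 0.1, np.random.default_rng(0))
        assert 0 not in out.ids  # the singleton died at this seed
        g = out.genotype(0)  # still resolvable from the archive
        assert g.growth_rate == 0.3
        assert out.lineage_table().shape[0] == 2


# ---------------------------------------------------------------------------
# competition invariant

def test_two_genotype_logratio_grows_linearly_through_dilutions():
    """log(N_b/N_a) gains exactly (mu_b-mu_a)*dt; dilution never biases it."""
    pop = Population.from_arrays(np.array([1e6, 1e3]), np.array([0.3, 0.48]))
    dt, n_steps = 0.1, 200
    logratio0 = math.log(pop.counts[1] / pop.counts[0])
    for k in range(n_steps):
        pop = grow_deterministic(pop, dt)
        if k % 40 == 39:
            pop = dilute(pop, 0.25, None)
    expected = logratio0 + (0.48 - 0.30) * dt * n_steps
    assert math.log(pop.counts[1] / pop.counts[0]) == pytest.approx(
        expected, rel=1e-12)


def test_lineage_bottleneck_survival_increases_with_advantage():
    """P(single mutant cell survives a growth+bottleneck protocol) rises
    with its selective advantage s."""
    survival = []
    for i, s in enumerate([0.0, 0.2, 0.6]):
        rng = np.random.default_rng(1000 + i)
        n_rep = 3000
        pop = Population.from_arrays(np.ones(n_rep, np.int64),
                                     np.full(n_rep, 0.3 * (1 + s)))
        for _ in range(5):  # five cycles of regrowth + 1:4 bottleneck
            for _ in range(30):
                pop = grow_stochastic(pop, 0.1, rng)
            pop = dilute(pop, 0.25, rng)
        survival.append(pop.n_genotypes / n_rep)
    assert survival[0] < survival[1] < survival[2]


# ---------------------------------------------------------------------------
# biofilm

class TestBiofilm:
    def test_no_attachment_keeps_walls_clean(self):
        bf = BiofilmState(attach_rate=0.0)
        pop = Population.single(1e6, 0.0)
        for _ in range(50):
            bf, pop = update_biofilm(bf, pop, 0.1)
        assert bf.adhered("A") == 0.0

    def test_pure_attachment_is_linear_in_time(self):
        # k_s = mu_f = 0 and constant N: B(t) = k_a * N * t
        bf = BiofilmState(attach_rate=1e-6, detach_rate=0.0, growth_rate=0.0)
        n0 = 1e9
        pop = Population.single(n0, 0.0)
        dt, n_steps = 0.01, 100
        for _ in range(n_steps):
            frozen = Population.single(n0, 0.0)  # hold N constant
            bf, _ = update_biofilm(bf, frozen, dt)
        assert bf.adhered("A") == pytest.approx(1e-6 * n0 * dt * n_steps,
                                                rel=1e-9)

    @pytest.mark.parametrize("per_genotype", [False, True])
    def test_total_cells_conserved_without_growth(self, per_genotype):
        bf = BiofilmState(attach_rate=1e-3, detach_rate=0.02,
                          growth_rate=0.0, per_genotype=per_genotype)
        bf.film["A"] = 500.0
        if per_genotype:
            bf.film, bf.film_by_genotype = {"A": 0.0, "B": 0.0}, \
                {"A": {0: 300.0, 1: 200.0}, "B": {}}
        pop = Population.from_arrays(np.array([4e5, 6e5]), np.zeros(2))
        total0 = pop.total() + bf.adhered("A")
        for _ in range(20):
            bf, pop = update_biofilm(bf, pop, 0.05)
        assert pop.total() + bf.adhered("A") == pytest.approx(total0,
                                                              rel=1e-9)

    def test_cleaning_zeroes_the_chamber(self):
        bf = BiofilmState()
        bf.film["A"] = 1e7
        bf.clean("A")
        assert bf.adhered("A") == 0.0

    def test_shedding_preserves_planktonic_composition(self):
        # aggregate-mode shedding is genotype-symmetric by construction
        bf = BiofilmState(attach_rate=0.0, detach_rate=0.1, growth_rate=0.0)
        bf.film["A"] = 1e4
        pop = Population.from_arrays(np.array([3e6, 1e6]), np.zeros(2))
        f0 = pop.frequencies()
        _, out = update_biofilm(bf, pop, 0.5)
        np.testing.assert_allclose(out.frequencies(), f0, rtol=1e-12)
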