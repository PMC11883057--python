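"""Gamete production, ovule fates, donor sampling, zygotes and viability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcesim import (
    Origin,
    OvuleFate,
    draw_pollen_donor,
    fate_probabilities,
    form_zygote,
    gamete_distribution,
    init_population,
    produce_offspring_pool,
    resolve_ovule_fate,
    validate_params,
    zygote_viability,
)
from mcesim.params import TimingMode


class TestGameteDistribution:
    def test_diploid_with_reference_ug_rate(self, make_params):
        g = gamete_distribution(2, make_params(u_ug=0.012))
        assert g.mass("1n") == pytest.approx(0.988)
        assert g.mass("2n") == pytest.approx(0.012)

    def test_diploid_no_ug(self, make_params):
        g = gamete_distribution(2, make_params(u_ug=0.0))
        assert g.mass("1n") == 1.0

    def test_tetraploid_unreduced_is_4n(self, make_params):
        g = gamete_distribution(4, make_params(u_ug=0.1))
        assert g.mass("2n") == pytest.approx(0.9)
        assert g.mass("4n") == pytest.approx(0.1)

    def test_sterile_triploid(self, make_params):
        g = gamete_distribution(3, make_params(f3_fertility=0.0))
        assert g.mass("nonfunctional") == 1.0

    def test_fertile_triploid_spectrum(self, make_params):
        p = make_params(f3_fertility=0.8)
        g = gamete_distribution(3, p)
        assert g.mass("nonfunctional") == pytest.approx(0.2)
        assert g.mass("2n") == pytest.approx(0.8 * 0.375)

    def test_unknown_cytotype_rejected(self, make_params):
        with pytest.raises(ValueError):
            gamete_distribution(5, make_params())

    @settings(max_examples=50, deadline=None)
    @given(u=st.floats(0, 1), f3=st.floats(0, 1))
    def test_mass_sums_to_one(self, u, f3):
        p = validate_params({"u_ug": u, "f3_fertility": f3})
        for cyt in (2, 3, 4):
            assert gamete_distribution(cyt, p).probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestOvuleFate:
    @pytest.mark.parametrize(
        "mode,a,p,expected",
        [
            (TimingMode.delayed, 0.8, 0.9, (0.9, 0.08, 0.02)),
            (TimingMode.prior, 0.8, 0.9, (0.18, 0.8, 0.02)),
            (TimingMode.competing, 0.8, 0.9, (0.54, 0.44, 0.02)),
            (TimingMode.delayed, 1.0, 0.0, (0.0, 1.0, 0.0)),
            (TimingMode.prior, 1.0, 0.0, (0.0, 1.0, 0.0)),
        ],
    )
    def test_closed_form_probabilities(self, mode, a, p, expected):
        probs = fate_probabilities(mode, a, p)
        assert probs == pytest.approx(expected, abs=1e-15)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(0, 1),
        p=st.floats(0, 1),
        mode=st.sampled_from(list(TimingMode)),
    )
    def test_fate_probs_are_a_distribution(self, a, p, mode):
        probs = fate_probabilities(mode, a, p)
        assert all(x >= -1e-15 for x in probs)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_empirical_frequencies_match_closed_form(self, rng):
        # 10^5 single-ovule draws against the delayed-mode closed form,
        # within 4 binomial standard errors
        n = 100_000
        fates = [resolve_ovule_fate(TimingMode.delayed, 0.8, 0.9, rng) for _ in range(n)]
        for fate, p_exp in [
            (OvuleFate.outcrossed, 0.9),
            (OvuleFate.selfed, 0.08),
            (OvuleFate.unfertilized, 0.02),
        ]:
            obs = sum(f == fate for f in fates) / n
            se = np.sqrt(p_exp * (1 - p_exp) / n)
            assert abs(obs - p_exp) < 4 * se

    def test_no_pollinators_always_selfed(self, rng):
        for mode in TimingMode:
            assert resolve_ovule_fate(mode, 1.0, 0.0, rng) == OvuleFate.selfed


class TestPollenDonor:
    def _pop(self, n4, n, rng, params):
        pop = init_population(params.replace(n_adults=n, q0=n4 / n), rng)
        return pop

    def test_random_mating_matches_frequencies(self, make_params, rng):
        pop = self._pop(25, 100, rng, make_params())
        mother = int(np.flatnonzero(pop.cytotype == 4)[0])
        draws = np.array(
            [pop.cytotype[draw_pollen_donor(pop, mother, 0.0, rng)] for _ in range(20_000)]
        )
        obs = np.mean(draws == 4)
        se = np.sqrt(0.25 * 0.75 / draws.size)
        assert abs(obs - 0.25) < 4 * se

    def test_assortment_weight_algebra(self, make_params, rng):
        # alpha=1, 4x mother at 4x frequency 0.25: P(4x donor) = 0.5/1.25 = 0.4
        pop = self._pop(25, 100, rng, make_params())
        mother = int(np.flatnonzero(pop.cytotype == 4)[0])
        draws = np.array(
            [pop.cytotype[draw_pollen_donor(pop, mother, 1.0, rng)] for _ in range(20_000)]
        )
        obs = np.mean(draws == 4)
        se = np.sqrt(0.4 * 0.6 / draws.size)
        assert abs(obs - 0.4) < 4 * se

    def test_strong_assortment_limit(self, make_params, rng):
        pop = self._pop(25, 100, rng, make_params())
        mother = int(np.flatnonzero(pop.cytotype == 4)[0])
        draws = [pop.cytotype[draw_pollen_donor(pop, mother, 1e9, rng)] for _ in range(500)]
        assert np.mean(np.array(draws) == 4) > 0.99

    def test_empty_population_rejected(self, make_params, rng):
        from mcesim.params import Population

        empty = Population(
            cytotype=np.array([], dtype=np.int8),
            genet_id=np.array([], dtype=np.int64),
            fitness_deviation=0.0,
        )
        with pytest.raises(ValueError):
            draw_pollen_donor(empty, 0, 0.0, rng)


class TestZygote:
    @pytest.mark.parametrize("mg,pg,expected", [(1, 1, 2), (1, 2, 3), (2, 2, 4), (2, 4, 6)])
    def test_ploidy_is_gamete_sum(self, mg, pg, expected):
        assert form_zygote(mg, pg) == expected

    def test_nonfunctional_gamete_rejected(self):
        with pytest.raises(ValueError):
            form_zygote(0, 1)

    @pytest.mark.parametrize(
        "ploidy,t3,expected",
        [(2, 0.0, 1.0), (4, 0.0, 1.0), (3, 0.0, 0.0), (3, 0.4, 0.4), (5, 0.0, 0.0), (6, 1.0, 0.0)],
    )
    def test_viability_table(self, make_params, ploidy, t3, expected):
        p = make_params(t3_fitness=t3)
        w = zygote_viability(ploidy, Origin.outcross, 2, donor_genet=1, mother_genet=0, params=p)
        assert w == expected

    def test_self_incompatibility_zeroes_uniparental_zygotes(self, make_params):
        p = make_params(self_compatible={"2x": False, "3x": True, "4x": True})
        selfed = zygote_viability(2, Origin.selfed, 2, donor_genet=0, mother_genet=0, params=p)
        geitono = zygote_viability(2, Origin.geitonogamous, 2, donor_genet=5, mother_genet=5, params=p)
        outcross = zygote_viability(2, Origin.outcross, 2, donor_genet=7, mother_genet=5, params=p)
        assert selfed == 0.0 and geitono == 0.0 and outcross == 1.0


class TestOffspringPool:
    def test_pure_clonality_preserves_cytotypes(self, make_params, rng):
        p = make_params(c_clonal=1.0, n_adults=400, q0=0.25)
        pop = init_population(p, rng)
        pool = produce_offspring_pool(pop, p, rng)
        assert set(pool.origin.tolist()) == {Origin.clonal}
        obs = np.mean(pool.cytotype == 4)
        se = np.sqrt(0.25 * 0.75 / pool.size)
        assert abs(obs - 0.25) < 4 * se
        # clones carry their parents' genet ids
        assert set(pool.genet_id.tolist()) <= set(pop.genet_id.tolist())

    def test_no_triploids_when_blocked(self, make_params, rng):
        p = make_params(u_ug=0.0, t3_fitness=0.0, p_outcross=1.0, a_selfing=0.0, n_adults=300)
        pop = init_population(p, rng)
        pool = produce_offspring_pool(pop, p, rng)
        assert not np.any(pool.cytotype == 3)

    def test_offspring_ploidies_are_legal(self, make_params, rng):
        p = make_params(
            u_ug=0.3, t3_fitness=0.5, f3_fertility=0.5, p_outcross=0.7, a_selfing=0.5, n_adults=300
        )
        pop = init_population(p, rng)
        pool = produce_offspring_pool(pop, p, rng)
        assert set(np.unique(pool.cytotype)) <= {2, 3, 4}
        assert np.all(pool.weight > 0)

    def test_pool_4x_share_matches_enumeration(self, make_params):
        # pure outcrossing with a triploid block: expected viable 4x share is
        # q^2 / (q^2 + (1-q)^2) = 0.002762... at q=0.05 (mean-field enumeration)
        p = make_params(
            c_clonal=0.0, p_outcross=1.0, a_selfing=0.0, u_ug=0.0, t3_fitness=0.0,
            n_adults=4000, q0=0.05, fecundity_b=10.0,
        )
        rng = np.random.default_rng(77)
        shares = []
        for _ in range(10):
            pop = init_population(p, rng)
            pool = produce_offspring_pool(pop, p, rng)
            shares.append(np.mean(pool.cytotype == 4))
        expected = 0.05**2 / (0.05**2 + 0.95**2)
        assert np.mean(shares) == pytest.approx(expected, abs=3 * np.std(shares) / np.sqrt(10) + 1e-4)

    def test_sexual_offspring_get_fresh_genets(self, make_params, rng):
        p = make_params(p_outcross=1.0, a_selfing=0.0, n_adults=200, q0=0.5)
        pop = init_population(p, rng)
        pool = produce_offspring_pool(pop, p, rng)
        assert pool.genet_id.min() >= pop.next_genet_id
        assert len(set(pool.genet_id.tolist())) == pool.size

    def test_self_incompatible_population_with_no_pollinators_fails(self, make_params, rng):
        p = make_params(
            p_outcross=0.0, a_selfing=1.0, c_clonal=0.0,
            self_compatible={"2x": False, "3x": False, "4x": False},
        )
        pop = init_population(p, rng)
        pool = produce_offspring_pool(pop, p, rng)
        assert pool.size == 0
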