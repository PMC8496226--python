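"""Relatedness core: priors, site conditionals vs the enumeration oracle,
EM/SQUAREM behaviour, degenerate collapses and parameter recovery."""

from itertools import product

import numpy as np
import pytest

from admixrelate import (
    IBD_STATES,
    FreqPanel,
    ancestry_prior,
    brute_force_site_likelihood,
    em_step,
    estimate_paired_ancestry,
    estimate_relatedness,
    gen_ancestral_freqs,
    genotype_likelihoods,
    genotype_pair_prior,
    ibd_prior,
    independent_pairing,
    kinship_from_R,
    sim_reads,
    sim_relative_pair,
    site_conditionals,
    squarem_step,
)
from admixrelate.relatedness import relatedness_loglik

from conftest import random_gl_triples, random_symmetric_phi


class TestIBDPrior:
    @pytest.mark.parametrize(
        "r, expected",
        [
            ((1, 0, 0), (1, 0, 0, 0)),
            ((0, 1, 0), (0, 0.5, 0.5, 0)),
            ((0.25, 0.5, 0.25), (0.25, 0.25, 0.25, 0.25)),
        ],
    )
    def test_values(self, r, expected):
        np.testing.assert_allclose(ibd_prior(np.array(r, float)), expected)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            ibd_prior(np.array([0.5, 0.5, 0.5]))


class TestKinship:
    @pytest.mark.parametrize(
        "r, phi",
        [((1, 0, 0), 0.0), ((0, 1, 0), 0.25), ((0, 0, 1), 0.5),
         ((0.25, 0.5, 0.25), 0.25)],
    )
    def test_values(self, r, phi):
        assert kinship_from_R(np.array(r, float)) == pytest.approx(phi)


class TestAncestryPrior:
    def test_single_population_concentrates(self):
        phi = np.ones((1, 1))
        for z in IBD_STATES:
            p = ancestry_prior(z, phi, phi)
            assert p[0, 0, 0, 0] == pytest.approx(1.0)

    def test_no_sharing_uniform_product(self):
        pa = independent_pairing(np.array([0.5, 0.5]))
        p = ancestry_prior((0, 0), pa, pa)
        np.testing.assert_allclose(p, np.full((2, 2, 2, 2), 1 / 16))

    def test_one_shared_slot_uniform(self):
        pa = independent_pairing(np.array([0.5, 0.5]))
        p = ancestry_prior((1, 0), pa, pa)
        for a in product(range(2), repeat=4):
            expected = 1 / 8 if a[0] == a[2] else 0.0
            assert p[a] == pytest.approx(expected)

    @pytest.mark.parametrize("k", [1, 2, 3])
    @pytest.mark.parametrize("mode", ["mean", "indA", "indB"])
    def test_normalization_random_phis(self, rng, k, mode):
        for z in IBD_STATES:
            phiA = random_symmetric_phi(rng, k)
            phiB = random_symmetric_phi(rng, k)
            p = ancestry_prior(z, phiA, phiB, mode=mode)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0)

    def test_modes_coincide_for_shared_independent_phi(self, rng):
        pa = independent_pairing(rng.dirichlet(np.ones(3)))
        for z in IBD_STATES:
            ref = ancestry_prior(z, pa, pa, mode="mean")
            for mode in ("indA", "indB"):
                np.testing.assert_allclose(
                    ancestry_prior(z, pa, pa, mode=mode), ref, atol=1e-14
                )


class TestGenotypePairPrior:
    def test_no_sharing_half_frequency_uniform(self):
        p = genotype_pair_prior((0, 0, 0, 0), (0, 0), np.array([0.5]))
        np.testing.assert_allclose(p, np.full((2, 2, 2, 2), 1 / 16))

    def test_both_shared_two_draws(self):
        p = genotype_pair_prior((0, 1, 0, 1), (1, 1), np.array([0.2, 0.2]))
        assert p[1, 1, 1, 1] == pytest.approx(0.04)

    def test_shared_slot_forbids_state_mismatch(self):
        p = genotype_pair_prior((0, 0, 0, 1), (1, 0), np.array([0.3, 0.6]))
        # z1=1 with g1A=1, g1B=0 is impossible
        assert p[1, 0, 0, 0] == 0.0

    def test_inconsistent_ancestry_config_raises(self):
        with pytest.raises(ValueError):
            genotype_pair_prior((0, 0, 1, 0), (1, 0), np.array([0.3, 0.6]))

    def test_normalization_random(self, rng):
        for k in (1, 2, 3):
            f = rng.uniform(0.05, 0.95, size=k)
            for z in IBD_STATES:
                a = tuple(rng.integers(0, k, size=4))
                a = (a[0], a[1], a[0] if z[0] else a[2], a[1] if z[1] else a[3])
                p = genotype_pair_prior(a, z, f)
                assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestSiteConditionals:
    def test_double_missing_site_is_flat(self, rng):
        gl = np.ones((1, 3))
        freqs = FreqPanel(rng.uniform(0.1, 0.9, size=(2, 1)))
        phi = random_symmetric_phi(rng, 2)
        c = site_conditionals(gl, gl, freqs, phi, phi)
        np.testing.assert_allclose(c[0], np.ones(4), atol=1e-12)

    def test_single_population_hom_alt_closed_form(self):
        # f = 0.5, both individuals certainly hom-alt: f^4, f^3, f^3, f^2
        gl = np.array([[0.0, 0.0, 1.0]])
        freqs = FreqPanel(np.array([[0.5]]))
        phi = np.ones((1, 1))
        c = site_conditionals(gl, gl, freqs, phi, phi)
        np.testing.assert_allclose(c[0], [0.0625, 0.125, 0.125, 0.25])

    def test_single_population_half_frequency_table(self):
        # closed forms at f = 1/2 for certain genotypes, K = 1
        hom0 = [1.0, 0.0, 0.0]
        het = [0.0, 1.0, 0.0]
        hom1 = [0.0, 0.0, 1.0]
        cases = {
            ("hom0", "hom0"): (1 / 16, 1 / 8, 1 / 8, 1 / 4),
            ("het", "het"): (1 / 4, 1 / 4, 1 / 4, 1 / 2),
            ("hom0", "hom1"): (1 / 16, 0.0, 0.0, 0.0),
        }
        triples = {"hom0": hom0, "het": het, "hom1": hom1}
        freqs = FreqPanel(np.array([[0.5]]))
        phi = np.ones((1, 1))
        for (na, nb), expected in cases.items():
            c = site_conditionals(
                np.array([triples[na]]), np.array([triples[nb]]), freqs, phi, phi
            )
            np.testing.assert_allclose(c[0], expected, atol=1e-15)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_enumeration_oracle(self, rng, k):
        for _ in range(6):
            m = int(rng.integers(1, 6))
            freqs = FreqPanel(rng.uniform(0.05, 0.95, size=(k, m)))
            phiA = random_symmetric_phi(rng, k)
            phiB = random_symmetric_phi(rng, k)
            glA = random_gl_triples(rng, m)
            glB = random_gl_triples(rng, m)
            c = site_conditionals(glA, glB, freqs, phiA, phiB)
            for j in range(m):
                for zi, z in enumerate(IBD_STATES):
                    ref = brute_force_site_likelihood(
                        glA[j], glB[j], freqs.clamped[:, j], phiA, phiB, z
                    )
                    assert c[j, zi] == pytest.approx(ref, abs=1e-12)

    def test_total_probability_with_uninformative_data(self, rng):
        m = 4
        gl = np.ones((m, 3))
        freqs = FreqPanel(rng.uniform(0.05, 0.95, size=(3, m)))
        phiA = random_symmetric_phi(rng, 3)
        phiB = random_symmetric_phi(rng, 3)
        c = site_conditionals(gl, gl, freqs, phiA, phiB)
        for _ in range(5):
            r = rng.dirichlet(np.ones(3))
            np.testing.assert_allclose(c @ ibd_prior(r), np.ones(m), atol=1e-12)


class TestEMStep:
    def test_flat_conditionals_are_a_fixed_point(self, rng):
        c = np.ones((10, 4)) * rng.uniform(0.5, 2.0, size=(10, 1))
        r = rng.dirichlet(np.ones(3))
        np.testing.assert_allclose(em_step(c, r), r, atol=1e-12)

    def test_forced_posterior_mass(self):
        c = np.tile([0.0, 0.0, 0.0, 1.0], (5, 1))
        r = em_step(c, np.array([1 / 3, 1 / 3, 1 / 3]))
        np.testing.assert_allclose(r, [0, 0, 1], atol=1e-12)

    def test_three_site_hand_computation(self):
        # prior at r=(1/3,1/3,1/3) is (1/3,1/6,1/6,1/3); per-site posteriors
        # are (1/3,1/6,1/6,1/3), (0,0,0,1), (1,0,0,0); means give the update
        c = np.array([[1, 1, 1, 1], [0, 0, 0, 1], [1, 0, 0, 0]], float)
        r = em_step(c, np.array([1 / 3, 1 / 3, 1 / 3]))
        np.testing.assert_allclose(r, [4 / 9, 1 / 9, 4 / 9], atol=1e-12)

    def test_monotone_loglik(self, rng):
        c = rng.uniform(0.01, 1.0, size=(300, 4))
        r = np.array([1 / 3, 1 / 3, 1 / 3])
        ll = relatedness_loglik(c, r)
        for _ in range(100):
            r = em_step(c, r)
            new_ll = relatedness_loglik(c, r)
            assert new_ll >= ll - 1e-9
            ll = new_ll


class TestSQUAREM:
    def test_fixed_point_returns_input(self, rng):
        c = np.ones((10, 4))
        r = rng.dirichlet(np.ones(3))
        np.testing.assert_allclose(squarem_step(c, r), r, atol=1e-12)

    def test_never_below_plain_double_step(self, rng):
        for _ in range(20):
            c = rng.uniform(0.01, 1.0, size=(200, 4))
            r = rng.dirichlet(np.ones(3))
            accel = squarem_step(c, r)
            plain2 = em_step(c, em_step(c, r))
            assert relatedness_loglik(c, accel) >= relatedness_loglik(c, plain2) - 1e-9
            assert accel.min() >= 0 and abs(accel.sum() - 1) < 1e-9

    def test_same_optimum_with_and_without_acceleration(self, rng):
        freqs = gen_ancestral_freqs(3000, 2, 0.2, rng)
        qs = [np.array([0.75, 0.25]), np.array([0.25, 0.75])]
        pair = sim_relative_pair("full_sib", qs, freqs, rng)
        glA = genotype_likelihoods(sim_reads(pair.genotypes_a, 6, 0.005, rng), 0.005)
        glB = genotype_likelihoods(sim_reads(pair.genotypes_b, 6, 0.005, rng), 0.005)
        phi = independent_pairing(np.array([0.5, 0.5]))
        # drive both to a tight stationary point: plain EM's step size
        # overstates its distance from the optimum near convergence
        fast = estimate_relatedness(
            glA, glB, freqs, phi, phi, accel=True, tol=1e-8, max_iter=50_000
        )
        slow = estimate_relatedness(
            glA, glB, freqs, phi, phi, accel=False, tol=1e-8, max_iter=50_000
        )
        assert fast.converged and slow.converged
        np.testing.assert_allclose(fast.r, slow.r, atol=1e-5)
        assert fast.n_iter <= slow.n_iter


def _simulated_pair_gls(rng, relationship, m, depth, qs=None):
    freqs = gen_ancestral_freqs(m, 2, 0.15, rng)
    if qs is None:
        grid = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        nf = {"unrelated": 2, "parent_offspring": 2, "full_sib": 2}.get(
            relationship, 4
        )
        qs = [np.array([w, 1 - w]) for w in rng.choice(grid, nf)]
    pair = sim_relative_pair(relationship, qs, freqs, rng)
    glA = genotype_likelihoods(sim_reads(pair.genotypes_a, depth, 0.005, rng), 0.005)
    glB = genotype_likelihoods(sim_reads(pair.genotypes_b, depth, 0.005, rng), 0.005)
    return pair, glA, glB, freqs


class TestEstimateRelatedness:
    def test_no_sites_is_an_error(self, rng):
        freqs = FreqPanel(np.empty((2, 0)))
        phi = independent_pairing(np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            estimate_relatedness(np.empty((0, 3)), np.empty((0, 3)), freqs, phi, phi)

    def test_dimension_mismatch_is_an_error(self, rng):
        freqs = FreqPanel(rng.uniform(0.2, 0.8, size=(2, 5)))
        phi = independent_pairing(np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            estimate_relatedness(
                random_gl_triples(rng, 4), random_gl_triples(rng, 4), freqs, phi, phi
            )

    def test_pair_order_symmetry(self, rng):
        pair, glA, glB, freqs = _simulated_pair_gls(rng, "full_sib", 3000, 6)
        phiA = estimate_paired_ancestry(glA, freqs)
        phiB = estimate_paired_ancestry(glB, freqs)
        ab = estimate_relatedness(glA, glB, freqs, phiA, phiB)
        ba = estimate_relatedness(glB, glA, freqs, phiB, phiA)
        np.testing.assert_allclose(ab.r, ba.r, atol=1e-5)

    def test_per_site_gl_rescaling_is_irrelevant(self, rng):
        pair, glA, glB, freqs = _simulated_pair_gls(rng, "half_sib", 2000, 4)
        phiA = estimate_paired_ancestry(glA, freqs)
        phiB = estimate_paired_ancestry(glB, freqs)
        ref = estimate_relatedness(glA, glB, freqs, phiA, phiB)
        scaled = glA * rng.uniform(0.1, 10.0, size=(glA.shape[0], 1))
        res = estimate_relatedness(scaled, glB, freqs, phiA, phiB)
        np.testing.assert_allclose(res.r, ref.r, atol=1e-9)
        assert res.n_iter == ref.n_iter

    def test_modes_coincide_for_equal_independent_phis(self, rng):
        pair, glA, glB, freqs = _simulated_pair_gls(
            rng, "full_sib", 2000, 6, qs=[np.array([0.5, 0.5])] * 2
        )
        phi = independent_pairing(np.array([0.5, 0.5]))
        rs = [
            estimate_relatedness(glA, glB, freqs, phi, phi, mode=m).r
            for m in ("mean", "indA", "indB")
        ]
        np.testing.assert_allclose(rs[0], rs[1], atol=1e-12)
        np.testing.assert_allclose(rs[0], rs[2], atol=1e-12)

    def test_certainty_gls_match_hard_genotype_model(self, rng):
        # With indicator GLs the model collapses to the genotype-based
        # estimator; oracle: enumeration conditionals + a plain EM loop.
        freqs = gen_ancestral_freqs(500, 2, 0.2, rng)
        qs = [np.array([0.75, 0.25]), np.array([0.25, 0.75])]
        pair = sim_relative_pair("full_sib", qs, freqs, rng)
        phiA = independent_pairing(pair.qa)
        phiB = independent_pairing(pair.qb)

        def indicator(geno):
            gl = np.zeros((geno.shape[0], 3))
            gl[np.arange(geno.shape[0]), geno.sum(axis=1)] = 1.0
            return gl

        glA, glB = indicator(pair.genotypes_a), indicator(pair.genotypes_b)
        res = estimate_relatedness(glA, glB, freqs, phiA, phiB, accel=False)

        c = np.array(
            [
                [
                    brute_force_site_likelihood(
                        glA[j], glB[j], freqs.clamped[:, j], phiA, phiB, z
                    )
                    for z in IBD_STATES
                ]
                for j in range(500)
            ]
        )
        r = np.array([1 / 3, 1 / 3, 1 / 3])
        for _ in range(5000):
            prior = np.array([r[0], r[1] / 2, r[1] / 2, r[2]])
            w = c * prior
            g = (w / w.sum(axis=1, keepdims=True)).mean(axis=0)
            new = np.array([g[0], g[1] + g[2], g[3]])
            if np.linalg.norm(new - r) < 1e-6:
                r = new
                break
            r = new
        np.testing.assert_allclose(res.r, r, atol=1e-6)

    def test_parent_offspring_recovery_high_depth(self, rng):
        pair, glA, glB, freqs = _simulated_pair_gls(
            rng, "parent_offspring", 100_000, 16
        )
        phiA = estimate_paired_ancestry(glA, freqs)
        phiB = estimate_paired_ancestry(glB, freqs)
        res = estimate_relatedness(glA, glB, freqs, phiA, phiB)
        assert abs(res.k1 - 1.0) < 0.02

    def test_full_sib_recovers_realized_ibd_high_depth(self, rng):
        # realized IBD fractions, not the pedigree expectation, are the
        # estimand for an individual pair
        pair, glA, glB, freqs = _simulated_pair_gls(rng, "full_sib", 100_000, 16)
        phiA = estimate_paired_ancestry(glA, freqs)
        phiB = estimate_paired_ancestry(glB, freqs)
        res = estimate_relatedness(glA, glB, freqs, phiA, phiB)
        np.testing.assert_allclose(res.r, pair.realized_r, atol=0.02)
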