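import itertools

import numpy as np
import pytest
from scipy import stats as sps

from knockloc import simulate as sim
from knockloc.hmm import HaplotypeHMM, haplotype_loglik, sample_haplotypes
from knockloc.knockoffs import (
    MarkovChain,
    exact_joint_pmf_small,
    genotype_knockoffs_from_phased,
    hmm_group_knockoffs,
    knockoff_path_logprob,
    posterior_chain,
    sample_group_knockoff_chain,
)
from knockloc.partition import Partition

from conftest import contiguous_partitions


def _partition(groups, positions=None):
    groups = np.asarray(groups)
    pos = np.arange(1, groups.size + 1) if positions is None else positions
    return Partition(groups, pos, 0.0)


class TestChainKnockoffs:
    def test_deterministic_chain_copies_the_path(self):
        # point-mass transitions force z-tilde == z
        init = np.array([1.0, 0.0])
        trans = np.tile(np.eye(2), (3, 1, 1))
        chain = MarkovChain(init, trans)
        z = np.zeros(4, dtype=int)
        for groups in ([1, 1, 1, 1], [1, 1, 2, 2], [1, 2, 3, 4]):
            zt = sample_group_knockoff_chain(chain, z, _partition(groups), seed=1)
            assert np.array_equal(zt, z)

    def test_single_group_draws_independent_copy(self):
        # one group spanning all sites: z-tilde ~ chain law, independent of z
        rng = np.random.default_rng(3)
        init = rng.dirichlet([2, 2])
        trans = np.stack([rng.dirichlet([2, 2], size=2) for _ in range(2)])
        chain = MarkovChain(init, trans)
        part = _partition([1, 1, 1])
        n = 6000
        counts = np.zeros((2, 8))  # first-site state of z vs full z-tilde
        rng2 = np.random.default_rng(5)
        for i in range(n):
            z = [int(np.searchsorted(np.cumsum(init), rng2.random()))]
            for j in range(2):
                z.append(int(np.searchsorted(np.cumsum(trans[j][z[-1]]), rng2.random())))
            zt = sample_group_knockoff_chain(chain, np.array(z), part, seed=int(rng2.integers(2**31)))
            counts[z[0], int(zt @ np.array([4, 2, 1]))] += 1
        _, pval, *_ = sps.chi2_contingency(counts)
        assert pval > 0.001

    def test_singleton_groups_swap_invariance_exact(self, tiny_model3):
        # enumerate the sampler's conditionals: law of (z, zt) invariant to
        # swapping any single coordinate
        h = np.array([1, 0, 1], dtype=np.int8)
        chain = posterior_chain(tiny_model3, h)
        part = _partition([1, 2, 3])
        paths = list(itertools.product(range(2), repeat=3))
        joint = {}
        for z in paths:
            pz = chain.init[z[0]] * chain.trans[0][z[0], z[1]] * chain.trans[1][z[1], z[2]]
            for zt in paths:
                lp = knockoff_path_logprob(chain, np.array(z), np.array(zt), part)
                joint[z, zt] = pz * np.exp(lp)
        for j in range(3):
            for z in paths:
                for zt in paths:
                    zs, zts = list(z), list(zt)
                    zs[j], zts[j] = zts[j], zs[j]
                    assert joint[z, zt] == pytest.approx(
                        joint[tuple(zs), tuple(zts)], abs=1e-10
                    )


class TestExactJointPmf:
    def test_normalization_and_marginals(self, tiny_model3):
        part = _partition([1, 1, 2])
        table, _ = exact_joint_pmf_small(tiny_model3, part)
        assert table.sum() == pytest.approx(1.0, abs=1e-10)
        # marginal law of the knockoff equals the marginal law of the original
        assert np.allclose(table.sum(axis=0), table.sum(axis=1), atol=1e-10)

    def test_group_swap_symmetry(self, tiny_model3):
        for groups in contiguous_partitions(3):
            part = _partition(groups)
            table, haps = exact_joint_pmf_small(tiny_model3, part)
            for sl in part.group_slices():
                swapped = np.zeros_like(table)
                for a, ha in enumerate(haps):
                    for b, hb in enumerate(haps):
                        hswap = ha.copy()
                        tswap = hb.copy()
                        hswap[sl], tswap[sl] = hb[sl], ha[sl].copy()
                        ai = int("".join(map(str, hswap)), 2)
                        bi = int("".join(map(str, tswap)), 2)
                        swapped[a, b] = table[ai, bi]
                assert np.abs(swapped - table).max() < 1e-10

    def test_instance_size_guard(self):
        model = sim.synthetic_hmm(p=6, K=2, seed=1)
        with pytest.raises(ValueError, match="too large"):
            exact_joint_pmf_small(model, _partition(np.ones(6, dtype=int)))


class TestHaplotypeKnockoffs:
    def test_full_recombination_singletons_match_marginals(self):
        # r == 1: each knockoff column is an independent redraw of the
        # site's marginal mixture
        p, K = 5, 3
        rng = np.random.default_rng(11)
        model = HaplotypeHMM(
            alpha=rng.dirichlet(np.ones(K) * 3, size=p),
            theta=rng.uniform(0.2, 0.8, (p, K)),
            r=np.ones(p),
            positions=np.arange(1, p + 1),
        )
        H, _ = sample_haplotypes(model, 10_000, seed=13)
        part = _partition(np.arange(1, p + 1))
        Ht = hmm_group_knockoffs(model, H, part, seed=17)
        expected = np.einsum("jk,jk->j", model.alpha, model.theta)
        se = np.sqrt(expected * (1 - expected) / H.shape[0])
        assert np.all(np.abs(Ht.mean(axis=0) - expected) < 3 * se + 1e-12)

    def test_whole_chromosome_group_matches_fresh_samples(self):
        model = sim.synthetic_hmm(p=30, K=3, seed=19)
        H, _ = sample_haplotypes(model, 3000, seed=23)
        part = _partition(np.ones(30, dtype=int), model.positions)
        Ht = hmm_group_knockoffs(model, H, part, seed=29)
        fresh, _ = sample_haplotypes(model, 3000, seed=31)
        stat = sps.ks_2samp(haplotype_loglik(model, Ht), haplotype_loglik(model, fresh))
        assert stat.pvalue > 0.001

    def test_batch_sampler_matches_enumerated_conditionals(self, tiny_model4):
        # fix one haplotype and one latent path; the vectorized sampler's
        # empirical law of z-tilde must match the generic sampler's exact law
        from knockloc.hmm import _backward, _forward
        from knockloc.knockoffs import _batch_knockoff_paths

        m = tiny_model4
        h = np.array([1, 0, 1, 1], dtype=np.int8)
        part = _partition([1, 1, 2, 2], m.positions)
        chain = posterior_chain(m, h)
        z = np.array([0, 1, 1, 0])
        paths = np.array(list(itertools.product(range(2), repeat=4)))
        exact = np.array(
            [np.exp(knockoff_path_logprob(chain, z, zt, part)) for zt in paths]
        )
        assert exact.sum() == pytest.approx(1.0, abs=1e-10)
        n = 40_000
        H = np.tile(h, (n, 1))
        _, c, _ = _forward(m, H)
        b = _backward(m, H, c)
        Zt = _batch_knockoff_paths(
            m, H, b, np.tile(z, (n, 1)).astype(np.int32), part,
            np.random.default_rng(37),
        )
        codes = Zt @ (2 ** np.arange(4)[::-1])
        emp = np.bincount(codes, minlength=16) / n
        se = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(emp - exact) < 4 * se + 1e-4)


class TestGenotypeKnockoffs:
    def test_zero_model_gives_zero_knockoffs(self):
        p = 4
        model = HaplotypeHMM(
            alpha=np.ones((p, 1)),
            theta=np.zeros((p, 1)),
            r=np.r_[1.0, np.full(p - 1, 0.3)],
            positions=np.arange(1, p + 1),
        )
        H = np.zeros((10, p), dtype=np.int8)
        ks = genotype_knockoffs_from_phased(model, H, _partition([1, 1, 2, 2]), 1)
        assert not ks.X_tilde.any()

    def test_odd_row_count_rejected(self, tiny_model4):
        H = np.zeros((3, 4), dtype=np.int8)
        with pytest.raises(ValueError, match="even"):
            genotype_knockoffs_from_phased(tiny_model4, H, _partition([1, 1, 1, 1]), 1)

    def test_moments_and_ld_match_originals(self):
        # n=2000, p=100 fixture: knockoffs must reproduce means, variances,
        # and the local LD profile of the originals
        model = sim.synthetic_hmm(p=100, K=4, seed=41)
        H, X = sim.simulate_genotypes(model, 2000, seed=43)
        groups = np.repeat(np.arange(1, 21), 5)
        ks = genotype_knockoffs_from_phased(
            model, H, _partition(groups, model.positions), 47
        )
        Xt = ks.X_tilde.astype(float)
        Xf = X.astype(float)
        se_mean = Xf.std(axis=0) / np.sqrt(X.shape[0])
        assert np.all(np.abs(Xt.mean(0) - Xf.mean(0)) < 4 * se_mean + 1e-12)
        assert np.all(np.abs(Xt.var(0) - Xf.var(0)) < 0.15)
        from knockloc.partition import ld_r2

        r2x = ld_r2(Xf, window=10).r2
        r2t = ld_r2(Xt, window=10).r2
        band = np.triu(np.ones_like(r2x, dtype=bool), 1) & ~np.triu(
            np.ones_like(r2x, dtype=bool), 11
        )
        assert np.abs(r2t[band] - r2x[band]).mean() < 0.05

    def test_runtime_scales_linearly_in_p(self):
        import time

        times = []
        for p in (200, 800):
            model = sim.synthetic_hmm(p=p, K=3, seed=53)
            H, _ = sample_haplotypes(model, 200, seed=59)
            part = _partition(np.repeat(np.arange(1, p // 10 + 1), 10), model.positions)
            t0 = time.time()
            hmm_group_knockoffs(model, H, part, seed=61)
            times.append(time.time() - t0)
        # 4x the sites should cost well under 16x (i.e., subquadratic)
        assert times[1] < 8 * times[0] + 0.1
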