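"""Group knockoffs for haplotypes distributed as a hidden Markov model.

Knockoffs are synthetic negative-control variables: for a partition G of the
variants, a group knockoff X-tilde of X satisfies (1) it is constructed
without looking at the phenotype, and (2) the joint law of (X, X-tilde) is
invariant when any group's coordinates are swapped between X and X-tilde.

Construction for one haplotype h under the haplotype-cluster HMM:

1. draw a latent cluster path z from the exact posterior P(Z | h);
2. draw a knockoff path z-tilde of z with respect to the (inhomogeneous)
   Markov law of Z given h, group by group along the genome: each group's
   states are sampled jointly from the knockoff conditional given z and the
   previously sampled knockoff groups, with the group-internal normalizing
   functions propagated by dynamic programming (sequential conditional
   independent pairs); the total cost is O(p K^2) per haplotype;
3. re-emit alleles at the knockoff states from the emission frequencies.

A vectorized implementation processes all haplotypes of a dataset at once in
O(p K) per haplotype by exploiting the jump-persist structure of the
transition matrices.  An exact enumeration of the sampler's conditional
probabilities on tiny models serves as an oracle for the exchangeability
contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._utils import as_rng
from .hmm import HaplotypeHMM, _backward, _check_binary, _emission, _forward, \
    _sample_posterior_paths, _sample_rows
from .partition import Partition

__all__ = [
    "MarkovChain",
    "KnockoffSet",
    "sample_group_knockoff_chain",
    "knockoff_path_logprob",
    "hmm_group_knockoffs",
    "genotype_knockoffs_from_phased",
    "exact_joint_pmf_small",
    "posterior_chain",
]


@dataclass
class MarkovChain:
    """Inhomogeneous finite Markov chain: init (K,), trans (p-1, K, K)."""

    init: np.ndarray
    trans: np.ndarray  # trans[j] maps state at site j to site j+1

    @property
    def p(self) -> int:
        return self.trans.shape[0] + 1

    @property
    def K(self) -> int:
        return self.init.shape[0]


@dataclass
class KnockoffSet:
    """Knockoff genotypes aligned column-wise to the originals."""

    X_tilde: np.ndarray  # (n, p) in {0,1,2}
    partition: Partition
    seed: int
    provenance: str = "phased"


def posterior_chain(model: HaplotypeHMM, h: np.ndarray) -> MarkovChain:
    """Markov law of the latent path given one haplotype, as dense matrices.

    Intended for small instances (tests, oracles); the production path never
    materializes these matrices.
    """
    h = _check_binary(np.atleast_2d(h))
    _, c, _ = _forward(model, h)
    b = _backward(model, h, c)
    p, K = model.p, model.K
    init = model.alpha[0] * _emission(model, 0, h[:, 0])[0] * b[0, 0]
    init = init / init.sum()
    trans = np.empty((p - 1, K, K))
    for j in range(1, p):
        u = (_emission(model, j, h[:, j]) * b[j])[0]
        rj = model.r[j]
        Q = (1.0 - rj) * np.eye(K) * u[None, :] + rj * model.alpha[j][None, :] * u[None, :]
        s = Q.sum(axis=1, keepdims=True)
        if np.any(s <= 0):
            raise ValueError("zero-probability path in posterior chain")
        trans[j - 1] = Q / s
    return MarkovChain(init, trans)


def _group_bounds(partition: Partition) -> list[tuple[int, int]]:
    return [(sl.start, sl.stop - 1) for sl in partition.group_slices()]


def _knockoff_chain_pass(chain: MarkovChain, z, partition, rng=None, given=None):
    """Shared DP for sampling a knockoff path or scoring a given one.

    Processes the groups left to right.  For group [s, e] the conditional of
    the knockoff states v_{s:e} is proportional to

        psi(v_s) * prod_{j=s+1}^{e} Q_{j}(v_{j-1}, v_j) * Q_{e+1}(v_e, z_{e+1})

    where psi(v) = Q_s(z_{s-1}, v) * Q_s(zt_{s-1}, v) / N_prev(v) links to the
    original path and to the previous group's knockoff states through its
    normalizing function N_prev, itself computed by a forward recursion over
    the previous group.  Returns (z_tilde, logprob).
    """
    z = np.asarray(z, dtype=int)
    p, K = chain.p, chain.K
    if z.shape != (p,):
        raise ValueError("path length does not match chain")
    if partition.p != p:
        raise ValueError("partition does not cover the chain sites")
    zt = np.empty(p, dtype=int)
    logprob = 0.0
    N_prev = None
    for s, e in _group_bounds(partition):
        # boundary factor psi at the group's first site
        if s == 0:
            psi = chain.init.copy()
        else:
            Q = chain.trans[s - 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                psi = Q[z[s - 1]] * Q[zt[s - 1]] / N_prev
            psi[~np.isfinite(psi)] = 0.0
        # backward messages within the group
        b = np.empty((e - s + 1, K))
        b[-1] = chain.trans[e][:, z[e + 1]] if e < p - 1 else 1.0
        for j in range(e - 1, s - 1, -1):
            v = chain.trans[j] @ b[j - s + 1]
            m = v.max()
            b[j - s] = v / m if m > 0 else v
        # sample (or score) forward through the group
        w = psi * b[0]
        tot = w.sum()
        if tot <= 0:
            raise ValueError("zero-probability path in knockoff sampling")
        if given is None:
            zt[s] = _sample_rows(w[None, :], rng)[0]
        else:
            zt[s] = given[s]
            logprob += np.log(w[zt[s]] / tot) if w[zt[s]] > 0 else -np.inf
        for j in range(s + 1, e + 1):
            w = chain.trans[j - 1][zt[j - 1]] * b[j - s]
            tot = w.sum()
            if tot <= 0:
                raise ValueError("zero-probability path in knockoff sampling")
            if given is None:
                zt[j] = _sample_rows(w[None, :], rng)[0]
            else:
                zt[j] = given[j]
                logprob += np.log(w[zt[j]] / tot) if w[zt[j]] > 0 else -np.inf
        # normalizing function N_g(x) for the next group's boundary factor
        if e < p - 1:
            f = psi
            for j in range(s, e):
                f = f @ chain.trans[j]
                m = f.sum()
                f = f / m  # scale freely; only ratios across x matter
            N_prev = f @ chain.trans[e]
    return zt, logprob


def sample_group_knockoff_chain(
    chain: MarkovChain, z: np.ndarray, partition: Partition, seed
) -> np.ndarray:
    """Sample a group-knockoff copy of the latent path ``z``.

    The output satisfies group-swap exchangeability: for every group G of the
    partition, the joint law of (z, z-tilde) is unchanged when the
    coordinates in G are swapped.
    """
    rng = as_rng(seed)
    zt, _ = _knockoff_chain_pass(chain, z, partition, rng=rng)
    return zt


def knockoff_path_logprob(
    chain: MarkovChain, z: np.ndarray, z_tilde: np.ndarray, partition: Partition
) -> float:
    """Exact log P(z-tilde | z) under the knockoff sampler (oracle support)."""
    _, lp = _knockoff_chain_pass(chain, z, partition, given=np.asarray(z_tilde))
    return lp


# ---------------------------------------------------------------------------
# Vectorized HMM path: all haplotypes at once, O(p K) per haplotype
# ---------------------------------------------------------------------------


def hmm_group_knockoffs(
    model: HaplotypeHMM, H: np.ndarray, partition: Partition, seed
) -> np.ndarray:
    """Generate knockoff haplotypes H-tilde for every row of ``H``.

    Implements posterior path sampling, the group-knockoff chain pass, and
    allele re-emission in one vectorized sweep over sites.  The phenotype is
    never an input anywhere in this module.
    """
    H = _check_binary(H)
    if H.shape[1] != model.p:
        raise ValueError("haplotype width does not match model")
    if partition.p != model.p:
        raise ValueError("partition does not cover the model sites")
    rng = as_rng(seed)
    _, c, _ = _forward(model, H)
    b = _backward(model, H, c)
    Z = _sample_posterior_paths(model, H, b, rng)
    Zt = _batch_knockoff_paths(model, H, b, Z, partition, rng)
    n, p = H.shape
    probs = model.theta[np.arange(p)[None, :], Zt]
    return (rng.random((n, p)) < probs).astype(np.int8)


def _post_u(model, H, b, j):
    """Unnormalized posterior emission-times-backward weights at site j: (n,K)."""
    return _emission(model, j, H[:, j]) * b[j]


def _post_trans_apply_rows(model, H, b, j, z_col):
    """Rows Q-hat_j(z_col, .) of the posterior transition into site j: (n, K).

    Q-hat_j(a, v) = Q_j(a, v) u_j(v) / d_j(a); the row normalizer d_j(a) is a
    constant in v and is omitted (callers renormalize).
    """
    n = H.shape[0]
    u = _post_u(model, H, b, j)
    rj = model.r[j]
    w = rj * model.alpha[j][None, :] * u
    idx = np.arange(n)
    w[idx, z_col] += (1.0 - rj) * u[idx, z_col]
    return w


def _post_trans_rownorm(model, H, b, j):
    """d_j(i, v) = sum_x Q_j(v, x) u_j(i, x), for all states v: (n, K)."""
    u = _post_u(model, H, b, j)
    rj = model.r[j]
    mix = u @ model.alpha[j]
    return (1.0 - rj) * u + rj * mix[:, None]


def _batch_knockoff_paths(model, H, b, Z, partition, rng):
    """Group-knockoff chain pass for all haplotypes at once.

    Mirrors :func:`_knockoff_chain_pass` on the posterior chain of Z given
    each haplotype, using the jump-persist transition structure so every
    per-site update costs O(n K).
    """
    n, p = H.shape
    K = model.K
    idx = np.arange(n)
    Zt = np.empty((n, p), dtype=np.int32)
    N_prev = None
    for s, e in _group_bounds(partition):
        # --- boundary factor psi (n, K)
        if s == 0:
            psi = model.alpha[0][None, :] * _post_u(model, H, b, 0)
        else:
            qa = _post_trans_apply_rows(model, H, b, s, Z[:, s - 1])
            qb = _post_trans_apply_rows(model, H, b, s, Zt[:, s - 1])
            with np.errstate(divide="ignore", invalid="ignore"):
                psi = qa * qb / N_prev
            psi[~np.isfinite(psi)] = 0.0
        psi = psi / psi.sum(axis=1, keepdims=True)
        # --- backward messages within the group (w+1, n, K)
        w_len = e - s + 1
        bk = np.empty((w_len, n, K))
        if e < p - 1:
            re1 = model.r[e + 1]
            d = _post_trans_rownorm(model, H, b, e + 1)
            num = np.repeat(
                (re1 * model.alpha[e + 1][Z[:, e + 1]])[:, None], K, axis=1
            )
            num[idx, Z[:, e + 1]] += 1.0 - re1
            bk[-1] = num / d
        else:
            bk[-1] = 1.0
        for j in range(e, s, -1):
            u = _post_u(model, H, b, j)
            d = _post_trans_rownorm(model, H, b, j)
            ub = u * bk[j - s]
            mix = np.einsum("nk,k->n", ub, model.alpha[j])
            v = ((1.0 - model.r[j]) * ub + model.r[j] * mix[:, None]) / d
            bk[j - s - 1] = v / v.max(axis=1, keepdims=True)
        # --- forward sampling through the group
        wgt = psi * bk[0]
        Zt[:, s] = _sample_rows(wgt, rng)
        for j in range(s + 1, e + 1):
            q = _post_trans_apply_rows(model, H, b, j, Zt[:, j - 1])
            Zt[:, j] = _sample_rows(q * bk[j - s], rng)
        # --- forward normalizing function for the next group's boundary
        if e < p - 1:
            f = psi
            for j in range(s + 1, e + 1):
                u = _post_u(model, H, b, j)
                d = _post_trans_rownorm(model, H, b, j)
                g = f / d
                mix = g.sum(axis=1)
                f = u * ((1.0 - model.r[j]) * g + model.r[j] * model.alpha[j][None, :] * mix[:, None])
                f = f / f.sum(axis=1, keepdims=True)
            u = _post_u(model, H, b, e + 1)
            d = _post_trans_rownorm(model, H, b, e + 1)
            g = f / d
            N_prev = u * (
                (1.0 - model.r[e + 1]) * g
                + model.r[e + 1] * model.alpha[e + 1][None, :] * g.sum(axis=1)[:, None]
            )
    return Zt


def genotype_knockoffs_from_phased(
    model: HaplotypeHMM, H: np.ndarray, partition: Partition, seed: int
) -> KnockoffSet:
    """Knockoff genotypes from phased haplotypes (2 consecutive rows/sample).

    Each haplotype receives its own knockoff given its own latent posterior;
    the knockoff genotype is the within-individual sum, so no implicit
    re-phasing of the genotypes is ever needed.
    """
    H = _check_binary(H)
    if H.shape[0] % 2 != 0:
        raise ValueError("phased input needs an even number of haplotype rows")
    Ht = hmm_group_knockoffs(model, H, partition, seed)
    X_tilde = (Ht[0::2] + Ht[1::2]).astype(np.int8)
    return KnockoffSet(X_tilde=X_tilde, partition=partition, seed=int(seed))


# ---------------------------------------------------------------------------
# Exact enumeration oracle for tiny models
# ---------------------------------------------------------------------------


def exact_joint_pmf_small(model: HaplotypeHMM, partition: Partition):
    """Exact joint pmf table P(h, h-tilde) on a tiny model, by enumeration.

    Enumerates the sampler's own conditional probabilities (no Monte Carlo):
    P(h, ht) = sum_z sum_zt P(h) P(z|h) K_h(zt|z) P(ht|zt).  Returns
    (table, haplotype list); the table is 2^p x 2^p and sums to 1.
    """
    p, K = model.p, model.K
    if p > 4 or K > 3:
        raise ValueError("instance too large for exact enumeration")
    haps = np.array(list(itertools.product((0, 1), repeat=p)), dtype=np.int8)
    paths = np.array(list(itertools.product(range(K), repeat=p)), dtype=int)
    # emission matrix E[path, hap] = P(h | z)
    E = np.ones((len(paths), len(haps)))
    for j in range(p):
        th = model.theta[j][paths[:, j]]
        E *= np.where(haps[None, :, j] == 1, th[:, None], 1.0 - th[:, None])
    from .hmm import haplotype_loglik

    ph = np.exp(haplotype_loglik(model, haps))
    table = np.zeros((len(haps), len(haps)))
    for hi, h in enumerate(haps):
        chain = posterior_chain(model, h)
        pz = chain.init[paths[:, 0]].copy()
        for j in range(1, p):
            pz *= chain.trans[j - 1][paths[:, j - 1], paths[:, j]]
        mt = np.zeros(len(paths))
        for zi, z in enumerate(paths):
            if pz[zi] <= 0:
                continue
            for ti, zt in enumerate(paths):
                lp = knockoff_path_logprob(chain, z, zt, partition)
                if np.isfinite(lp):
                    mt[ti] += pz[zi] * np.exp(lp)
        table[hi] = ph[hi] * (mt @ E)
    return table, haps
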