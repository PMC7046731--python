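"""Haplotype-cluster hidden Markov model of linkage disequilibrium.

Each haplotype is modeled as a mosaic of K latent ancestral clusters.  At
variant j the latent cluster either persists from site j-1 (probability
1 - r[j]) or "jumps" (a recombination event, probability r[j]) to a cluster
drawn from the local cluster weights alpha[j].  Given the cluster k, the
alternate allele is emitted with frequency theta[j, k].  This is the classic
fastPHASE-style model; it captures local LD but not long-range structure.

All recursions are scaled per site, so likelihoods are stable for very long
chromosomes; EM fitting, exact per-haplotype likelihoods, forward sampling,
and posterior (backward-sampling) path draws are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import as_rng

__all__ = [
    "HaplotypeHMM",
    "fit_hmm_em",
    "haplotype_loglik",
    "sample_haplotypes",
    "posterior_latent_sample",
    "posterior_latent_sample_batch",
    "write_hmm",
    "read_hmm",
]

_ATOL = 1e-8


@dataclass
class HaplotypeHMM:
    """Parameters of the haplotype-cluster HMM.

    Attributes
    ----------
    alpha : (p, K) array
        Per-site cluster weights; each row is a probability vector.  Row 0 is
        the initial cluster distribution; row j is the jump destination law.
    theta : (p, K) array
        Per-site, per-cluster alternate-allele emission frequencies in [0, 1].
    r : (p,) array
        Per-site jump (recombination) probabilities; ``r[0] == 1`` by
        convention (the first site always "jumps" from nothing).
    positions : (p,) array
        1-based base-pair coordinates, strictly increasing.
    chromosome : str
        Chromosome label.
    loglik_history : array or None
        Per-iteration total log-likelihood of the EM run that produced this
        model (populated by :func:`fit_hmm_em`).
    """

    alpha: np.ndarray
    theta: np.ndarray
    r: np.ndarray
    positions: np.ndarray
    chromosome: str = "1"
    loglik_history: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.validate()

    @property
    def p(self) -> int:
        return self.alpha.shape[0]

    @property
    def K(self) -> int:
        return self.alpha.shape[1]

    def validate(self):
        p, K = self.alpha.shape
        if K < 1:
            raise ValueError("need at least one cluster")
        if self.theta.shape != (p, K):
            raise ValueError("theta shape mismatch")
        if self.r.shape != (p,):
            raise ValueError("r shape mismatch")
        if self.positions.shape != (p,):
            raise ValueError("positions shape mismatch")
        if not np.allclose(self.alpha.sum(axis=1), 1.0, atol=_ATOL):
            raise ValueError("alpha rows must sum to 1")
        if np.any((self.theta < -_ATOL) | (self.theta > 1 + _ATOL)):
            raise ValueError("theta must lie in [0, 1]")
        if np.any((self.r < -_ATOL) | (self.r > 1 + _ATOL)):
            raise ValueError("r must lie in [0, 1]")
        if abs(self.r[0] - 1.0) > _ATOL:
            raise ValueError("r[0] must equal 1")
        if p > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def _check_binary(H: np.ndarray) -> np.ndarray:
    H = np.asarray(H)
    if H.ndim != 2:
        raise ValueError("haplotype matrix must be 2-D")
    if not np.isin(H, (0, 1)).all():
        raise ValueError("haplotype matrix must be binary {0,1}")
    return H.astype(np.int8)


def _emission(model: HaplotypeHMM, j: int, hj: np.ndarray) -> np.ndarray:
    """Emission probabilities at site j for allele column hj: (n, K)."""
    th = model.theta[j]
    return np.where(hj[:, None] == 1, th[None, :], 1.0 - th[None, :])


def _forward(model: HaplotypeHMM, H: np.ndarray, keep: bool = False):
    """Scaled forward pass, vectorized over haplotypes.

    Returns (fhat, c, loglik): fhat is the list of scaled forward vectors
    (only if ``keep``), c the (p, n) scale factors, loglik the per-haplotype
    log-likelihoods.
    """
    n, p = H.shape
    K = model.K
    c = np.empty((p, n))
    fhat_all = np.empty((p, n, K)) if keep else None
    f = model.alpha[0][None, :] * _emission(model, 0, H[:, 0])
    for j in range(p):
        if j > 0:
            rj = model.r[j]
            pred = (1.0 - rj) * f + rj * model.alpha[j][None, :]
            f = pred * _emission(model, j, H[:, j])
        cj = f.sum(axis=1)
        if np.any(cj <= 0):
            raise ValueError(
                "haplotype has zero probability under the model "
                "(impossible observation)"
            )
        f = f / cj[:, None]
        c[j] = cj
        if keep:
            fhat_all[j] = f
    loglik = np.log(c).sum(axis=0)
    return fhat_all, c, loglik


def _backward(model: HaplotypeHMM, H: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Scaled backward messages beta-hat, shape (p, n, K).

    Scaling uses the forward scale factors so that gamma = fhat * bhat is the
    normalized posterior state distribution at each site.
    """
    n, p = H.shape
    K = model.K
    b = np.empty((p, n, K))
    b[p - 1] = 1.0
    for j in range(p - 1, 0, -1):
        u = _emission(model, j, H[:, j]) * b[j]
        rj = model.r[j]
        mix = u @ model.alpha[j]
        b[j - 1] = ((1.0 - rj) * u + rj * mix[:, None]) / c[j][:, None]
    return b


def haplotype_loglik(model: HaplotypeHMM, H: np.ndarray) -> np.ndarray:
    """Exact log-likelihood of each haplotype row under the model."""
    H = _check_binary(H)
    if H.shape[1] != model.p:
        raise ValueError("haplotype width does not match model")
    _, _, ll = _forward(model, H)
    return ll


def sample_haplotypes(model: HaplotypeHMM, n_hap: int, seed):
    """Draw ``n_hap`` haplotypes from the model.

    Returns ``(H, Z)`` where Z holds the latent cluster paths actually used
    for emission.
    """
    if n_hap < 1:
        raise ValueError("n_hap must be >= 1")
    rng = as_rng(seed)
    p, K = model.p, model.K
    Z = np.empty((n_hap, p), dtype=np.int32)
    cum0 = np.cumsum(model.alpha[0])
    Z[:, 0] = np.searchsorted(cum0, rng.random(n_hap), side="right")
    for j in range(1, p):
        jump = rng.random(n_hap) < model.r[j]
        Z[:, j] = Z[:, j - 1]
        if jump.any():
            cum = np.cumsum(model.alpha[j])
            Z[jump, j] = np.searchsorted(cum, rng.random(jump.sum()), side="right")
    probs = model.theta[np.arange(p)[None, :], Z]
    H = (rng.random((n_hap, p)) < probs).astype(np.int8)
    return H, Z


def posterior_latent_sample_batch(model: HaplotypeHMM, H: np.ndarray, seed):
    """Sample one latent path per haplotype from P(Z | H), vectorized.

    Uses backward messages plus a forward (left-to-right) sampling sweep
    through the posterior chain, which is the form also needed by the
    knockoff machinery.
    """
    H = _check_binary(H)
    rng = as_rng(seed)
    _, c, _ = _forward(model, H)
    b = _backward(model, H, c)
    return _sample_posterior_paths(model, H, b, rng), b


def _sample_posterior_paths(model, H, b, rng) -> np.ndarray:
    n, p = H.shape
    Z = np.empty((n, p), dtype=np.int32)
    w = model.alpha[0][None, :] * _emission(model, 0, H[:, 0]) * b[0]
    Z[:, 0] = _sample_rows(w, rng)
    idx = np.arange(n)
    for j in range(1, p):
        u = _emission(model, j, H[:, j]) * b[j]
        rj = model.r[j]
        w = rj * model.alpha[j][None, :] * u
        w[idx, Z[:, j - 1]] += (1.0 - rj) * u[idx, Z[:, j - 1]]
        Z[:, j] = _sample_rows(w, rng)
    return Z


def _sample_rows(w: np.ndarray, rng) -> np.ndarray:
    """Sample one index per row proportionally to the row weights."""
    tot = w.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("zero-probability observation in posterior sampling")
    cdf = np.cumsum(w, axis=1)
    u = rng.random((w.shape[0], 1)) * tot
    return (cdf < u).sum(axis=1).astype(np.int32)


def posterior_latent_sample(model: HaplotypeHMM, h: np.ndarray, seed) -> np.ndarray:
    """Draw a single latent path from the exact posterior P(Z | h)."""
    h = np.atleast_2d(h)
    Z, _ = posterior_latent_sample_batch(model, h, seed)
    return Z[0]


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def fit_hmm_em(
    H: np.ndarray,
    K: int,
    max_iter: int = 50,
    tol: float = 1e-4,
    n_restarts: int = 3,
    seed: int = 0,
    positions: np.ndarray | None = None,
    chromosome: str = "1",
) -> HaplotypeHMM:
    """Fit the haplotype-cluster HMM by EM (Baum-Welch) with random restarts.

    The restart with the highest final log-likelihood is returned; its
    per-iteration log-likelihood trace is stored in ``loglik_history`` and is
    non-decreasing by construction of EM.

    Parameters
    ----------
    H : (n_hap, p) binary matrix of haplotypes (no missing entries).
    K : number of latent clusters.
    max_iter : maximum EM iterations per restart.
    tol : stop when the total log-likelihood improves by less than this.
    n_restarts : number of random initializations.
    seed : master seed for the initializations.
    """
    H = _check_binary(H)
    n, p = H.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if K > n:
        raise ValueError("degenerate model: K exceeds the number of haplotypes")
    if positions is None:
        positions = np.arange(1, p + 1, dtype=np.int64)

    rng = as_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        model = _init_model(p, K, rng, positions, chromosome)
        model, history = _em_run(model, H, max_iter, tol)
        if best is None or history[-1] > best.loglik_history[-1]:
            model.loglik_history = np.asarray(history)
            best = model
    return best


def _init_model(p, K, rng, positions, chromosome) -> HaplotypeHMM:
    theta = rng.uniform(0.1, 0.9, size=(p, K))
    alpha = np.full((p, K), 1.0 / K)
    r = np.full(p, 0.1)
    r[0] = 1.0
    return HaplotypeHMM(alpha, theta, r, positions, chromosome)


def _em_run(model: HaplotypeHMM, H: np.ndarray, max_iter: int, tol: float):
    n, p = H.shape
    K = model.K
    history = []
    for _ in range(max_iter):
        fhat, c, ll = _forward(model, H, keep=True)
        history.append(float(ll.sum()))
        b = _backward(model, H, c)
        gamma = fhat * b  # (p, n, K), rows sum to 1

        theta_num = np.einsum("jnk,nj->jk", gamma, H.astype(float))
        theta_den = gamma.sum(axis=1)
        theta = model.theta.copy()
        ok = theta_den > 1e-12
        theta[ok] = theta_num[ok] / theta_den[ok]
        np.clip(theta, 1e-12, 1 - 1e-12, out=theta)

        alpha = model.alpha.copy()
        r = model.r.copy()
        alpha[0] = gamma[0].sum(axis=0) / n
        for j in range(1, p):
            u = _emission(model, j, H[:, j]) * b[j]
            # expected jump-to-k counts at site j summed over haplotypes
            Jk = model.r[j] * model.alpha[j][None, :] * u / c[j][:, None]
            Jk = Jk.sum(axis=0)
            U = Jk.sum()
            r[j] = min(max(U / n, 0.0), 1.0)
            if U > 1e-12:
                alpha[j] = Jk / U
        alpha /= alpha.sum(axis=1, keepdims=True)

        model = HaplotypeHMM(alpha, theta, r, model.positions, model.chromosome)
        if len(history) >= 2 and history[-1] - history[-2] < tol:
            break
    _, _, ll = _forward(model, H)
    history.append(float(ll.sum()))
    return model, history


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------


def write_hmm(model: HaplotypeHMM, path):
    """Write the model to a plain-text parameter file (bit-exact round-trip)."""
    with open(path, "w") as fh:
        fh.write(f"#haplotype-hmm K={model.K} p={model.p} chrom={model.chromosome}\n")
        fh.write("#position r alpha[1..K] theta[1..K]\n")
        for j in range(model.p):
            vals = [repr(float(model.r[j]))]
            vals += [repr(float(v)) for v in model.alpha[j]]
            vals += [repr(float(v)) for v in model.theta[j]]
            fh.write(f"{model.positions[j]}\t" + "\t".join(vals) + "\n")


def read_hmm(path) -> HaplotypeHMM:
    """Read a model written by :func:`write_hmm`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#haplotype-hmm"):
            raise ValueError("not a haplotype-hmm parameter file")
        meta = dict(tok.split("=") for tok in header.split()[1:])
        K, p = int(meta["K"]), int(meta["p"])
        chrom = meta["chrom"]
        fh.readline()  # column comment
        positions = np.empty(p, dtype=np.int64)
        r = np.empty(p)
        alpha = np.empty((p, K))
        theta = np.empty((p, K))
        for j in range(p):
            parts = fh.readline().split("\t")
            positions[j] = int(parts[0])
            r[j] = float(parts[1])
            alpha[j] = [float(v) for v in parts[2 : 2 + K]]
            theta[j] = [float(v) for v in parts[2 + K : 2 + 2 * K]]
    return HaplotypeHMM(alpha, theta, r, positions, chrom)
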