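"""Group importance statistics from sparse regression on [Z, X, X-tilde].

A cross-validated lasso (linear for continuous traits, logistic for binary
ones) is fitted to the augmented design of covariates, genotypes, and
knockoff genotypes.  Covariate coefficients are unpenalized and ignored in
the statistics.  The importance of group g is T_g = sum of |beta_j| over its
original columns, T~_g likewise over knockoff columns, and the test statistic
is the antisymmetric contrast W_g = T_g - T~_g: a null group's W is
symmetrically distributed around zero because its columns are exchangeable
with their knockoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from ._utils import as_rng, standardize_columns
from .knockoffs import KnockoffSet
from .partition import Partition

__all__ = [
    "LassoConfig",
    "Design",
    "ImportanceStats",
    "build_design",
    "fit_sparse_regression",
    "group_importance",
    "compute_W",
    "importance_stats",
]

# covariate columns are multiplied by this factor before an L1 logistic fit,
# making their effective penalty negligible (the linear fit profiles them out
# exactly instead)
_COV_SCALE = 1e4


@dataclass
class LassoConfig:
    """Cross-validated lasso settings.

    lambda_min_ratio scales the smallest penalty on the grid relative to the
    smallest penalty that zeroes every genetic coefficient; the grid is
    log-spaced.  The rule is minimum CV deviance.  ``lambda_override`` skips
    CV and fits at a fixed penalty (as a fraction of lambda_max).
    """

    family: str = "gaussian"  # "gaussian" | "binary"
    n_folds: int = 5
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-4
    fold_seed: int = 0
    standardize: bool = True
    max_iter: int = 3000
    lambda_override: float | None = None

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.family not in ("gaussian", "binary"):
            raise ValueError("family must be 'gaussian' or 'binary'")


@dataclass
class Design:
    """Augmented design matrix with its column bookkeeping.

    ``original_cols[j]`` / ``knockoff_cols[j]`` give the design column of
    variant j's original / knockoff copy; the within-pair order was
    randomized so a solver's positional tie-breaking cannot favor originals.
    """

    matrix: np.ndarray  # (n, m + 2p)
    n_covariates: int
    original_cols: np.ndarray  # (p,)
    knockoff_cols: np.ndarray  # (p,)
    dropped: np.ndarray  # boolean (2p over variant copies) — zero variance

    @property
    def p(self) -> int:
        return self.original_cols.size


@dataclass
class ImportanceStats:
    """Per-group importance measures at one resolution."""

    T: np.ndarray
    T_tilde: np.ndarray
    W: np.ndarray
    lambda_cv: float
    beta: np.ndarray = field(repr=False, default=None)  # (m + 2p,) design scale

    def __post_init__(self):
        if np.any(self.T < 0) or np.any(self.T_tilde < 0):
            raise ValueError("importance measures must be non-negative")


def build_design(
    Z: np.ndarray | None, X: np.ndarray, X_tilde, seed
) -> Design:
    """Assemble [Z, interleaved (X_j, X~_j) pairs] with standardized columns.

    Genotype and knockoff columns are standardized to mean 0 / variance 1;
    the order of each (original, knockoff) pair is randomized with the given
    seed and recorded in the column map.  Zero-variance columns are kept as
    zeros (their coefficient, hence importance contribution, is exactly 0).
    """
    if isinstance(X_tilde, KnockoffSet):
        X_tilde = X_tilde.X_tilde
    X = np.asarray(X, dtype=float)
    X_tilde = np.asarray(X_tilde, dtype=float)
    if X.shape != X_tilde.shape:
        raise ValueError("X and X_tilde must be aligned")
    n, p = X.shape
    if Z is None:
        Z = np.empty((n, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] != n:
        raise ValueError("covariate rows do not match samples")
    rng = as_rng(seed)
    Xs, keep_x = standardize_columns(X)
    Ts, keep_t = standardize_columns(X_tilde)
    if not (keep_x.all() and keep_t.all()):
        import warnings

        warnings.warn("zero-variance genotype column(s): importance fixed at 0")
    m = Z.shape[1]
    mat = np.empty((n, m + 2 * p))
    mat[:, :m] = Z
    flip = rng.random(p) < 0.5
    original_cols = np.empty(p, dtype=np.int64)
    knockoff_cols = np.empty(p, dtype=np.int64)
    for j in range(p):
        a, b = m + 2 * j, m + 2 * j + 1
        if flip[j]:
            a, b = b, a
        mat[:, a] = Xs[:, j]
        mat[:, b] = Ts[:, j]
        original_cols[j] = a
        knockoff_cols[j] = b
    dropped = np.zeros(2 * p, dtype=bool)
    dropped[original_cols - m] = ~keep_x
    dropped[knockoff_cols - m] = ~keep_t
    return Design(mat, m, original_cols, knockoff_cols, dropped)


def _lambda_grid(lam_max: float, cfg: LassoConfig) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def fit_sparse_regression(design: Design, y: np.ndarray, cfg: LassoConfig):
    """L1-penalized fit at the CV-selected penalty.

    Returns (beta, lambda_cv): beta has one entry per design column; the
    covariate block is unpenalized.  Deterministic given ``cfg.fold_seed``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if design.matrix.shape[0] != n:
        raise ValueError("sample mismatch between design and phenotype")
    if n < cfg.n_folds:
        raise ValueError("fewer samples than CV folds")
    if cfg.family == "binary":
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
            raise ValueError("binary phenotype must contain both classes 0 and 1")
        return _fit_logistic(design, y, cfg)
    return _fit_gaussian(design, y, cfg)


def _fit_gaussian(design: Design, y, cfg: LassoConfig):
    m = design.n_covariates
    G = design.matrix[:, m:]
    Zf = np.column_stack([np.ones(y.size), design.matrix[:, :m]])
    # unpenalized covariates are profiled out exactly (partialled lasso);
    # rank-revealing basis so redundant covariate columns change nothing
    U, s, _ = np.linalg.svd(Zf, full_matrices=False)
    Q = U[:, s > s.max() * 1e-10]
    Gr = G - Q @ (Q.T @ G)
    yr = y - Q @ (Q.T @ y)
    lam_max = np.max(np.abs(Gr.T @ yr)) / y.size
    if lam_max <= 0:
        beta_g = np.zeros(G.shape[1])
        lam = 0.0
    elif cfg.lambda_override is not None:
        lam = float(cfg.lambda_override * lam_max)
        model = Lasso(alpha=lam, fit_intercept=False, max_iter=cfg.max_iter)
        model.fit(Gr, yr)
        beta_g = model.coef_
    else:
        cv = KFold(cfg.n_folds, shuffle=True, random_state=cfg.fold_seed)
        model = LassoCV(
            alphas=_lambda_grid(lam_max, cfg),
            cv=cv,
            fit_intercept=False,
            max_iter=cfg.max_iter,
            precompute=True,
        )
        model.fit(Gr, yr)
        beta_g = model.coef_
        lam = float(model.alpha_)
    gamma, *_ = np.linalg.lstsq(Zf, y - G @ beta_g, rcond=None)
    beta = np.concatenate([gamma[1:], beta_g])
    return beta, lam


def _fit_logistic(design: Design, y, cfg: LassoConfig):
    m = design.n_covariates
    n = y.size
    G = design.matrix[:, m:]
    Zf = np.column_stack([np.ones(n), design.matrix[:, :m]]) * _COV_SCALE
    M = np.column_stack([Zf, G])
    lam_max = np.max(np.abs(G.T @ (y - y.mean()))) / n
    lams = (
        np.array([cfg.lambda_override * lam_max])
        if cfg.lambda_override is not None
        else _lambda_grid(lam_max, cfg)
    )
    Cs = 1.0 / (n * lams)
    if lams.size == 1:
        best_C = Cs[0]
    else:
        cv = StratifiedKFold(cfg.n_folds, shuffle=True, random_state=cfg.fold_seed)
        dev = np.zeros(Cs.size)
        for tr, te in cv.split(M, y):
            clf = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", fit_intercept=False,
                warm_start=True, max_iter=cfg.max_iter, tol=1e-5,
            )
            for ci, C in enumerate(Cs):
                clf.C = C
                clf.fit(M[tr], y[tr])
                eta = M[te] @ clf.coef_[0]
                eta = np.clip(eta, -30, 30)
                dev[ci] += np.sum(np.log1p(np.exp(eta)) - y[te] * eta)
        best_C = Cs[int(np.argmin(dev))]
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", fit_intercept=False,
        C=float(best_C), max_iter=cfg.max_iter, tol=1e-6,
    )
    clf.fit(M, y)
    coef = clf.coef_[0]
    beta = np.concatenate([coef[1 : m + 1] * _COV_SCALE, coef[m + 1 :]])
    return beta, float(1.0 / (n * best_C))


def group_importance(beta: np.ndarray, design: Design, partition: Partition):
    """Per-group sums of |beta| over original and knockoff columns."""
    if partition.p != design.p:
        raise ValueError("partition does not cover the design variants")
    b = np.abs(np.asarray(beta, dtype=float))
    T = np.empty(partition.L)
    T_tilde = np.empty(partition.L)
    for g, sl in enumerate(partition.group_slices()):
        T[g] = b[design.original_cols[sl]].sum()
        T_tilde[g] = b[design.knockoff_cols[sl]].sum()
    return T, T_tilde


def compute_W(T: np.ndarray, T_tilde: np.ndarray, method: str = "difference"):
    """Antisymmetric contrast of group importances (default T - T~)."""
    T = np.asarray(T, dtype=float)
    T_tilde = np.asarray(T_tilde, dtype=float)
    if T.shape != T_tilde.shape:
        raise ValueError("length mismatch")
    if method == "difference":
        return T - T_tilde
    if method == "signed_max":
        return np.maximum(T, T_tilde) * np.sign(T - T_tilde)
    raise ValueError(f"unknown antisymmetric statistic '{method}'")


def importance_stats(
    X: np.ndarray,
    knockoffs: KnockoffSet | np.ndarray,
    y: np.ndarray,
    partition: Partition,
    cfg: LassoConfig | None = None,
    Z: np.ndarray | None = None,
    seed: int = 0,
) -> ImportanceStats:
    """Convenience pipeline: design -> CV lasso -> (T, T~, W) for one partition."""
    cfg = cfg or LassoConfig()
    design = build_design(Z, X, knockoffs, seed)
    beta, lam = fit_sparse_regression(design, y, cfg)
    T, T_tilde = group_importance(beta, design, partition)
    return ImportanceStats(T=T, T_tilde=T_tilde, W=compute_W(T, T_tilde),
                           lambda_cv=lam, beta=beta)
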