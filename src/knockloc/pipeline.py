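"""End-to-end orchestration: LD partitions -> HMM fit -> knockoffs ->
lasso statistics -> knockoff filter, at every resolution of the ladder.

The stages are pure functions of (data, config, seed).  Partitions and
knockoffs are produced from genotype data alone; the phenotype enters only
at the statistics stage, which is what makes the knockoffs valid negative
controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import child_seeds
from .filtering import DiscoverySet, knockoff_threshold, select
from .hmm import HaplotypeHMM, fit_hmm_em
from .knockoffs import genotype_knockoffs_from_phased
from .partition import (
    MultiResolutionPartition,
    build_dendrogram,
    cut_partitions,
    heights_for_mean_widths,
    ld_r2,
)
from .stats import LassoConfig, importance_stats

__all__ = [
    "PipelineConfig",
    "ResolutionResult",
    "PipelineResult",
    "run_pipeline",
    "simulation_study",
]


@dataclass
class PipelineConfig:
    """Settings for the full multi-resolution run."""

    K: int = 5
    em_max_iter: int = 25
    em_tol: float = 1e-2
    em_restarts: int = 1
    em_subsample: int = 800  # haplotypes used for model fitting (0 = all)
    ld_window: int = 1000
    target_widths_bp: tuple = (25_000, 10_000, 2_000)
    q: float = 0.1
    lasso: LassoConfig = field(default_factory=LassoConfig)
    offset: int = 1

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")


@dataclass
class ResolutionResult:
    W: np.ndarray
    threshold: float
    discoveries: DiscoverySet
    lambda_cv: float


@dataclass
class PipelineResult:
    partitions: MultiResolutionPartition
    model: HaplotypeHMM
    resolutions: list[ResolutionResult]

    @property
    def discoveries(self) -> list[DiscoverySet]:
        return [r.discoveries for r in self.resolutions]


def run_pipeline(
    H: np.ndarray,
    y: np.ndarray,
    positions: np.ndarray,
    config: PipelineConfig | None = None,
    Z: np.ndarray | None = None,
    seed: int = 0,
    model: HaplotypeHMM | None = None,
) -> PipelineResult:
    """Run every stage on phased haplotypes ``H`` (2 rows per individual).

    The LD partition and the HMM are estimated from H only; a fresh set of
    group knockoffs is generated per resolution; a cross-validated sparse
    regression of y on [Z, X, X-tilde] yields W statistics which the
    knockoff filter thresholds at level ``config.q``.
    """
    config = config or PipelineConfig()
    H = np.asarray(H)
    X = (H[0::2] + H[1::2]).astype(np.int8)
    seeds = child_seeds(seed, 2 + 2 * len(config.target_widths_bp))

    ld = ld_r2(H, window=config.ld_window)
    tree = build_dendrogram(ld, positions=positions)
    heights = heights_for_mean_widths(tree, config.target_widths_bp)
    partitions = cut_partitions(tree, heights)

    if model is None:
        H_fit = H
        if 0 < config.em_subsample < H.shape[0]:
            sub = np.random.default_rng(int(seeds[1])).choice(
                H.shape[0], size=config.em_subsample, replace=False
            )
            H_fit = H[np.sort(sub)]
        model = fit_hmm_em(
            H_fit,
            K=config.K,
            max_iter=config.em_max_iter,
            tol=config.em_tol,
            n_restarts=config.em_restarts,
            seed=int(seeds[0]),
            positions=np.asarray(positions),
        )

    results = []
    for i, part in enumerate(partitions):
        ks = genotype_knockoffs_from_phased(model, H, part, int(seeds[2 + 2 * i]))
        st = importance_stats(
            X, ks, y, part, cfg=config.lasso, Z=Z, seed=int(seeds[3 + 2 * i])
        )
        tau = knockoff_threshold(st.W, config.q, offset=config.offset)
        ds = select(st.W, tau, part, q=config.q)
        results.append(
            ResolutionResult(W=st.W, threshold=tau, discoveries=ds,
                             lambda_cv=st.lambda_cv)
        )
    return PipelineResult(partitions=partitions, model=model, resolutions=results)


def simulation_study(
    n_replicates: int = 25,
    seed: int = 0,
    h2: float | None = None,
    family: str = "gaussian",
    n: int | None = None,
    p: int | None = None,
    n_clusters: int | None = None,
    liability_threshold: float = 0.8416,
    config: PipelineConfig | None = None,
    margin_bp: int = 100_000,
):
    """Replicated end-to-end experiment on fully synthetic data.

    Each replicate draws a fresh HMM, genotypes, causal architecture, and
    trait; runs the full pipeline; and scores FDP (group-level truth: a
    discovery is false iff it contains no causal variant) and locus-detection
    power at every resolution.  Returns a tidy DataFrame with one row per
    (replicate, resolution).
    """
    import pandas as pd

    from . import simulate as sim

    h2 = sim.DEFAULT_H2 if h2 is None else h2
    n = sim.DEFAULT_N if n is None else n
    p = sim.DEFAULT_P if p is None else p
    n_clusters = sim.DEFAULT_N_CLUSTERS if n_clusters is None else n_clusters
    config = config or PipelineConfig(
        lasso=LassoConfig(family="binary" if family == "probit" else "gaussian")
    )
    rows = []
    rep_seeds = child_seeds(seed, n_replicates)
    for rep in range(n_replicates):
        s = child_seeds(int(rep_seeds[rep]), 5)
        model = sim.synthetic_hmm(p=p, K=config.K, seed=int(s[0]))
        H, X = sim.simulate_genotypes(model, n, int(s[1]))
        vt = sim.variant_table(model, X)
        spec = sim.place_causal_clusters(
            vt, n_clusters=n_clusters, seed=int(s[2]), h2_causal=h2, family=family
        )
        if family == "probit":
            y, _ = sim.simulate_probit_trait(
                X, spec, h2, liability_threshold, int(s[3])
            )
        else:
            y = sim.simulate_gaussian_trait(X, spec, int(s[3]))
        result = run_pipeline(H, y, model.positions, config=config, seed=int(s[4]))
        for lvl, rr in enumerate(result.resolutions):
            fdp, n_true, n_false = sim.evaluate_discoveries(rr.discoveries, spec)
            power = sim.evaluate_locus_detection(rr.discoveries, spec, margin_bp)
            rows.append(
                {
                    "replicate": rep,
                    "level": lvl,
                    "resolution_bp": rr.discoveries.resolution_bp,
                    "L": rr.discoveries.partition.L,
                    "n_discoveries": rr.discoveries.n,
                    "n_true": n_true,
                    "n_false": n_false,
                    "fdp": fdp,
                    "power": power,
                }
            )
    return pd.DataFrame(rows)
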