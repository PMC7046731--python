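"""Multi-resolution LD partitions of the genome.

Variants are grouped into contiguous blocks by adjacency-constrained
hierarchical clustering with complete linkage on the dissimilarity 1 - r^2,
where r^2 is the squared Pearson correlation of allele counts.  Cutting the
resulting dendrogram at a ladder of heights yields nested partitions, from
coarse LD blocks down to single variants; the groups at each resolution are
the units on which conditional-association hypotheses are tested.

Groups are fixed from genotype data alone, before any phenotype is seen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LDMatrix",
    "Partition",
    "MultiResolutionPartition",
    "Dendrogram",
    "ld_r2",
    "build_dendrogram",
    "cut_partitions",
    "heights_for_mean_widths",
]


@dataclass
class LDMatrix:
    """Banded symmetric r^2 similarity between variants within a window."""

    r2: np.ndarray  # (p, p), zero beyond the window
    window: int

    @property
    def p(self) -> int:
        return self.r2.shape[0]


@dataclass
class Partition:
    """One contiguous partition of the variants.

    ``group_ids`` assigns each variant a group label in 1..L, non-decreasing
    along the genome with unit jumps (groups are contiguous runs).
    """

    group_ids: np.ndarray  # (p,), values 1..L
    positions: np.ndarray  # (p,) bp
    resolution_bp: float  # realized mean group width in bp
    chromosome: str = "1"

    def __post_init__(self):
        g = np.asarray(self.group_ids)
        if g[0] != 1 or np.any(~np.isin(np.diff(g), (0, 1))):
            raise ValueError("group ids must be contiguous runs 1..L")
        self.group_ids = g.astype(np.int64)
        self.positions = np.asarray(self.positions, dtype=np.int64)

    @property
    def p(self) -> int:
        return self.group_ids.size

    @property
    def L(self) -> int:
        return int(self.group_ids[-1])

    def group_slices(self) -> list[slice]:
        """Variant index slice for each group, in genomic order."""
        starts = np.flatnonzero(np.r_[1, np.diff(self.group_ids)])
        ends = np.r_[starts[1:], self.p]
        return [slice(int(s), int(e)) for s, e in zip(starts, ends)]

    def ranges(self) -> pd.DataFrame:
        """Per-group first/last variant index and bp range (inclusive)."""
        rows = []
        for gid, sl in enumerate(self.group_slices(), start=1):
            rows.append(
                {
                    "group_id": gid,
                    "first_idx": sl.start,
                    "last_idx": sl.stop - 1,
                    "bp_min": int(self.positions[sl.start]),
                    "bp_max": int(self.positions[sl.stop - 1]),
                    "n_snps": sl.stop - sl.start,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class MultiResolutionPartition:
    """Ordered list of nested partitions, coarsest first."""

    partitions: list[Partition]
    heights: list[float]
    dendrogram: "Dendrogram" = field(repr=False, default=None)

    def __post_init__(self):
        for coarse, fine in zip(self.partitions, self.partitions[1:]):
            check_nested(coarse, fine)

    def __len__(self):
        return len(self.partitions)

    def __iter__(self):
        return iter(self.partitions)

    def __getitem__(self, i):
        return self.partitions[i]


def check_nested(coarse: Partition, fine: Partition):
    """Raise unless every fine group lies within exactly one coarse group."""
    df = pd.DataFrame({"fine": fine.group_ids, "coarse": coarse.group_ids})
    if (df.groupby("fine")["coarse"].nunique() > 1).any():
        raise ValueError("partitions are not nested")


@dataclass
class Dendrogram:
    """Adjacency-constrained merge tree over variants in genomic order.

    ``merge_heights[m]`` is the complete-linkage dissimilarity of the m-th
    merge and ``merge_boundary[m]`` is the inter-variant boundary (between
    variant b and b+1) removed by that merge.  Heights are non-decreasing.
    """

    merge_heights: np.ndarray  # (p-1,)
    merge_boundary: np.ndarray  # (p-1,)
    positions: np.ndarray  # (p,)
    chromosome: str = "1"

    @property
    def p(self) -> int:
        return self.positions.size


def ld_r2(
    M: np.ndarray, window: int = 1000, haplotypes: bool | None = None
) -> LDMatrix:
    """Pairwise r^2 between variant columns of a genotype or haplotype matrix.

    Pairs separated by more than ``window`` variants are set to 0.
    Monomorphic variants get off-diagonal r^2 = 0 (with a warning).
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute LD")
    p = M.shape[1]
    sd = M.std(axis=0)
    mono = sd == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic variant(s): r^2 set to 0")
    Ms = np.zeros_like(M)
    Ms[:, ~mono] = (M[:, ~mono] - M[:, ~mono].mean(0)) / sd[~mono]
    r2 = (Ms.T @ Ms / M.shape[0]) ** 2
    np.clip(r2, 0.0, 1.0, out=r2)
    if window < p:
        idx = np.arange(p)
        r2[np.abs(idx[:, None] - idx[None, :]) > window] = 0.0
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(r2=r2, window=window)


def build_dendrogram(
    ld: LDMatrix, positions: np.ndarray | None = None, chromosome: str = "1"
) -> Dendrogram:
    """Adjacency-constrained complete-linkage clustering on 1 - r^2.

    Only genomically adjacent clusters may merge; at each step the adjacent
    pair with the smallest complete-linkage dissimilarity merges, ties broken
    by the leftmost pair.  Complete linkage guarantees non-decreasing merge
    heights even under the adjacency constraint.
    """
    p = ld.p
    if p == 0:
        raise ValueError("empty LD matrix")
    if positions is None:
        positions = np.arange(1, p + 1, dtype=np.int64)
    positions = np.asarray(positions, dtype=np.int64)
    D = 1.0 - ld.r2
    if p == 1:
        return Dendrogram(np.empty(0), np.empty(0, dtype=np.int64), positions, chromosome)

    # clusters are contiguous [start, end) intervals; adjacent-pair linkage
    starts = list(range(p))
    ends = list(range(1, p + 1))
    link = [float(D[i, i + 1]) for i in range(p - 1)]
    heights = np.empty(p - 1)
    boundaries = np.empty(p - 1, dtype=np.int64)
    for m in range(p - 1):
        i = int(np.argmin(link))  # leftmost minimum
        heights[m] = link[i]
        boundaries[m] = ends[i] - 1  # boundary between variant ends[i]-1 and ends[i]
        # merge clusters i and i+1
        ends[i] = ends[i + 1]
        del starts[i + 1], ends[i + 1], link[i]
        if i > 0:
            link[i - 1] = float(
                D[starts[i - 1] : ends[i - 1], starts[i] : ends[i]].max()
            )
        if i < len(link):
            link[i] = float(D[starts[i] : ends[i], starts[i + 1] : ends[i + 1]].max())
    return Dendrogram(heights, boundaries, positions, chromosome)


def _cut_one(tree: Dendrogram, height: float, chromosome: str) -> Partition:
    p = tree.p
    keep = np.ones(p - 1, dtype=bool)  # inter-variant boundaries that survive
    merged = tree.merge_boundary[tree.merge_heights <= height]
    keep[merged] = False
    group_ids = np.r_[1, 1 + np.cumsum(keep)].astype(np.int64)
    part = Partition(group_ids, tree.positions, resolution_bp=0.0,
                     chromosome=chromosome)
    rng_df = part.ranges()
    part.resolution_bp = float((rng_df.bp_max - rng_df.bp_min).mean())
    return part


def cut_partitions(tree: Dendrogram, heights) -> MultiResolutionPartition:
    """Cut the dendrogram at descending heights (coarse -> fine).

    Nestedness holds by construction: the merges below a lower height are a
    subset of those below a higher one.  Each partition is labeled with its
    realized mean group width in bp.
    """
    heights = list(heights)
    if any(h > 1 + 1e-12 or h < -1e-12 for h in heights):
        raise ValueError("cut heights must lie in [0, 1]")
    if any(b > a for a, b in zip(heights, heights[1:])):
        raise ValueError("heights must be sorted descending (coarse to fine)")
    parts = [_cut_one(tree, h, tree.chromosome) for h in heights]
    return MultiResolutionPartition(parts, heights, tree)


def heights_for_mean_widths(tree: Dendrogram, target_widths_bp) -> list[float]:
    """Choose cut heights whose realized mean group width best matches targets.

    Candidate heights are midpoints between consecutive distinct merge
    heights (plus the extremes); for each target the candidate minimizing the
    absolute mean-width error is chosen.  Targets must be given coarse to
    fine; the returned heights are non-increasing by construction.
    """
    hs = np.unique(tree.merge_heights)
    cands = np.r_[hs.max() + 1e-9 if hs.size else 1.0,
                  (hs[1:] + hs[:-1]) / 2 if hs.size > 1 else [],
                  -1e-9]
    cands = np.clip(np.unique(cands)[::-1], 0.0, 1.0)
    widths = np.array(
        [_cut_one(tree, h, tree.chromosome).resolution_bp for h in cands]
    )
    out = []
    lo = 0
    for target in target_widths_bp:
        j = lo + int(np.argmin(np.abs(widths[lo:] - target)))
        out.append(float(cands[j]))
        lo = j  # keep the ladder monotone
    return out
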