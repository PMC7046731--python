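"""The knockoff filter: FDR-calibrated selection of groups, local FDR, and
the cross-resolution summary.

Under the exchangeability contract the signs of null groups' W statistics
are i.i.d. coin flips, so the number of negatives above a threshold t
estimates the number of false positives above t.  The filter picks the
smallest t whose estimated false discovery proportion, with a +1 offset for
provable control, is below the nominal level q.  A consequence of the +1
offset is a power floor: no discovery can be made unless at least 1/q
groups clear the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.isotonic import IsotonicRegression

from .partition import MultiResolutionPartition, Partition, check_nested

__all__ = [
    "DiscoverySet",
    "knockoff_threshold",
    "select",
    "local_fdr",
    "simplified_count",
    "chicago_rectangles",
]

_MIN_GROUPS_LOCAL_FDR = 200


@dataclass
class DiscoverySet:
    """Selected groups at one resolution.

    ``table`` has one row per discovery: group_id, first/last variant index,
    bp range, n_snps, W, and (when estimable) local_fdr.
    """

    table: pd.DataFrame
    resolution_bp: float
    q: float
    threshold: float
    partition: Partition

    @property
    def n(self) -> int:
        return len(self.table)


def knockoff_threshold(W: np.ndarray, q: float, offset: int = 1) -> float:
    """Data-dependent threshold of the knockoff filter.

    tau = min{ t in {|W_g| : W_g != 0} :
               (offset + #{g : W_g <= -t}) / max(1, #{g : W_g >= t}) <= q },
    or +inf when no candidate qualifies.  ``offset=1`` (the default) gives
    provable FDR control; ``offset=0`` is the relaxed variant without the
    guarantee.
    """
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise ValueError("empty W vector")
    if not np.all(np.isfinite(W)):
        raise ValueError("W must be finite")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if offset == 0:
        import warnings

        warnings.warn("offset=0 relaxes the filter; provable FDR control is lost")
    candidates = np.unique(np.abs(W[W != 0]))
    for t in candidates:
        fdp_hat = (offset + np.sum(W <= -t)) / max(1, np.sum(W >= t))
        if fdp_hat <= q:
            return float(t)
    return float("inf")


def select(
    W: np.ndarray,
    threshold: float,
    partition: Partition,
    q: float,
    with_local_fdr: bool = True,
) -> DiscoverySet:
    """Report the groups with W >= threshold, annotated with genomic ranges."""
    W = np.asarray(W, dtype=float)
    if W.size != partition.L:
        raise ValueError("W length must equal the number of groups")
    ranges = partition.ranges()
    ranges = ranges.assign(W=W)
    lf = local_fdr(W) if with_local_fdr else None
    ranges["local_fdr"] = lf if lf is not None else np.nan
    chosen = ranges[ranges.W >= threshold].reset_index(drop=True)
    return DiscoverySet(
        table=chosen,
        resolution_bp=partition.resolution_bp,
        q=q,
        threshold=float(threshold),
        partition=partition,
    )


def local_fdr(W: np.ndarray) -> np.ndarray | None:
    """Per-group local FDR estimates for positive W, or None if too few groups.

    Exploits the null sign-symmetry: the null density is estimated from the
    negative statistics reflected about zero, the mixture density from all
    statistics (Gaussian kernels); the ratio, scaled by the estimated null
    mass, is clipped to [0, 1] and made non-increasing in W by isotonic
    regression.  Entries for W <= 0 are set to 1.
    """
    W = np.asarray(W, dtype=float)
    if W.size < _MIN_GROUPS_LOCAL_FDR:
        return None
    neg = W[W < 0]
    out = np.ones(W.size)
    pos_mask = W > 0
    if neg.size < 10 or not pos_mask.any():
        # nearly one-sided: no evidence of nulls among positives
        out[pos_mask] = 0.0 if neg.size < 10 else 1.0
        return out
    null_sample = np.concatenate([neg, -neg])
    f0 = gaussian_kde(null_sample)
    f = gaussian_kde(np.concatenate([W, -W]))  # symmetrized mixture density
    pi0 = min(1.0, 2.0 * neg.size / W.size)
    w_pos = W[pos_mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pi0 * f0(w_pos) / f(w_pos)
    ratio[~np.isfinite(ratio)] = 0.0
    ratio = np.clip(ratio, 0.0, 1.0)
    order = np.argsort(w_pos)
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    fitted = iso.fit_transform(np.arange(order.size), ratio[order])
    vals = np.empty_like(ratio)
    vals[order] = fitted
    out[pos_mask] = vals
    return out


def simplified_count(discoveries: list[DiscoverySet]) -> pd.DataFrame:
    """Cross-resolution summary keeping only the most specific supported findings.

    Input is ordered coarse -> fine with nested partitions.  A discovery is
    *supported* if it is at the coarsest resolution or some discovery at the
    immediately coarser resolution contains it; unsupported finer discoveries
    are flagged "floating" and excluded from the summary.  A supported
    discovery is kept unless a supported finer discovery lies within it.
    """
    for a, b in zip(discoveries, discoveries[1:]):
        check_nested(a.partition, b.partition)
    rows = []
    supported_ranges: list[list[tuple[int, int]]] = []
    for lvl, ds in enumerate(discoveries):
        level_ranges = []
        for _, row in ds.table.iterrows():
            lo, hi = int(row.first_idx), int(row.last_idx)
            if lvl == 0:
                supp = True
            else:
                supp = any(a <= lo and hi <= b for a, b in supported_ranges[lvl - 1])
            rows.append(
                {
                    "level": lvl,
                    "resolution_bp": ds.resolution_bp,
                    "group_id": int(row.group_id),
                    "first_idx": lo,
                    "last_idx": hi,
                    "bp_min": int(row.bp_min),
                    "bp_max": int(row.bp_max),
                    "W": float(row.W),
                    "supported": supp,
                    "floating": not supp,
                }
            )
            if supp:
                level_ranges.append((lo, hi))
        supported_ranges.append(level_ranges)
    df = pd.DataFrame(
        rows,
        columns=[
            "level", "resolution_bp", "group_id", "first_idx", "last_idx",
            "bp_min", "bp_max", "W", "supported", "floating",
        ],
    )
    keep = []
    for i, row in df.iterrows():
        if not row.supported:
            keep.append(False)
            continue
        finer = df[(df.level > row.level) & df.supported]
        masked = (
            (finer.first_idx >= row.first_idx) & (finer.last_idx <= row.last_idx)
        ).any()
        keep.append(not masked)
    df["kept"] = keep
    return df


def chicago_rectangles(discoveries: list[DiscoverySet]) -> pd.DataFrame:
    """Rectangle data for a stacked multi-resolution discovery plot.

    One row per discovery: chrom, bp_min, bp_max, resolution_level
    (0 = coarsest at the bottom of the stack).  Intended for export to
    external plotting tools.
    """
    rows = []
    for lvl, ds in enumerate(discoveries):
        for _, r in ds.table.iterrows():
            rows.append(
                {
                    "chrom": ds.partition.chromosome,
                    "bp_min": int(r.bp_min),
                    "bp_max": int(r.bp_max),
                    "resolution_level": lvl,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "bp_min", "bp_max", "resolution_level"]
    )
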