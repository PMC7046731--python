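"""Readers and writers for standard formats, plus quality-control filters.

PLINK BED/BIM/FAM (SNP-major .bed, 2 bits per genotype) is read and written
directly; genotypes count copies of BIM allele1 (bit code 00 -> 2 copies,
10 -> 1, 11 -> 0, 01 -> missing, stored as NaN).  Haplotypes travel in a
simple TSV dialect: a header row of variant ids, then one row per haplotype
keyed by sample id with "_1"/"_2" suffixes.  Coordinates are 1-based
everywhere; group ranges are inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_plink",
    "write_plink",
    "read_haplotypes_tsv",
    "write_haplotypes_tsv",
    "read_phenotypes",
    "hwe_exact_p",
    "qc_filter",
    "mean_impute",
    "write_partition_tsv",
    "write_stats_tsv",
    "write_discoveries_tsv",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> allele1 count (1 = missing)
_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str):
    """Read a .bed/.bim/.fam triple.

    Returns (X, variants, samples): X is (n, p) float with NaN for missing,
    counting BIM allele1; variants has id/chrom/pos/allele1/allele2/maf.
    """
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError("not a SNP-major PLINK .bed file (bad magic bytes)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_var = (n + 3) // 4
    if data.size != bytes_per_var * p:
        raise ValueError("truncated or oversized .bed payload")
    data = data.reshape(p, bytes_per_var)
    shifts = np.arange(4) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11  # (p, bytes, 4)
    codes = codes.reshape(p, -1)[:, :n]
    X = _CODE_TO_COUNT[codes].T  # (n, p)
    freq = np.nanmean(X, axis=0) / 2.0
    variants = bim[["id", "chrom", "pos", "allele1", "allele2"]].copy()
    variants["maf"] = np.minimum(freq, 1 - freq)
    return X, variants, fam


def write_plink(prefix: str, X: np.ndarray, variants: pd.DataFrame,
                samples: pd.DataFrame | None = None):
    """Write genotypes to a .bed/.bim/.fam triple (allele1 counts in X)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if samples is None:
        samples = pd.DataFrame(
            {"fid": [f"F{i+1}" for i in range(n)], "iid": [f"I{i+1}" for i in range(n)],
             "father": 0, "mother": 0, "sex": 0, "phenotype": -9}
        )
    bim = pd.DataFrame(
        {
            "chrom": variants["chrom"],
            "id": variants["id"],
            "cm": 0,
            "pos": variants["pos"],
            "allele1": variants["allele1"],
            "allele2": variants["allele2"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    samples.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    # map counts -> 2-bit codes; NaN -> 01
    codes = np.full(X.shape, 1, dtype=np.uint8)
    codes[X == 2] = 0b00
    codes[X == 1] = 0b10
    codes[X == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes.T, np.zeros((p, pad), dtype=np.uint8)])
    else:
        codes = codes.T.copy()
    codes = codes.reshape(p, -1, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def write_haplotypes_tsv(path, H: np.ndarray, variant_ids, sample_ids=None):
    """One row per haplotype; sample ids get "_1"/"_2" suffixes when diploid."""
    H = np.asarray(H)
    n_hap = H.shape[0]
    if sample_ids is None:
        sample_ids = [f"I{i + 1}" for i in range(n_hap // 2 or n_hap)]
    rows = (
        [f"{s}_{k}" for s in sample_ids for k in (1, 2)]
        if n_hap == 2 * len(sample_ids)
        else list(sample_ids)
    )
    df = pd.DataFrame(H, index=rows, columns=list(variant_ids))
    df.to_csv(path, sep="\t", index_label="haplotype_id")


def read_haplotypes_tsv(path):
    """Returns (H, variant_ids, haplotype_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    H = df.to_numpy()
    if not np.isin(H, (0, 1)).all():
        raise ValueError("haplotype TSV must contain only 0/1 entries")
    return H.astype(np.int8), list(df.columns), list(df.index)


def read_phenotypes(path, fam: pd.DataFrame, phenotype: str,
                    covariates: list[str] | None = None):
    """Load a TSV keyed by FID/IID, aligned to the FAM sample order.

    Returns (y, Z) with Z None when no covariates are requested.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    key = fam[["fid", "iid"]].rename(columns={"fid": "FID", "iid": "IID"})
    merged = key.merge(tab, on=["FID", "IID"], how="left")
    if merged[phenotype].isna().any():
        raise ValueError("phenotype missing for some FAM samples")
    y = merged[phenotype].to_numpy(dtype=float)
    Z = merged[covariates].to_numpy(dtype=float) if covariates else None
    return y, Z


def mean_impute(X: np.ndarray) -> np.ndarray:
    """Replace missing genotypes by the per-variant mean."""
    X = np.asarray(X, dtype=float).copy()
    means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = means[nan_c]
    return X


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of genotype-count probabilities
    no larger than the observed one, conditional on allele counts)."""
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n == 0 or n_rare == 0:
        return 1.0
    # unnormalized probabilities over all feasible heterozygote counts
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    logs = np.zeros(het_values.size)
    from scipy.special import gammaln

    for i, het in enumerate(het_values):
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        logs[i] = (
            het * np.log(2)
            + gammaln(n + 1)
            - gammaln(het + 1)
            - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1)
        )
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = np.flatnonzero(het_values == n_het)
    if obs.size == 0:
        raise ValueError("inconsistent genotype counts")
    p_obs = probs[obs[0]]
    return float(np.minimum(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))


def qc_filter(
    X: np.ndarray,
    variants: pd.DataFrame,
    maf_min: float = 0.001,
    hwe_p_min: float = 1e-6,
):
    """Keep variants with MAF > maf_min and HWE exact p >= hwe_p_min.

    Returns (X_kept, variants_kept, report).  Monomorphic variants always
    fail the MAF filter.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    keep = np.ones(p, dtype=bool)
    reasons = np.array([""] * p, dtype=object)
    for j in range(p):
        col = X[:, j]
        col = col[~np.isnan(col)]
        freq = col.mean() / 2.0 if col.size else 0.0
        maf = min(freq, 1 - freq)
        if not maf > maf_min:
            keep[j] = False
            reasons[j] = "maf"
            continue
        n_het = int(np.sum(col == 1))
        n_hom1 = int(np.sum(col == 2))
        n_hom2 = int(np.sum(col == 0))
        if hwe_exact_p(n_het, n_hom1, n_hom2) < hwe_p_min:
            keep[j] = False
            reasons[j] = "hwe"
    report = pd.DataFrame(
        {"id": variants["id"], "kept": keep, "reason": reasons}
    )
    return X[:, keep], variants[keep].reset_index(drop=True), report


def write_partition_tsv(path, partition, variants: pd.DataFrame):
    df = pd.DataFrame(
        {
            "variant_id": variants["id"],
            "chrom": variants["chrom"],
            "bp": variants["pos"],
            "group_id": partition.group_ids,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_stats_tsv(path, stats, partition, chromosome="1"):
    rng_df = partition.ranges()
    df = pd.DataFrame(
        {
            "group_id": rng_df.group_id,
            "chrom": chromosome,
            "bp_min": rng_df.bp_min,
            "bp_max": rng_df.bp_max,
            "T": stats.T,
            "T_knockoff": stats.T_tilde,
            "W": stats.W,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_discoveries_tsv(path, ds, chromosome="1"):
    tab = ds.table.copy()
    tab.insert(0, "resolution_bp", ds.resolution_bp)
    tab.insert(1, "chrom", chromosome)
    tab["threshold"] = ds.threshold
    tab.to_csv(path, sep="\t", index=False, float_format="%.10g")
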