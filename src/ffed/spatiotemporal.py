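"""Permutation enrichment of gene groups across brain regions and periods.

The procedure mirrors spatio-temporal expression atlases of typical
neurodevelopment (four brain regions x eight developmental periods):
samples below an RNA-integrity cutoff and uninformative genes are
filtered out; a significant gene list is split into two clusters by
hierarchical clustering of its standardized region-by-period mean
profiles; and each cluster's mean expression per cell is compared with
the means of size-matched random gene sets over B permutations.

Tail convention: the source procedure scores the proportion of
permutations in which the group's mean is HIGHER than the random mean —
a score near 1 for enriched cells. We report the standard complement,
``p = (1 + #{null >= observed}) / (B + 1)`` (small p = enrichment, ties
count against the group), and expose the literal score as ``1 - p``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ffed.stats import bh_adjust

__all__ = [
    "filter_samples",
    "filter_genes",
    "cluster_gene_list",
    "permutation_enrichment",
]


def filter_samples(
    matrix: pd.DataFrame, meta: pd.DataFrame, rin_min: float = 9.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples with RIN below ``rin_min`` (RNA-quality QC)."""
    keep = meta["RIN"] >= rin_min
    if not keep.any():
        warnings.warn("all samples fall below the RIN cutoff; returning empty matrix")
    meta_out = meta[keep].reset_index(drop=True)
    return matrix[meta_out["sample_id"].tolist()], meta_out


def filter_genes(
    matrix: pd.DataFrame,
    min_fpkm: float = 1.0,
    min_samples: int = 2,
    presence_frac: float = 0.5,
    cv_min: float = 0.25,
) -> pd.DataFrame:
    """Remove low-expression and low-variability genes.

    A gene is kept iff it reaches ``min_fpkm`` in at least ``min_samples``
    samples, and is NOT simultaneously sparse (> 0 in fewer than
    ``presence_frac`` of samples) and flat (coefficient of variation
    below ``cv_min``). The CV is computed over the samples where the gene
    is expressed (> 0): across all samples, the zeros of a sparse gene
    force its CV above any sensible cutoff and the flatness clause could
    never fire.
    """
    vals = matrix.to_numpy(dtype=float)
    expressed = (vals >= min_fpkm).sum(axis=1) >= min_samples
    present_frac = (vals > 0).mean(axis=1)
    cv = np.zeros(vals.shape[0])
    for i, row in enumerate(vals):
        nz = row[row > 0]
        if nz.size >= 2 and nz.mean() > 0:
            cv[i] = nz.std(ddof=1) / nz.mean()
    low_var = (present_frac < presence_frac) & (cv < cv_min)
    return matrix[expressed & ~low_var]


def _cell_profiles(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean expression per (region, period) cell, genes x cells."""
    cells = meta.assign(cell=meta["region"] + "|" + meta["period"])
    groups = {
        cell: grp["sample_id"].tolist() for cell, grp in cells.groupby("cell")
    }
    prof = pd.DataFrame(
        {cell: matrix[samples].mean(axis=1) for cell, samples in groups.items()}
    )
    return prof


def cluster_gene_list(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    genes: list[str],
    k: int = 2,
) -> pd.DataFrame:
    """Split a gene list into k clusters of standardized spatio-temporal profiles.

    Per gene, mean expression in each region-by-period cell is computed
    first and z-standardized across cells; agglomerative clustering
    (average linkage, correlation distance) is cut at ``k``. Returns a
    table of gene, cluster label, and the standardized profile.
    """
    present = [g for g in genes if g in matrix.index]
    if len(present) < k:
        raise ValueError("fewer genes than requested clusters")
    prof = _cell_profiles(matrix.loc[present], meta)
    z = prof.sub(prof.mean(axis=1), axis=0)
    sd = prof.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = z.div(sd, axis=0)
    if len(present) == k:
        labels = np.arange(1, k + 1)
    else:
        lk = linkage(z.to_numpy(), method="average", metric="correlation")
        labels = fcluster(lk, t=k, criterion="maxclust")
    out = z.copy()
    out.insert(0, "cluster", labels)
    return out


def permutation_enrichment(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    group: list[str],
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation enrichment of a gene group in every region-by-period cell.

    Observed statistic per cell: mean expression of the group. Null:
    means of ``n_perm`` size-matched gene sets drawn uniformly from the
    matrix. ``p = (1 + #{null >= observed})/(n_perm + 1)``; BH-FDR across
    all cells. Returns a long table (region, period, observed_mean, p,
    padj, score) where ``score`` is the literal higher-than-random
    proportion, ``1 - p``.
    """
    group = list(dict.fromkeys(group))
    missing = [g for g in group if g not in matrix.index]
    if missing:
        raise ValueError(f"group genes absent from matrix: {missing[:5]}")
    if len(group) > matrix.shape[0]:
        raise ValueError("group larger than the gene universe")
    rng = np.random.default_rng(seed)
    prof = _cell_profiles(matrix, meta)  # all genes x cells
    vals = prof.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(prof.index)}
    gi = np.array([gene_pos[g] for g in group])
    observed = vals[gi].mean(axis=0)

    k = len(gi)
    n_genes = vals.shape[0]
    exceed = np.zeros(vals.shape[1], dtype=int)
    for _ in range(n_perm):
        idx = rng.choice(n_genes, size=k, replace=False)
        exceed += vals[idx].mean(axis=0) >= observed
    p = (1 + exceed) / (n_perm + 1)
    padj = bh_adjust(p)

    cells = [c.split("|") for c in prof.columns]
    return pd.DataFrame(
        {
            "region": [c[0] for c in cells],
            "period": [c[1] for c in cells],
            "observed_mean": observed,
            "p": p,
            "padj": padj,
            "score": 1 - p,
            "n_perm": n_perm,
        }
    )
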