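"""Alpha and beta diversity.

Alpha: per-sample zOTU richness, rooted Faith phylogenetic diversity, and
Levins niche breadth B = 1/sum(p_i^2), the effective number of samples a
taxon occupies (B = 1 for a specialist confined to one sample, B = n for a
perfectly even generalist).

Beta: Bray-Curtis dissimilarity, the Baselga partition of Sorensen
dissimilarity into turnover (beta_sim) and nestedness (beta_sne) components,
and a Mantel-style Spearman correlation between two dissimilarity matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FeatureTable, PhyloTree


@dataclass
class BetaPartition:
    """Sorensen dissimilarity split into turnover + nestedness components."""

    beta_sor: float
    beta_sim: float
    beta_sne: float

    def __post_init__(self) -> None:
        for v in (self.beta_sor, self.beta_sim, self.beta_sne):
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"component {v} outside [0, 1]")
        if abs(self.beta_sor - (self.beta_sim + self.beta_sne)) > 1e-12:
            raise ValueError("beta_sor must equal beta_sim + beta_sne")


@dataclass
class DissimilarityMatrix:
    """Symmetric zero-diagonal matrix of pairwise dissimilarities in [0, 1]."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValueError("diagonal must be zero")
        self.matrix = m

    def condensed(self) -> np.ndarray:
        """Strict lower-triangle entries in row-major order."""
        i, j = np.tril_indices(len(self.sample_ids), k=-1)
        return self.matrix[i, j]


def richness(table: FeatureTable) -> pd.Series:
    """Number of taxa with count > 0, per sample."""
    return pd.Series((table.counts > 0).sum(axis=0), index=table.sample_ids, name="richness")


def faith_pd(table: FeatureTable, tree: PhyloTree) -> pd.Series:
    """Rooted Faith PD per sample.

    Sum of branch lengths of the minimal rooted subtree spanning a sample's
    observed taxa, i.e. the union of all root-to-observed-tip paths (the
    rooted convention: the path up to the root is always included).
    """
    observed = {t for t, row in zip(table.taxon_ids, table.counts) if row.any()}
    missing = sorted(observed - tree.tip_names)
    if missing:
        raise ValueError(f"observed taxa absent from tree: {missing}")
    n_samples = len(table.sample_ids)
    presence = table.counts > 0
    row_of = {t: i for i, t in enumerate(table.taxon_ids)}
    pd_vals = np.zeros(n_samples)
    # single postorder pass: a branch contributes to a sample iff any
    # descendant tip is observed in that sample
    covered: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            idx = row_of.get(node.name)
            mask = presence[idx] if idx is not None else np.zeros(n_samples, dtype=bool)
        else:
            mask = np.zeros(n_samples, dtype=bool)
            for child in node.children:
                mask |= covered.pop(id(child))
        covered[id(node)] = mask
        if not node.is_root():
            pd_vals += mask * (node.length or 0.0)
    return pd.Series(pd_vals, index=table.sample_ids, name="faith_pd")


def levins_breadth(table: FeatureTable, group_samples: list[str]) -> pd.Series:
    """Levins niche breadth B per taxon within a sample group.

    B_j = 1 / sum_i p_ij^2 with p_ij the share of taxon j's group total held
    by sample i. Taxa absent from the group are excluded (not reported as 0).
    """
    if len(group_samples) < 2:
        raise ValueError("group must have at least 2 samples")
    sub = table.select_samples(group_samples)
    totals = sub.taxon_totals().astype(float)
    present = totals > 0
    p = sub.counts[present] / totals[present, None]
    b = 1.0 / (p**2).sum(axis=1)
    taxa = [t for t, keep in zip(sub.taxon_ids, present) if keep]
    return pd.Series(b, index=taxa, name="levins_B")


def community_breadth(table: FeatureTable, group_samples: list[str]) -> pd.Series:
    """Per-sample unweighted mean of Levins B over taxa present in the sample.

    B is computed over ``group_samples``; the mean is reported for each of
    those samples. A sample with no taxa gets NaN.
    """
    b = levins_breadth(table, group_samples)
    sub = table.select_samples(group_samples)
    b_vec = b.reindex(sub.taxon_ids).to_numpy()
    out = np.full(len(group_samples), np.nan)
    for j in range(len(group_samples)):
        present = sub.counts[:, j] > 0
        if present.any():
            out[j] = np.nanmean(b_vec[present])
    return pd.Series(out, index=group_samples, name="community_breadth")


def bray_curtis(table: FeatureTable) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity BC(u, v) = sum|u - v| / sum(u + v).

    A pair of all-zero samples is defined as 0 (with a warning).
    """
    x = table.counts.astype(float).T  # samples x taxa
    n = x.shape[0]
    m = np.zeros((n, n))
    degenerate = False
    for i in range(n):
        diff = np.abs(x[i + 1:] - x[i]).sum(axis=1)
        tot = (x[i + 1:] + x[i]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        if np.any(tot == 0):
            degenerate = True
        m[i, i + 1:] = d
        m[i + 1:, i] = d
    if degenerate:
        warnings.warn("all-zero sample pair: dissimilarity defined as 0", stacklevel=2)
    return DissimilarityMatrix(list(table.sample_ids), m)


def baselga_partition(u, v) -> BetaPartition:
    """Partition pairwise Sorensen dissimilarity into turnover and nestedness.

    With a shared taxa and b, c unique to each side:
    beta_sor = (b+c)/(2a+b+c), beta_sim = min(b,c)/(a+min(b,c)) (turnover),
    beta_sne = beta_sor - beta_sim (nestedness-resultant).
    """
    u, v = set(u), set(v)
    if not u and not v:
        raise ValueError("both presence sets empty: partition undefined")
    a = len(u & v)
    b = len(u - v)
    c = len(v - u)
    beta_sor = (b + c) / (2 * a + b + c)
    mn = min(b, c)
    beta_sim = mn / (a + mn) if (a + mn) > 0 else 0.0
    return BetaPartition(beta_sor, beta_sim, beta_sor - beta_sim)


def matrix_rank_correlation(
    d1: DissimilarityMatrix,
    d2: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel-style Spearman correlation between two dissimilarity matrices.

    rho is Spearman over corresponding strict-lower-triangle entries; the
    p-value permutes the sample labels of ``d2`` (n_perm permutations),
    p = (#{|rho_perm| >= |rho_obs|} + 1) / (n_perm + 1).
    """
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("matrices must share sample ids and ordering")
    v1 = d1.condensed()
    rho_obs = stats.spearmanr(v1, d2.condensed()).statistic
    rng = np.random.default_rng(seed)
    n = len(d1.sample_ids)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        m2 = d2.matrix[np.ix_(perm, perm)]
        i, j = np.tril_indices(n, k=-1)
        rho_p = stats.spearmanr(v1, m2[i, j]).statistic
        if abs(rho_p) >= abs(rho_obs):
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(rho_obs), float(p)
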