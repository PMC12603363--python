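"""Phylogenetic comparison of leaf traits between habits.

Species means are compared between the two leaf habits with a phylogenetic
ANOVA: generalized least squares under a Brownian-motion covariance derived
from the tree, with significance from a residual-randomization permutation
procedure (RRPP) on the reduced-model residuals. Trees are handled with
dendropy; the Brownian covariance C[i,j] = shared root-to-MRCA branch
length is built from node depths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhyloError",
    "PglsResult",
    "prune_tree",
    "phylo_covariance",
    "species_means",
    "pgls_anova",
    "pearson_regression",
]

EIGENVALUE_FLOOR = 1e-12


class PhyloError(ValueError):
    """Invalid tree or trait table."""


@dataclass
class PglsResult:
    """Phylogenetic ANOVA outcome for one trait."""

    trait: str
    f_statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    effect_size: float      # standardized group difference on GLS-whitened data
    group_means: dict

    def __post_init__(self) -> None:
        assert self.f_statistic >= 0
        assert 0 <= self.p_value <= 1


def _check_tree(tree: dendropy.Tree) -> None:
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(tips) < 2:
        raise PhyloError("tree must have at least 2 tips")
    if len(set(tips)) != len(tips):
        raise PhyloError("tip labels must be unique")


def prune_tree(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Subtree on the tip set ``keep``; unifurcations collapsed, lengths summed."""
    _check_tree(tree)
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(keep) - labels
    if unknown:
        raise PhyloError(f"tips not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise PhyloError("keep at least 2 tips")
    return tree.extract_tree_with_taxa_labels(labels=keep)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [l.taxon.label for l in tree.leaf_node_iter()]


def phylo_covariance(tree: dendropy.Tree, order: list[str] | None = None
                     ) -> tuple[list[str], np.ndarray]:
    """Brownian-motion trait covariance implied by the tree.

    C[i,j] is the branch length shared by tips i and j on their paths from
    the root (the depth of their MRCA); C[i,i] is the root-to-tip depth.
    Returns the tip order used and the matrix.
    """
    _check_tree(tree)
    for e in tree.preorder_edge_iter():
        if e.head_node is not tree.seed_node and e.length is None:
            raise PhyloError("tree has edges without branch lengths")
    labels = tip_labels(tree)
    if order is not None:
        if set(order) != set(labels):
            raise PhyloError("order must be a permutation of the tip labels")
        labels = list(order)
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
        depth[node] = d
    tipmap = {l.taxon.label: l for l in tree.leaf_node_iter()}
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    C = np.zeros((n, n))
    for i in range(n):
        ti = tipmap[labels[i]]
        C[i, i] = depth[ti]
        for j in range(i + 1, n):
            tj = tipmap[labels[j]]
            dij = pdm.patristic_distance(ti.taxon, tj.taxon)
            C[i, j] = C[j, i] = 0.5 * (depth[ti] + depth[tj] - dij)
    return labels, C


def species_means(table: pd.DataFrame, trait_cols: list[str] | None = None
                  ) -> pd.DataFrame:
    """Collapse a per-tree trait table to one row of arithmetic means per species.

    The ``habit`` factor must be constant within a species and is carried
    through; a ``year`` column, if present, is dropped.
    """
    if "species" not in table.columns:
        raise PhyloError("table must have a 'species' column")
    if "habit" in table.columns:
        bad = table.groupby("species")["habit"].nunique()
        bad = bad[bad > 1]
        if len(bad):
            raise PhyloError(f"habit not constant within species: {list(bad.index)}")
    if trait_cols is None:
        drop = {"species", "tree_id", "habit", "year"}
        trait_cols = [c for c in table.columns
                      if c not in drop and pd.api.types.is_numeric_dtype(table[c])]
    out = table.groupby("species", sort=True)[trait_cols].mean().reset_index()
    if "habit" in table.columns:
        habit = table.groupby("species", sort=True)["habit"].first().reset_index()
        out = habit.merge(out, on="species")
    return out


def _whitener(C: np.ndarray) -> np.ndarray:
    """Inverse square root of C by symmetric eigendecomposition."""
    w, V = np.linalg.eigh(C)
    if np.any(w < -1e-8 * np.abs(w).max()):
        raise PhyloError("covariance matrix is not positive semi-definite")
    w = np.maximum(w, EIGENVALUE_FLOOR)
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def pgls_anova(
    means: pd.DataFrame,
    trait: str,
    tree: dendropy.Tree,
    factor: str = "habit",
    n_perm: int = 1000,
    seed: int | None = 0,
    exact: bool = False,
) -> PglsResult:
    """Phylogenetic ANOVA of one trait against a two-level factor.

    The response and design are whitened by C^(-1/2) (Brownian covariance
    from the tree); F compares the habit model against the intercept-only
    model on the whitened data. The null distribution permutes the
    reduced-model residuals (RRPP); the observed statistic counts as one of
    the ``n_perm`` draws, so p >= 1/n_perm. ``exact=True`` enumerates every
    residual permutation instead of sampling (feasible for small trees) and
    serves as the oracle for the sampled mode.
    """
    if trait not in means.columns:
        raise PhyloError(f"trait {trait!r} not in table")
    if factor not in means.columns:
        raise PhyloError(f"factor {factor!r} not in table")
    labels, C = phylo_covariance(tree, order=sorted(means["species"]))
    tab = means.set_index("species").loc[labels]
    y = tab[trait].to_numpy(dtype=float)
    levels = sorted(tab[factor].unique())
    if len(levels) != 2:
        raise PhyloError(f"factor must have exactly 2 levels, got {levels}")
    counts = tab[factor].value_counts()
    if (counts < 1).any():
        raise PhyloError("each factor level needs at least one species")
    g = (tab[factor] == levels[1]).to_numpy(dtype=float)
    n = y.size

    P = _whitener(C)
    yt = P @ y
    Xf = P @ np.column_stack([np.ones(n), g])
    Xr = P @ np.ones((n, 1))

    df1 = 1
    df2 = n - 2
    if df2 <= 0:
        raise PhyloError("too few species for the habit model")

    def f_stat(yv: np.ndarray) -> float:
        sse_r = _sse(yv, Xr)
        sse_f = _sse(yv, Xf)
        return max(0.0, (sse_r - sse_f) / df1) / max(sse_f / df2, 1e-300)

    f_obs = f_stat(yt)

    beta_r, *_ = np.linalg.lstsq(Xr, yt, rcond=None)
    fitted_r = Xr @ beta_r
    resid_r = yt - fitted_r

    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
        n_perm = perms.shape[0]
        f_null = np.array([f_stat(fitted_r + resid_r[p]) for p in perms])
        p_value = float(np.mean(f_null >= f_obs - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        count = 1  # the observed statistic is one of the draws
        for _ in range(n_perm - 1):
            p = rng.permutation(n)
            if f_stat(fitted_r + resid_r[p]) >= f_obs - 1e-12:
                count += 1
        p_value = count / n_perm

    gm = {lvl: float(tab.loc[tab[factor] == lvl, trait].mean()) for lvl in levels}
    pooled = float(np.std(y, ddof=1)) if n > 1 else float("nan")
    effect = (gm[levels[1]] - gm[levels[0]]) / pooled if pooled else float("nan")
    return PglsResult(trait=trait, f_statistic=float(f_obs), p_value=p_value,
                      n_permutations=int(n_perm), seed=seed,
                      effect_size=float(effect), group_means=gm)


def pearson_regression(x, y) -> dict:
    """OLS line with Pearson correlation and its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PhyloError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise PhyloError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PhyloError("correlation undefined for constant input")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "p": float(res.pvalue), "n": int(x.size)}
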