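"""Blomberg's K* phylogenetic-signal statistic with a permutation test.

K compares the observed ratio of trait variance ignoring the tree (MSE0) to
the variance under the tree's Brownian covariance (MSE) against the ratio
expected under Brownian motion on that tree; K ~ 1 indicates Brownian-like
signal, K ~ 0 no signal.  The permutation p-value shuffles trait values
across tips and asks how often the phylogenetically corrected error is as
small as observed.
"""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np

import dendropy

__all__ = ["blomberg_k", "phylo_covariance", "tree_from_newick"]


def tree_from_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string (or file content) into a dendropy tree."""
    return dendropy.Tree.get(data=newick, schema="newick")


def phylo_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance matrix V among tips (V_ij = shared root-to-MRCA path).

    Raises on non-positive branch lengths, naming the offending edges.
    """
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    V = np.zeros((n, n))
    bad = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length
        if length is None or length <= 0:
            if node.is_leaf():
                bad.append(node.taxon.label)
            else:
                bad.append(f"internal edge above {node.leaf_nodes()[0].taxon.label}…")
            continue
        tips = [idx[l.taxon.label] for l in node.leaf_iter()]
        V[np.ix_(tips, tips)] += length
    if bad:
        raise ValueError(
            "tree has zero/missing-length branches (V would be singular): "
            + ", ".join(bad[:5]))
    return V, taxa


def blomberg_k(tree: Union[dendropy.Tree, str],
               traits: Mapping[str, float],
               n_perm: int = 999,
               seed: int = 0) -> tuple[float, float]:
    """Blomberg's K* and its tip-permutation p-value.

    ``traits`` maps tip labels to values and must cover every tip.  With the
    phylogenetic GLS mean ``a = (1'V^-1 x)/(1'V^-1 1)``,

        K = (MSE0/MSE) / [(tr(V) - n/(1'V^-1 1)) / (n-1)]

    where ``MSE0 = (x-a)'(x-a)/(n-1)`` and ``MSE = (x-a)'V^-1(x-a)/(n-1)``.
    p is the fraction of tip-shuffled datasets whose MSE is at most the
    observed MSE (smaller MSE = stronger fit to the tree).
    """
    if isinstance(tree, str):
        tree = tree_from_newick(tree)
    V, taxa = phylo_covariance(tree)
    missing = [t for t in taxa if t not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:5]}")
    x = np.array([float(traits[t]) for t in taxa])
    n = x.size
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as e:
        raise ValueError("phylogenetic covariance is singular "
                         "(check for zero-length branches)") from e

    ones = np.ones(n)
    Vi_1 = np.linalg.solve(V, ones)
    denom_1 = float(ones @ Vi_1)
    expected = (np.trace(V) - n / denom_1) / (n - 1)

    def mses(vals: np.ndarray) -> tuple[float, float]:
        a = float(vals @ Vi_1) / denom_1
        d = vals - a
        w = np.linalg.solve(V, d)
        return float(d @ d) / (n - 1), float(d @ w) / (n - 1)

    mse0, mse = mses(x)
    if mse <= 0:
        raise ValueError("degenerate trait vector (zero variance)")
    K = (mse0 / mse) / expected

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, mse_p = mses(rng.permutation(x))
        if mse_p <= mse + 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(K), float(p)
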