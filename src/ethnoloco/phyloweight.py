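"""Phylogenetic-isolation resampling weights on a time-calibrated society tree.

Cross-cultural samples are phylogenetically autocorrelated (Galton's
problem): closely related societies are not independent observations.
The correction used downstream resamples societies with probability
proportional to each society's *phylogenetic isolation* — its mean
patristic (path-length) time distance to every other society in the
sample under analysis.  Weights are always recomputed on the exact
subsample being analysed, never renormalized from a larger sample.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_tree", "patristic_distances", "isolation_weights"]


def read_tree(
    path: str | Path, society_ids: Sequence[str] | None = None
) -> dendropy.Tree:
    """Load a rooted, branch-length-annotated Newick tree.

    Tip labels are society identifiers.  Branch lengths must be present
    and non-negative on every non-root edge.  When ``society_ids`` is
    given, a society without a matching tip is a hard error (silently
    reweighting a reduced sample would change the estimand); tips without
    a matching society are merely reported.  A root-to-tip depth spread
    above 1% triggers a non-ultrametricity warning (diagnostic only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"missing branch length above node {_describe(edge.head_node)}"
            )
        if edge.length < 0:
            raise ValueError(
                f"negative branch length {edge.length} above node "
                f"{_describe(edge.head_node)}"
            )
    if society_ids is not None:
        tipset = set(labels)
        missing = sorted(set(society_ids) - tipset)
        if missing:
            raise ValueError(f"societies absent from tree: {missing}")
        extra = sorted(tipset - set(society_ids))
        if extra:
            logger.info("tree has %d tips with no analysed society: %s", len(extra), extra)
    _check_ultrametric(tree)
    return tree


def _describe(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    tips = [l.taxon.label for l in node.leaf_iter()]
    return f"MRCA({','.join(tips[:3])}{'...' if len(tips) > 3 else ''})"


def _check_ultrametric(tree: dendropy.Tree, tolerance: float = 0.01) -> None:
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node is not tree.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    depths = np.asarray(depths)
    if depths.max() <= 0:
        return
    spread = (depths.max() - depths.min()) / depths.max()
    if spread > tolerance:
        logger.warning(
            "tree is not ultrametric: root-to-tip depths vary by %.1f%%", 100 * spread
        )


def patristic_distances(
    tree: dendropy.Tree, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise patristic distance matrix (sum of branch lengths along the
    unique path between two tips), in the tree's time units.

    Returns a symmetric, zero-diagonal DataFrame indexed by society id.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label is not None}
    if subset is None:
        ids = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    else:
        ids = list(subset)
        unknown = sorted(set(ids) - set(taxa))
        if unknown:
            raise KeyError(f"tips not in tree: {unknown}")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def isolation_weights(
    dist: pd.DataFrame, subsample: Sequence[str] | None = None
) -> pd.DataFrame:
    """Phylogenetic-isolation resampling weights for one analysis subsample.

    For each society i in the subsample, the raw isolation ``m_i`` is the
    mean time distance to every *other* society in that subsample, and
    the weight is ``w_i = m_i / sum_k m_k``.  Weights therefore depend on
    the subsample: restricting the sample and recomputing is not the same
    as renormalizing the full-sample weights.

    Returns a DataFrame indexed by society id with columns
    ``raw_isolation`` and ``weight``.
    """
    ids = list(dist.index) if subsample is None else list(subsample)
    if len(ids) != len(set(ids)):
        raise ValueError("subsample contains duplicate society ids")
    if len(ids) < 2:
        raise ValueError("isolation weights need at least 2 societies")
    missing = sorted(set(ids) - set(dist.index))
    if missing:
        raise KeyError(f"societies missing from distance matrix: {missing}")
    sub = dist.loc[ids, ids].to_numpy(dtype=float)
    if not np.allclose(sub, sub.T):
        raise ValueError("distance matrix is not symmetric")
    if (sub < -1e-12).any():
        raise ValueError("distance matrix has negative entries")
    n = len(ids)
    m = sub.sum(axis=1) / (n - 1)  # zero diagonal: sum over j != i
    total = m.sum()
    if total <= 0:
        raise ValueError("all pairwise distances are zero; weights undefined")
    return pd.DataFrame({"raw_isolation": m, "weight": m / total}, index=ids)
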