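"""Cell QC, log-CPM normalization, HVG selection, and type-profile trees.

QC removes low-quality cells (too few counts or detected features) and
putative doublets (too many detected features). Type relationships are
summarized by the correlation distance ``Dist = (1 - cor) / 2`` between
mean expression profiles, visualized either as a centroid-agglomeration
dendrogram or as a neighbor-joining tree with gene-resampling bootstrap
supports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .containers import DistanceMatrix, ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)

# Low-quality / doublet thresholds used throughout: cells with total counts
# below 500 or fewer than 330 detected features are low-quality; cells with
# more than 8,950 detected features are putative doublets.
MIN_COUNTS = 500
MIN_FEATURES = 330
MAX_FEATURES = 8950


def qc_filter(
    dataset: ExpressionDataset,
    min_counts: int = MIN_COUNTS,
    min_features: int = MIN_FEATURES,
    max_features: int = MAX_FEATURES,
    low_quality_rule: str = "either",
) -> ExpressionDataset:
    """Remove low-quality cells and putative doublets.

    With ``low_quality_rule="either"`` (default) a cell is low-quality if it
    fails either minimum (counts < ``min_counts`` or features <
    ``min_features``); ``"both"`` requires it to fail both. Cells with
    detected features strictly above ``max_features`` are removed as
    doublets in both modes.
    """
    if low_quality_rule not in ("either", "both"):
        raise ValueError(f"unknown low_quality_rule {low_quality_rule!r}")
    totals = np.asarray(dataset.counts.sum(axis=1)).ravel()
    features = np.asarray((dataset.counts > 0).sum(axis=1)).ravel()
    low_counts = totals < min_counts
    low_features = features < min_features
    if low_quality_rule == "either":
        low_quality = low_counts | low_features
    else:
        low_quality = low_counts & low_features
    doublet = features > max_features
    keep = ~(low_quality | doublet)
    logger.info(
        "qc_filter: removed %d low-count, %d low-feature, %d doublet "
        "(%d kept of %d)",
        int(low_counts.sum()),
        int(low_features.sum()),
        int(doublet.sum()),
        int(keep.sum()),
        dataset.n_cells,
    )
    if not keep.any():
        raise ValidationError("qc_filter removed every cell")
    return dataset.subset_cells(keep)


def qc_report(
    dataset: ExpressionDataset,
    min_counts: int = MIN_COUNTS,
    min_features: int = MIN_FEATURES,
    max_features: int = MAX_FEATURES,
) -> pd.DataFrame:
    """Per-cell QC table: totals, features, and the rule each cell fails."""
    totals = np.asarray(dataset.counts.sum(axis=1)).ravel()
    features = np.asarray((dataset.counts > 0).sum(axis=1)).ravel()
    status = np.where(
        features > max_features,
        "doublet",
        np.where(
            (totals < min_counts) | (features < min_features), "low_quality", "pass"
        ),
    )
    return pd.DataFrame(
        {"total_counts": totals, "n_features": features, "status": status},
        index=dataset.cell_ids,
    )


def normalize_log_cpm(dataset: ExpressionDataset) -> np.ndarray:
    """log2(1 + CPM) normalization; returns a dense cells x genes matrix.

    CPM rescales each cell to one million counts, standardizing against
    sequencing depth. Cells with zero total counts are rejected — they
    should have been removed by :func:`qc_filter`.
    """
    totals = np.asarray(dataset.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = dataset.cell_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"cell {bad!r} has zero total counts")
    cpm = dataset.counts.multiply(1e6 / totals[:, None])
    return np.log2(1.0 + np.asarray(cpm.todense()))


def select_hvgs(matrix: np.ndarray, gene_ids, k: int) -> list[str]:
    """Top-k highly variable genes by standard deviation across cells.

    Ties are broken deterministically by gene id (lexicographic).
    """
    gene_ids = list(gene_ids)
    if k > len(gene_ids):
        raise ValidationError(f"k={k} exceeds {len(gene_ids)} genes")
    sd = np.std(np.asarray(matrix), axis=0, ddof=1)
    order = sorted(range(len(gene_ids)), key=lambda i: (-sd[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:k]]


def type_mean_profiles(
    matrix: np.ndarray, labels, gene_ids=None
) -> pd.DataFrame:
    """Mean log-normalized profile per label (types x genes)."""
    df = pd.DataFrame(np.asarray(matrix))
    if gene_ids is not None:
        df.columns = list(gene_ids)
    df["__label"] = list(labels)
    out = df.groupby("__label", sort=True).mean()
    out.index.name = None
    return out


# ---------------------------------------------------------------------------
# Correlation distance and trees
# ---------------------------------------------------------------------------


def correlation_distance(profiles: pd.DataFrame) -> DistanceMatrix:
    """Pairwise correlation distance Dist = (1 - Pearson r) / 2.

    ``profiles`` has one row per type. Zero-variance profiles have no
    defined correlation and are rejected by name.
    """
    X = profiles.to_numpy(dtype=float)
    labels = [str(i) for i in profiles.index]
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 profiles")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = labels[int(np.argmax(sd == 0))]
        raise ValidationError(f"profile {bad!r} has zero variance")
    r = np.corrcoef(X)
    D = (1.0 - r) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=labels, D=np.clip(D, 0.0, 1.0))


@dataclass
class TypeTree:
    """A tree over cell-type labels, Newick-serializable.

    ``supports`` maps each nontrivial bipartition (canonical frozenset of
    leaf names) to a bootstrap percentage in [0, 100].
    """

    tree: TreeNode
    supports: dict[frozenset, float] | None = None

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    def to_newick(self) -> str:
        return str(self.tree).strip()

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.tree, self.leaf_names)


def _bipartitions(tree: TreeNode, all_leaves: set[str]) -> set[frozenset]:
    """Nontrivial bipartitions induced by internal edges, canonicalized."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = frozenset(all_leaves - side)
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return out


def centroid_merge_order(D: DistanceMatrix) -> list[tuple[frozenset, float]]:
    """Centroid agglomeration: ordered merges of (merged leaf set, height).

    Centroid linkage runs through the Lance-Williams update on squared
    distances (treating the correlation distances as Euclidean); merge
    heights are the centroid distances and can invert, as is characteristic
    of centroid agglomeration. Ties in the closest pair are broken by the
    lexicographically smallest label pair, where a cluster is labeled by its
    smallest leaf.
    """
    n = len(D.labels)
    if n < 2:
        raise ValidationError("need at least 2 leaves")
    d2 = D.D.astype(float) ** 2
    leaves: dict[int, frozenset] = {i: frozenset([D.labels[i]]) for i in range(n)}
    name: dict[int, str] = {i: D.labels[i] for i in range(n)}
    size: dict[int, int] = {i: 1 for i in range(n)}
    dist = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[frozenset, float]] = []
    next_id = n
    while len(leaves) > 1:
        (i, j), d2_ij = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((name[kv[0][0]], name[kv[0][1]])))),
        )
        h = float(np.sqrt(max(d2_ij, 0.0)))
        ni, nj = size[i], size[j]
        merged = leaves[i] | leaves[j]
        merges.append((merged, h))
        for k in list(leaves):
            if k in (i, j):
                continue
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            dist[(min(k, next_id), max(k, next_id))] = (
                (ni * d_ik + nj * d_jk) / (ni + nj)
                - ni * nj * d2_ij / (ni + nj) ** 2
            )
        dist = {key: v for key, v in dist.items() if i not in key and j not in key}
        leaves[next_id] = merged
        name[next_id] = min(name[i], name[j])
        size[next_id] = ni + nj
        del leaves[i], leaves[j]
        next_id += 1
    return merges


def hclust_centroid(D: DistanceMatrix) -> TypeTree:
    """Agglomerative dendrogram under centroid linkage (see
    :func:`centroid_merge_order` for the update rule and tie-break)."""
    merges = centroid_merge_order(D)
    nodes: dict[frozenset, TreeNode] = {
        frozenset([lab]): TreeNode(name=lab) for lab in D.labels
    }
    heights: dict[frozenset, float] = {frozenset([lab]): 0.0 for lab in D.labels}
    for merged, h in merges:
        pair = _partition_children(nodes, merged)
        kids = []
        for key in pair:
            node = nodes.pop(key)
            # branch length: merge height minus child height (clamped at 0;
            # centroid inversions would otherwise give negative lengths)
            node.length = max(h - heights.pop(key), 0.0)
            kids.append(node)
        parent = TreeNode(children=kids)
        nodes[merged] = parent
        heights[merged] = h
    root = next(iter(nodes.values()))
    return TypeTree(tree=root)


def _partition_children(nodes: dict[frozenset, TreeNode], merged: frozenset):
    keys = [k for k in nodes if k <= merged]
    pair = [k for k in keys if len(k) > 0]
    # exactly two active clusters union to `merged`
    assert len(pair) == 2 and pair[0] | pair[1] == merged
    return pair


def nj_tree(
    D: DistanceMatrix,
    profiles: pd.DataFrame | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> TypeTree:
    """Neighbor-joining tree with optional gene-resampling bootstrap.

    When ``profiles`` (types x genes, same order/labels as ``D``) is given,
    ``n_bootstrap`` replicates resample gene columns with replacement,
    rebuild the correlation-distance NJ tree, and each internal edge of the
    main tree gets the percentage of replicates containing its bipartition.
    Fewer than 4 leaves degrade gracefully to a cherry/star with no
    meaningful supports.
    """
    tree = _nj_once(D)
    supports: dict[frozenset, float] | None = None
    if profiles is not None and n_bootstrap > 0 and len(D.labels) >= 4:
        if list(profiles.index.astype(str)) != list(D.labels):
            raise ValidationError("profiles index does not match distance labels")
        rng = np.random.default_rng(seed)
        all_leaves = set(D.labels)
        target = _bipartitions(tree, all_leaves)
        hits = {bp: 0 for bp in target}
        n_genes = profiles.shape[1]
        for _ in range(n_bootstrap):
            cols = rng.integers(0, n_genes, size=n_genes)
            Db = correlation_distance(profiles.iloc[:, cols])
            rep = _bipartitions(_nj_once(Db), all_leaves)
            for bp in target:
                if bp in rep:
                    hits[bp] += 1
        supports = {bp: 100.0 * h / n_bootstrap for bp, h in hits.items()}
        _annotate_supports(tree, all_leaves, supports)
    return TypeTree(tree=tree, supports=supports)


def _nj_once(D: DistanceMatrix) -> TreeNode:
    n = len(D.labels)
    if n < 2:
        raise ValidationError("need at least 2 leaves")
    if n == 2:
        a, b = D.labels
        half = D.D[0, 1] / 2
        return TreeNode(
            children=[TreeNode(name=a, length=half), TreeNode(name=b, length=half)]
        )
    dm = _SkbioDM(D.D, ids=D.labels)
    return _skbio_nj(dm)


def _annotate_supports(
    tree: TreeNode, all_leaves: set[str], supports: dict[frozenset, float]
) -> None:
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = frozenset(all_leaves - side)
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: tuple(sorted(s)))
        if key in supports:
            node.name = f"{supports[key]:g}"
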