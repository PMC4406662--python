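"""Gene-set heatmap ordering and group-level PCA.

Rows of a gene-set x comparison table of enrichment Z scores are ranked
by max |Z| across comparisons to pick the most differentially modulated
sets, then ordered by agglomerative hierarchical clustering (Euclidean
distance, average linkage by default). PCA is run on the per-group
replicate averages of the expression Z scores, as one point per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .normalize import SampleDesign


def select_top_sets(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k rows by max |Z| across columns, descending; ties by row id.

    Returns all rows (still re-ranked) when k exceeds the row count.
    """
    if table.empty:
        raise ValidationError("table is empty")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    score = table.abs().max(axis=1)
    order = sorted(table.index, key=lambda i: (-score[i], i))
    return table.loc[order[: min(k, len(order))]]


@dataclass
class LeafOrder:
    """Deterministic dendrogram leaf order plus the merge history.

    ``merges`` has one row per agglomeration: the two cluster ids merged
    (original rows are 0..n-1, new clusters n, n+1, ...), the merge
    height, and the size of the new cluster.
    """

    order: list[str]
    merges: pd.DataFrame


def hcluster(
    table: pd.DataFrame, metric: str = "euclidean", method: str = "average"
) -> LeafOrder:
    """Agglomerative clustering of rows for heatmap ordering.

    Rows are presented to the linkage in lexicographic id order so that
    distance ties resolve identically across runs.
    """
    if table.shape[0] < 2:
        raise ValidationError("hcluster needs >= 2 rows")
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("table contains non-finite values")
    ordered = table.sort_index()
    linkage = hierarchy.linkage(
        pdist(ordered.to_numpy(dtype=float), metric=metric), method=method
    )
    leaves = hierarchy.leaves_list(linkage)
    merges = pd.DataFrame(
        linkage, columns=["cluster_a", "cluster_b", "height", "size"]
    ).astype({"cluster_a": int, "cluster_b": int, "size": int})
    return LeafOrder(order=[ordered.index[i] for i in leaves], merges=merges)


@dataclass
class PcaResult:
    """PCA of the group means: coordinates, loadings, explained variance.

    ``coordinates`` has one row per group and <= (n_groups - 1) columns;
    ``explained`` the variance fraction per component. ``degenerate`` is
    set when all group means coincide (zero total variance), with all
    coordinates 0.
    """

    coordinates: pd.DataFrame
    loadings: pd.DataFrame
    explained: pd.Series
    degenerate: bool = False


def pca_groups(z: pd.DataFrame, design: SampleDesign) -> PcaResult:
    """PCA on per-group replicate-average Z scores (one point per group).

    Component signs are fixed by making each component's largest-magnitude
    gene loading positive, so outputs are reproducible.
    """
    if len(design.groups) < 2:
        raise ValidationError("pca_groups needs >= 2 groups")
    means = pd.DataFrame(
        {g: z[design.samples_in(g)].mean(axis=1) for g in design.groups}
    )
    centered = means.sub(means.mean(axis=1), axis=0)  # center across groups
    x = centered.to_numpy(dtype=float).T  # groups x genes
    n_comp = min(len(design.groups) - 1, x.shape[1])
    pc_names = [f"PC{i + 1}" for i in range(n_comp)]
    total_var = float((x**2).sum())
    if total_var == 0:
        return PcaResult(
            coordinates=pd.DataFrame(0.0, index=list(design.groups), columns=pc_names),
            loadings=pd.DataFrame(0.0, index=z.index, columns=pc_names),
            explained=pd.Series(0.0, index=pc_names),
            degenerate=True,
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    # sign convention: largest-|loading| entry positive per component
    for i in range(n_comp):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u * s
    explained = s**2 / (s**2).sum() if (s**2).sum() > 0 else np.zeros(n_comp)
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=list(design.groups), columns=pc_names),
        loadings=pd.DataFrame(vt.T, index=z.index, columns=pc_names),
        explained=pd.Series(explained, index=pc_names),
        degenerate=False,
    )
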