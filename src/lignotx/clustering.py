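"""Hierarchical clustering of log2 condition means and heat-map rendering.

Genes are clustered on their per-condition mean log2 expression vectors with
agglomerative clustering on Euclidean distances (average linkage by default).
Heat maps use the 0 (dark blue) to 16 (dark red) log2 color scale; display
values are clipped to that range, the underlying data are not.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Literal

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression import DISPLAY_RANGE, ExpressionMatrix

Linkage = Literal["average", "complete", "single"]

#: dark blue -> white-ish midpoint -> dark red, anchored at the display range
HEATMAP_CMAP = LinearSegmentedColormap.from_list(
    "expression", ["#00008b", "#4169e1", "#f5f5dc", "#ff4500", "#8b0000"]
)


def condition_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene arithmetic mean of log2 replicate values for each condition."""
    return matrix.condition_means()


@dataclass
class Dendrogram:
    """Binary merge tree over gene leaves with Euclidean merge heights.

    ``linkage_matrix`` is the scipy (n-1, 4) encoding; ``leaves`` are the
    gene ids in the order handed to the linkage (lexicographically sorted for
    a deterministic tie-break).
    """

    linkage_matrix: np.ndarray
    leaves: list[str]
    method: str = "average"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.leaves[i] for i in order]

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.leaves, (int(x) for x in labels)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 4 * len(self.leaves) + 100))
        try:

            def fmt(node, parent_height: float) -> str:
                length = parent_height - (0.0 if node.is_leaf() else node.dist)
                if node.is_leaf():
                    length = parent_height
                    return f"{self.leaves[node.id]}:{length:.6g}"
                left = fmt(node.left, node.dist)
                right = fmt(node.right, node.dist)
                return f"({left},{right}):{length:.6g}"

            left = fmt(tree.left, tree.dist)
            right = fmt(tree.right, tree.dist)
            return f"({left},{right});"
        finally:
            sys.setrecursionlimit(limit)


def hierarchical_cluster(means: pd.DataFrame, linkage: Linkage = "average") -> Dendrogram:
    """Agglomerative clustering of genes on Euclidean condition-mean distances.

    Rows are sorted lexicographically by gene id before linkage so that ties
    resolve deterministically; duplicate rows (distance 0) merge first.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if len(means) < 2:
        raise ValueError("clustering needs at least two genes")
    ordered = means.sort_index(kind="stable")
    dist = pdist(ordered.to_numpy(dtype=float), metric="euclidean")
    Z = hierarchy.linkage(dist, method=linkage)
    return Dendrogram(Z, [str(g) for g in ordered.index], method=linkage)


@dataclass
class HeatmapSpec:
    """What a Figure-2/4-style heat map shows.

    ``means``: gene x condition log2 means; ``row_order``: display order of
    gene rows (e.g. a dendrogram leaf order); columns are displayed in the
    order given by ``column_order`` (default: as in ``means``).
    """

    means: pd.DataFrame
    row_order: list[str] | None = None
    column_order: list[str] | None = None
    vmin: float = DISPLAY_RANGE[0]
    vmax: float = DISPLAY_RANGE[1]

    def ordered(self) -> pd.DataFrame:
        out = self.means
        if self.row_order is not None:
            out = out.loc[self.row_order]
        if self.column_order is not None:
            out = out[self.column_order]
        return out


def render_heatmap(spec: HeatmapSpec, image_path, tsv_path) -> pd.DataFrame:
    """Write a heat-map image and a row-order TSV of the displayed values.

    Display values are clipped to [vmin, vmax]; the TSV retains the
    unclipped data so figure content stays testable without pixel
    comparison. Returns the TSV frame (row_rank, gene_id, one column per
    condition).
    """
    data = spec.ordered()
    if data.empty:
        raise ValueError("cannot render an empty heat map")
    fig_h = max(2.0, 0.12 * len(data) + 1.2)
    fig, ax = plt.subplots(figsize=(4.0, fig_h))
    ax.imshow(
        np.clip(data.to_numpy(dtype=float), spec.vmin, spec.vmax),
        aspect="auto",
        cmap=HEATMAP_CMAP,
        vmin=spec.vmin,
        vmax=spec.vmax,
        interpolation="nearest",
    )
    ax.set_xticks(range(data.shape[1]), [str(c) for c in data.columns], rotation=45, ha="right")
    if len(data) <= 60:
        ax.set_yticks(range(len(data)), [str(g) for g in data.index], fontsize=5)
    else:
        ax.set_yticks([])
    fig.colorbar(ax.images[0], ax=ax, label="log2 expression")
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)

    out = data.copy()
    out.insert(0, "row_rank", range(1, len(out) + 1))
    out.index.name = "gene_id"
    out.to_csv(tsv_path, sep="\t")
    return out
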