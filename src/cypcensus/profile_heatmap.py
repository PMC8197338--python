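"""Presence/absence profiles of P450 families across species.

Census heat maps code family presence as **3** and absence as **-3**
(rendered red/green in the original viewers), then cluster both axes
hierarchically under a Euclidean metric so species with similar P450
repertoires, and families with similar distributions, sit together.
Average linkage is the default (the classic Mev hierarchical-clustering
default); complete and single linkage are available.

The matrix has one row per P450-bearing species and one column per
observed family, so no all-absent column can exist.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PRESENT",
    "ABSENT",
    "PresenceMatrix",
    "build_presence_matrix",
    "cluster_matrix",
    "co_presence_counts",
    "linkage_to_newick",
]

PRESENT = 3
ABSENT = -3


@dataclass(frozen=True)
class PresenceMatrix:
    """Species x family matrix over {-3, 3} plus optional cluster results.

    ``row_order`` / ``col_order`` are leaf orderings after clustering;
    the linkage matrices are in scipy's standard form.
    """

    values: pd.DataFrame
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = set(np.unique(self.values.to_numpy())) if self.values.size else set()
        if not vals <= {PRESENT, ABSENT}:
            raise ValueError(f"matrix values must be in {{{ABSENT}, {PRESENT}}}, got {vals}")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def families(self) -> list[str]:
        return list(self.values.columns)

    @property
    def row_order(self) -> list[str]:
        if self.row_linkage is None:
            return self.species
        leaves = hierarchy.leaves_list(self.row_linkage)
        return [self.species[i] for i in leaves]

    @property
    def col_order(self) -> list[str]:
        if self.col_linkage is None:
            return self.families
        leaves = hierarchy.leaves_list(self.col_linkage)
        return [self.families[i] for i in leaves]

    # -- serialisation ------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="species")
        df.columns = [str(c) for c in df.columns]
        df.index.name = None
        return cls(values=df.astype(int))

    def row_newick(self) -> str | None:
        if self.row_linkage is None:
            return None
        return linkage_to_newick(self.row_linkage, self.species)

    def col_newick(self) -> str | None:
        if self.col_linkage is None:
            return None
        return linkage_to_newick(self.col_linkage, self.families)

    def save_png(self, path: str | Path) -> None:
        """Optional rendered heat map (presence red, absence green)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        ordered = self.values.loc[self.row_order, self.col_order]
        fig, ax = plt.subplots(
            figsize=(max(4, 0.25 * len(self.families)),
                     max(3, 0.25 * len(self.species)))
        )
        ax.imshow(ordered.to_numpy(), cmap=ListedColormap(["green", "red"]),
                  aspect="auto", interpolation="nearest")
        ax.set_xticks(range(len(ordered.columns)),
                      [f"CYP{f}" for f in ordered.columns], rotation=90, fontsize=6)
        ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=6)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_presence_matrix(
    counts: pd.DataFrame | Mapping[str, Mapping[str, int]],
) -> PresenceMatrix:
    """Code per-species family counts into the -3/3 presence matrix.

    ``counts`` is a species x family count table (as produced by
    ``census_stats.per_species_family_counts``) or an equivalent nested
    mapping; any count >= 1 codes as presence.
    """
    df = pd.DataFrame(counts).T if isinstance(counts, Mapping) else counts
    if df.size == 0:
        return PresenceMatrix(values=pd.DataFrame())
    df = df.fillna(0)
    coded = df.map(lambda c: PRESENT if c >= 1 else ABSENT).astype(int)
    coded = coded.loc[:, (coded == PRESENT).any(axis=0)]  # observed families only
    coded.columns = [str(c) for c in coded.columns]
    return PresenceMatrix(values=coded.sort_index())


def cluster_matrix(
    m: PresenceMatrix,
    metric: str = "euclidean",
    linkage: str = "average",
) -> PresenceMatrix:
    """Agglomerative clustering of both axes; an axis with fewer than two
    labels keeps its identity ordering and gets no dendrogram."""
    mat = m.values.to_numpy(dtype=float)
    row_link = col_link = None
    if mat.shape[0] >= 2:
        row_link = hierarchy.linkage(pdist(mat, metric=metric), method=linkage)
    if mat.shape[1] >= 2:
        col_link = hierarchy.linkage(pdist(mat.T, metric=metric), method=linkage)
    return replace(m, row_linkage=row_link, col_linkage=col_link)


def co_presence_counts(m: PresenceMatrix) -> pd.DataFrame:
    """Family x family table: number of species presenting both families."""
    indicator = (m.values == PRESENT).astype(int)
    return indicator.T @ indicator


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree.

    Branch lengths are the difference between a node's merge height and
    its child's, so root-to-leaf distances equal cophenetic heights.
    """
    tree = hierarchy.to_tree(link)

    def render(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            name = labels[node.id].replace(" ", "_")
            return f"{name}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"
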