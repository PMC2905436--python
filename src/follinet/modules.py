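"""Module detection: average-linkage clustering of 1-TOM and dynamic tree cut.

Genes are clustered by average linkage (UPGMA) on the topological
overlap dissimilarity d = 1 - TOM.  Branches of the dendrogram are then
cut adaptively: an initial static cut high up the dendrogram delimits
candidate branches, and each candidate is accepted as a module when it
is large enough, internally tight (core scatter below a threshold) and
not itself a merge of two well-separated module-sized branches;
otherwise the procedure descends into its sub-branches.
Genes ending up in no accepted branch are left unassigned ("grey").
Accepted modules are named by the conventional colour palette in order
of decreasing size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "GREY",
    "MODULE_COLORS",
    "ModuleAssignment",
    "dissimilarity",
    "average_linkage",
    "dynamic_tree_cut",
    "assign_colors",
    "detect_modules",
    "dendrogram_to_newick",
]

GREY = "grey"

#: colour palette applied to modules in decreasing size order
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

#: deep-split level -> maximum relative core scatter (tighter when low)
_CORE_SCATTER = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91}


@dataclass
class ModuleAssignment:
    """Per-gene module colour labels plus the parameters that produced them."""

    label_of: dict[str, str]
    module_sizes: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def labels(self, genes: list[str]) -> np.ndarray:
        return np.array([self.label_of[g] for g in genes])

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def grey_count(self) -> int:
        return sum(1 for c in self.label_of.values() if c == GREY)


def dissimilarity(tom: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap dissimilarity d_ij = 1 - TOM_ij (zero diagonal)."""
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=tom.index, columns=tom.columns)


def average_linkage(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """UPGMA linkage matrix (scipy encoding) from a square distance matrix."""
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    return linkage(squareform(d, checks=False), method="average")


def _subtree_members(Z: np.ndarray, n: int) -> list[np.ndarray]:
    """Leaf index arrays for each internal node (bottom-up, no recursion)."""
    members: list[np.ndarray] = []
    for i in range(Z.shape[0]):
        parts = []
        for child in (int(Z[i, 0]), int(Z[i, 1])):
            parts.append(np.array([child]) if child < n else members[child - n])
        members.append(np.concatenate(parts))
    return members


def _mean_within(d: np.ndarray, idx: np.ndarray) -> float:
    if idx.size < 2:
        return 0.0
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / (idx.size * (idx.size - 1)))


def _core_scatter(d: np.ndarray, idx: np.ndarray, min_size: int) -> float:
    """Mean pairwise dissimilarity over the branch's tightest members.

    The core holds min(min_size, 2 + sqrt(size)) leaves with the lowest
    mean distance to the rest of the branch, so stragglers on an
    otherwise tight branch do not disqualify it.
    """
    if idx.size < 2:
        return 0.0
    sub = d[np.ix_(idx, idx)]
    core_n = max(2, min(min_size, 2 + int(np.sqrt(idx.size))))
    if core_n >= idx.size:
        return _mean_within(d, idx)
    mean_dist = sub.sum(axis=1) / (idx.size - 1)
    core = np.argsort(mean_dist, kind="stable")[:core_n]
    return _mean_within(sub, core)


def dynamic_tree_cut(
    Z: np.ndarray,
    dist: pd.DataFrame | np.ndarray,
    min_size: int = 20,
    deep_split: int = 2,
    cut_height_fraction: float = 0.99,
    max_core_scatter: float | None = None,
    min_gap: float | None = None,
) -> np.ndarray:
    """Adaptive branch cutting of a dendrogram into module labels.

    Returns an integer label per leaf: 0 for unassigned (grey), 1..m for
    modules in order of discovery.  An initial static cut at
    ``cut_height_fraction`` of the dendrogram height range delimits
    candidate branches; a candidate is accepted as a module when

    * it has at least ``min_size`` leaves,
    * its mean within-branch dissimilarity (scatter) stays below a
      threshold derived from ``deep_split``,
    * the gap between its top merge and the height at which it joins the
      rest of the tree is large enough, and
    * its own top merge does not itself split it into two well-separated
      branches of module size (in which case the cut descends).

    A failing branch is split into its children and re-tested; leaves
    ending up in no accepted branch are unassigned (grey).
    ``deep_split`` (0-3) relaxes the scatter threshold and narrows the
    gap requirement, producing more, smaller modules; explicit
    ``max_core_scatter`` / ``min_gap`` (absolute dissimilarities)
    override the level-derived defaults.  Deterministic for fixed input.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if deep_split not in _CORE_SCATTER:
        raise ValueError("deep_split must be one of 0, 1, 2, 3")
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    n = Z.shape[0] + 1
    labels = np.zeros(n, dtype=int)
    if min_size > n:
        warnings.warn(
            f"min_size={min_size} exceeds the number of genes ({n}); all genes grey",
            stacklevel=2,
        )
        return labels

    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    h0 = hmin + cut_height_fraction * (hmax - hmin)
    base = float(np.quantile(heights, 0.05))
    span = max(h0 - base, 0.0)
    mcs = _CORE_SCATTER[deep_split]
    scatter_cap = base + mcs * span if max_core_scatter is None else max_core_scatter
    # split-gap floor calibrated on planted-module fixtures: boundary gaps
    # between tight merged modules run ~2x smaller than the classical
    # (1-mcs)*3/4 acceptance floor
    gap_floor = (1.0 - mcs) * 0.375 * span if min_gap is None else min_gap

    members = _subtree_members(Z, n)
    node_height = lambda node: 0.0 if node < n else heights[node - n]
    node_members = lambda node: (
        np.array([node]) if node < n else members[node - n]
    )

    # maximal branches whose top merge sits at or below the static cut;
    # each keeps the height at which it attaches to the rest of the tree
    initial: list[tuple[int, float]] = []
    stack: list[tuple[int, float]] = [(2 * n - 2, np.inf)]
    while stack:
        node, attach = stack.pop()
        if node_height(node) <= h0:
            initial.append((node, attach))
        else:
            h = node_height(node)
            stack.append((int(Z[node - n, 0]), h))
            stack.append((int(Z[node - n, 1]), h))

    next_label = 1
    work = sorted(initial)
    while work:
        node, attach = work.pop(0)
        idx = node_members(node)
        if idx.size < min_size:
            continue  # leaves stay grey
        h = node_height(node)
        children = None if node < n else (int(Z[node - n, 0]), int(Z[node - n, 1]))
        # top-split: the branch's own top merge joins two module-sized,
        # well-separated sub-branches -> descend rather than accept.
        # Separation shows either as a height gap below the merge or as
        # between-children dissimilarity exceeding the within-children one.
        split_top = False
        if children is not None:
            kids = [node_members(c) for c in children]
            if all(k.size >= min_size for k in kids):
                gaps = [h - node_height(c) for c in children]
                if all(g >= gap_floor for g in gaps):
                    split_top = True
                else:
                    cross = float(d[np.ix_(kids[0], kids[1])].mean())
                    within = max(_mean_within(d, k) for k in kids)
                    split_top = cross - within >= gap_floor
        if not split_top and _core_scatter(d, idx, min_size) <= scatter_cap:
            labels[idx] = next_label
            next_label += 1
        elif children is not None:
            work.append((children[0], h))
            work.append((children[1], h))
    return labels


def assign_colors(
    labels: np.ndarray,
    genes: list[str],
    min_size: int | None = None,
    parameters: dict | None = None,
) -> ModuleAssignment:
    """Name numeric module labels with the colour palette by falling size.

    Ties in size are broken by the smallest member gene ID; label 0 is
    grey.  If there are more modules than palette entries, the overflow
    gets indexed names ("module31", ...).
    """
    labels = np.asarray(labels)
    uniq = [l for l in np.unique(labels) if l != 0]
    stats = []
    for l in uniq:
        idx = np.flatnonzero(labels == l)
        stats.append((-idx.size, min(genes[i] for i in idx), l))
    stats.sort()
    color_of_label = {}
    for rank, (_, _, l) in enumerate(stats):
        color_of_label[l] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
    label_of = {
        g: (GREY if labels[i] == 0 else color_of_label[labels[i]])
        for i, g in enumerate(genes)
    }
    sizes = {
        color_of_label[l]: int((labels == l).sum()) for l in uniq
    }
    params = dict(parameters or {})
    if min_size is not None:
        params.setdefault("min_size", min_size)
    return ModuleAssignment(label_of=label_of, module_sizes=sizes, parameters=params)


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = 20,
    deep_split: int = 2,
    cut_height_fraction: float = 0.99,
    max_core_scatter: float | None = None,
    min_gap: float | None = None,
) -> tuple[ModuleAssignment, np.ndarray]:
    """Full detection pass: 1-TOM, UPGMA, dynamic cut, colour naming."""
    d = dissimilarity(tom)
    Z = average_linkage(d)
    raw = dynamic_tree_cut(
        Z, d, min_size=min_size, deep_split=deep_split,
        cut_height_fraction=cut_height_fraction,
        max_core_scatter=max_core_scatter, min_gap=min_gap,
    )
    assignment = assign_colors(
        raw, list(tom.index), min_size=min_size,
        parameters={"deep_split": deep_split, "cut_height_fraction": cut_height_fraction},
    )
    return assignment, Z


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as Newick, branch lengths from merge heights."""
    n = Z.shape[0] + 1
    heights = Z[:, 2]
    height = lambda node: 0.0 if node < n else heights[node - n]
    # iterative post-order assembly
    text: dict[int, str] = {}
    stack: list[tuple[int, bool]] = [(2 * n - 2, False)]
    while stack:
        node, expanded = stack.pop()
        if node < n:
            text[node] = labels[node]
            continue
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        if not expanded:
            stack.append((node, True))
            stack.append((a, False))
            stack.append((b, False))
        else:
            h = height(node)
            la = max(h - height(a), 0.0)
            lb = max(h - height(b), 0.0)
            text[node] = f"({text[a]}:{la:.10g},{text[b]}:{lb:.10g})"
    return text[2 * n - 2] + ";"
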