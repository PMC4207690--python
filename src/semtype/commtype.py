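"""Community typing: weighted UniFrac, UPGMA clustering, pseudo-F, diversity, PCoA.

The cohort is typed by computing pairwise weighted-UniFrac distances between
species-level relative-abundance profiles on a rooted reference phylogeny,
building a UPGMA dendrogram, and cutting it at the number of groups k that
maximizes the Calinski-Harabasz pseudo-F statistic. Alpha diversity (Shannon
entropy in nats, bias-corrected Chao1 richness) and principal-coordinates
embeddings support the downstream comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import chao1 as _skbio_chao1
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import calinski_harabasz_score

from . import assoc

__all__ = [
    "weighted_unifrac",
    "unifrac_matrix",
    "Dendrogram",
    "upgma_cluster",
    "pseudo_f",
    "choose_k",
    "shannon",
    "chao1",
    "pcoa",
    "diversity_table",
    "compare_group_diversity",
    "CommunityTyper",
]

_SIMPLEX_TOL = 1e-9


def _as_profile(p, leaves: Sequence[str]) -> np.ndarray:
    """Validate a simplex profile and expand it onto the tree's leaf order."""
    if isinstance(p, Mapping) or isinstance(p, pd.Series):
        s = pd.Series(p, dtype=float)
        extra = set(s.index) - set(leaves)
        if extra:
            raise ValueError(f"taxa absent from the tree: {sorted(extra)}")
        v = s.reindex(leaves, fill_value=0.0).to_numpy()
    else:
        v = np.asarray(p, dtype=float)
        if v.shape != (len(leaves),):
            raise ValueError("profile length does not match the tree's leaf count")
    if np.any(v < -_SIMPLEX_TOL):
        raise ValueError("profile has negative entries")
    if abs(v.sum() - 1.0) > 1e-6:
        raise ValueError(f"profile does not sum to 1 (sum = {v.sum():.6g})")
    return np.clip(v, 0.0, None)


def _tree_arrays(tree: TreeNode):
    """Postorder branch lengths, per-branch descendant-leaf indicators, leaf depths."""
    leaves = [lf.name for lf in tree.tips()]
    leaf_idx = {name: i for i, name in enumerate(leaves)}
    lengths = []
    indicators = []
    node_leafsets: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(len(leaves))
            mask[leaf_idx[node.name]] = 1.0
        else:
            mask = np.zeros(len(leaves))
            for child in node.children:
                mask += node_leafsets[id(child)]
        node_leafsets[id(node)] = mask
        if node.parent is not None:  # root carries no branch
            lengths.append(float(node.length or 0.0))
            indicators.append(mask)
    depths = np.zeros(len(leaves))
    for lf in tree.tips():
        d, node = 0.0, lf
        while node.parent is not None:
            d += float(node.length or 0.0)
            node = node.parent
        depths[leaf_idx[lf.name]] = d
    return leaves, np.array(lengths), np.array(indicators), depths


def weighted_unifrac(pA, pB, tree: TreeNode, normalized: bool = True) -> float:
    """Weighted UniFrac distance between two relative-abundance profiles.

    The raw statistic sums, over every branch, the branch length times the
    absolute difference between the fractions of each community descending
    through that branch. With ``normalized=True`` (default) it is divided by
    sum_j d_j (pA_j + pB_j), where d_j is the root-to-leaf path length, which
    bounds the distance in [0, 1].
    """
    leaves, lengths, indicators, depths = _tree_arrays(tree)
    a = _as_profile(pA, leaves)
    b = _as_profile(pB, leaves)
    raw = float(np.sum(lengths * np.abs(indicators @ a - indicators @ b)))
    if not normalized:
        return raw
    denom = float(np.sum(depths * (a + b)))
    if denom == 0.0:
        return 0.0
    return raw / denom


def unifrac_matrix(
    profiles: pd.DataFrame, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """All-pairs weighted UniFrac on a samples x taxa proportion matrix."""
    leaves, lengths, indicators, depths = _tree_arrays(tree)
    rows = np.vstack([_as_profile(profiles.loc[s], leaves) for s in profiles.index])
    masses = rows @ indicators.T  # sample x branch descendant mass
    leafdepth = rows @ depths
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        raw = np.sum(lengths * np.abs(masses[i] - masses[i + 1:]), axis=1)
        if normalized:
            denom = leafdepth[i] + leafdepth[i + 1:]
            raw = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
        d[i, i + 1:] = raw
        d[i + 1:, i] = raw
    return DistanceMatrix(d, ids=[str(s) for s in profiles.index])


@dataclass
class Dendrogram:
    """UPGMA merge history in scipy linkage format over ``ids``."""

    ids: list[str]
    linkage: np.ndarray  # (n-1, 4): left, right, height, size

    def cut(self, k: int) -> pd.Series:
        """Cut into exactly k groups named G1..Gk.

        Groups come from undoing the last k-1 merges; names follow the order of
        each group's first sample in ``ids``.
        """
        n = len(self.ids)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        parent = list(range(2 * n - 1))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for m in range(n - k):
            left, right = int(self.linkage[m, 0]), int(self.linkage[m, 1])
            parent[find(left)] = n + m
            parent[find(right)] = n + m
        roots: dict[int, list[int]] = {}
        for i in range(n):
            roots.setdefault(find(i), []).append(i)
        clusters = sorted(roots.values(), key=min)
        labels = {}
        for g, members in enumerate(clusters, start=1):
            for i in members:
                labels[self.ids[i]] = f"G{g}"
        return pd.Series(labels, name="group").reindex(self.ids)

    def to_newick(self) -> str:
        n = len(self.ids)
        height = {i: 0.0 for i in range(n)}
        text = {i: self.ids[i] for i in range(n)}
        for m in range(n - 1):
            left, right, h = int(self.linkage[m, 0]), int(self.linkage[m, 1]), self.linkage[m, 2]
            bl_l, bl_r = h - height[left], h - height[right]
            text[n + m] = f"({text[left]}:{bl_l:.6g},{text[right]}:{bl_r:.6g})"
            height[n + m] = h
        return text[2 * n - 2] + ";"


def upgma_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Ties on the minimum pairwise distance are broken by the lexicographically
    smallest pair of cluster labels (a cluster is labelled by its smallest
    member id), making the merge history fully deterministic.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("clustering requires at least 2 samples")
    d = {(i, j): dm[i, j] for i in range(n) for j in range(i + 1, n)}
    # cluster index -> (representative label, size); indices >= n are merges
    label = {i: ids[i] for i in range(n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    linkage = np.zeros((n - 1, 4))
    for m in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                key = (d[(min(i, j), max(i, j))],) + tuple(sorted((label[i], label[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[(min(i, j), max(i, j))]
        new = n + m
        for k in active:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(k, new)] = (size[i] * dik + size[j] * djk) / (size[i] + size[j])
        active -= {i, j}
        active.add(new)
        label[new] = min(label[i], label[j])
        size[new] = size[i] + size[j]
        linkage[m] = (i, j, dij / 2.0, size[new])
    return Dendrogram(ids=ids, linkage=linkage)


def pcoa(dm) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates analysis of a distance matrix.

    Gower-centers -D^2/2, eigendecomposes, keeps axes with eigenvalue > 1e-10,
    scales coordinates by sqrt(eigenvalue), and orients each axis so its
    largest-magnitude coordinate is positive. Returns (coordinates, all
    eigenvalues in descending order); negative eigenvalues (non-Euclidean
    input) are reported but their axes dropped.
    """
    if isinstance(dm, DistanceMatrix):
        ids, d = list(dm.ids), dm.data
    else:
        d = np.asarray(dm, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("pcoa requires a symmetric square distance matrix")
        ids = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-10
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    for ax in range(coords.shape[1]):
        col = coords[:, ax]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, ax] = -col
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=ids, columns=cols), evals


def pseudo_f(dm, labels, coords: pd.DataFrame | None = None, on: str = "pcoa") -> float:
    """Calinski-Harabasz pseudo-F for a clustering of a distance matrix.

    By default computed on PCoA coordinates (positive-eigenvalue axes), since
    UniFrac matrices need not embed exactly in Euclidean space; ``on='distance'``
    uses the sums-of-squared-distances form directly.
    """
    labels = pd.Series(labels)
    counts = labels.value_counts()
    k, n = len(counts), len(labels)
    if k < 2 or k >= n:
        raise ValueError(f"pseudo-F undefined for k={k} with n={n}")
    if on == "distance":
        d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
        idx = {s: i for i, s in enumerate(dm.ids)} if isinstance(dm, DistanceMatrix) \
            else {s: i for i, s in enumerate(labels.index)}
        sq = d ** 2
        tss = sq.sum() / (2 * n)
        wss = 0.0
        for g, members in labels.groupby(labels).groups.items():
            ii = [idx[str(m)] if str(m) in idx else idx[m] for m in members]
            wss += sq[np.ix_(ii, ii)].sum() / (2 * len(ii))
    else:
        if coords is None:
            coords, _ = pcoa(dm)
        x = coords.loc[[str(s) for s in labels.index]].to_numpy()
        return float(calinski_harabasz_score(x, labels.to_numpy()))
    return float(((tss - wss) / (k - 1)) / (wss / (n - k)))


def choose_k(
    dm: DistanceMatrix,
    dendrogram: Dendrogram,
    k_range: Iterable[int] = range(2, 11),
    on: str = "pcoa",
) -> tuple[int, dict[int, float]]:
    """Pseudo-F over dendrogram cuts; returns (argmax k, full trace).

    Ties go to the smallest k. k values outside [2, n-1] are skipped.
    """
    coords, _ = pcoa(dm) if on == "pcoa" else (None, None)
    n = len(dendrogram.ids)
    trace: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = dendrogram.cut(k)
        trace[k] = pseudo_f(dm, labels, coords=coords, on=on)
    if not trace:
        raise ValueError("no admissible k in k_range")
    chosen = min(trace, key=lambda k: (-trace[k], k))
    return chosen, trace


def shannon(p) -> float:
    """Shannon entropy of a relative-abundance vector, in nats."""
    v = np.asarray(p, dtype=float)
    if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
        raise ValueError("shannon requires a simplex vector")
    nz = v[v > 0]
    return float(-(nz * np.log(nz)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    c = np.asarray(counts)
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
        if np.issubdtype(c.dtype, np.floating) and np.all(c == np.floor(c)) and np.all(c >= 0):
            c = c.astype(int)
        else:
            raise ValueError("chao1 requires nonnegative integer read counts")
    return float(_skbio_chao1(c, bias_corrected=True))


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon (on proportions), Chao1, and observed-taxon count."""
    rows = []
    for s in counts.index:
        c = counts.loc[s].to_numpy()
        total = c.sum()
        if total == 0:
            raise ValueError(f"sample {s!r} has zero assigned reads")
        rows.append(
            {
                "sample_id": s,
                "shannon": shannon(c / total),
                "chao1": chao1(c.astype(int)),
                "observed_taxa": int((c > 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_group_diversity(table: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests per diversity metric.

    ``grouping`` maps each sample in ``table`` to a group; every group must be
    nonempty and every sample must belong to exactly one group.
    """
    grouping = pd.Series(grouping)
    groups = sorted(grouping.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    members = {g: grouping.index[grouping == g] for g in groups}
    for g, m in members.items():
        if len(m) == 0:
            raise ValueError(f"group {g!r} is empty")
        missing = [s for s in m if s not in table.index]
        if missing:
            raise ValueError(f"samples missing from diversity table: {missing}")
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            for metric in table.columns:
                p = assoc.mann_whitney(
                    table.loc[members[g1], metric], table.loc[members[g2], metric]
                )
                rows.append({"metric": metric, "group1": g1, "group2": g2, "p": p})
    return pd.DataFrame(rows)


class CommunityTyper(BaseEstimator, ClusterMixin):
    """Cluster samples into community types from species-level proportions.

    Computes weighted UniFrac on the given rooted tree, builds a UPGMA
    dendrogram, and either cuts at a fixed ``k`` or selects k in ``k_range``
    by maximizing the Calinski-Harabasz pseudo-F on PCoA coordinates.

    Parameters
    ----------
    tree : skbio.TreeNode or newick str
        Rooted phylogeny with branch lengths over the profile's taxa.
    k : int or None
        Number of groups; None selects by pseudo-F.
    k_range : tuple
        Inclusive (low, high) range of candidate k when selecting.
    normalized : bool
        Use the [0, 1]-normalized weighted UniFrac.
    pseudo_f_on : str
        'pcoa' (default) or 'distance'.

    Attributes
    ----------
    distance_matrix_ : skbio.DistanceMatrix
    dendrogram_ : Dendrogram
    pseudo_f_trace_ : dict k -> pseudo-F
    chosen_k_ : int
    labels_ : pd.Series sample -> 'G1'..'Gk'
    """

    def __init__(self, tree=None, k=None, k_range=(2, 10), normalized=True,
                 pseudo_f_on="pcoa"):
        self.tree = tree
        self.k = k
        self.k_range = k_range
        self.normalized = normalized
        self.pseudo_f_on = pseudo_f_on

    def _tree(self) -> TreeNode:
        if self.tree is None:
            raise ValueError("CommunityTyper requires a reference tree")
        if isinstance(self.tree, TreeNode):
            return self.tree
        return TreeNode.read([self.tree], convert_underscores=False)

    def fit(self, X: pd.DataFrame, y=None):
        tree = self._tree()
        self.distance_matrix_ = unifrac_matrix(X, tree, normalized=self.normalized)
        self.dendrogram_ = upgma_cluster(self.distance_matrix_)
        if self.k is None:
            lo, hi = self.k_range
            self.chosen_k_, self.pseudo_f_trace_ = choose_k(
                self.distance_matrix_, self.dendrogram_,
                k_range=range(lo, hi + 1), on=self.pseudo_f_on,
            )
        else:
            self.chosen_k_ = int(self.k)
            _, self.pseudo_f_trace_ = choose_k(
                self.distance_matrix_, self.dendrogram_,
                k_range=[self.chosen_k_], on=self.pseudo_f_on,
            ) if 2 <= self.k <= len(X) - 1 else (self.k, {})
        self.labels_ = self.dendrogram_.cut(self.chosen_k_)
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).labels_
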