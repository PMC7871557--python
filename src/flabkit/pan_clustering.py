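"""Hierarchical clustering of strains by gene-family presence/absence.

Strains are compared on their binary metabolic gene-content profiles and
clustered agglomeratively (Lance-Williams updates).  The scientific
question the module answers is whether a designated focal set of strains
-- phylogenetically scattered, but suspected of convergent gene loss --
ends up in a single cluster when the tree is cut at a given number of
clusters.  Co-clustering of a polyphyletic focal group on gene *content*
(against the grain of the phylogeny) is the convergence signal.

Equal-height merges are broken deterministically by the lexicographically
smallest member strain id, so dendrograms and their Newick exports are
reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import PresenceMatrix

__all__ = [
    "Dendrogram",
    "ClusterReport",
    "binary_distance",
    "hierarchical_cluster",
    "evaluate_focal_cluster",
    "sweep_focal_cluster",
]

LINKAGES = ("average", "complete", "ward")
METRICS = ("jaccard", "hamming")


def binary_distance(presence: PresenceMatrix, metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise strain distances on binary gene-content profiles.

    ``jaccard``: 1 - |intersection| / |union| (0 when both profiles are
    empty).  ``hamming``: mismatching families / total families.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    strains = presence.strains
    if len(strains) < 2:
        raise ValidationError("need at least 2 strains to compute distances")
    x = presence.values.to_numpy(dtype=np.float64).T  # strains x families
    inter = x @ x.T
    sizes = x.sum(axis=1)
    if metric == "jaccard":
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    else:
        n_fam = x.shape[1]
        if n_fam == 0:
            raise ValidationError("presence matrix has no families")
        mismatch = sizes[:, None] + sizes[None, :] - 2.0 * inter
        dist = mismatch / n_fam
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    # enforce exact symmetry against floating-point drift in the BLAS product
    dist = (dist + dist.T) / 2.0
    return pd.DataFrame(dist, index=strains, columns=strains)


@dataclass
class Dendrogram:
    """Agglomerative merge history over a fixed leaf set.

    ``merges`` follows the scipy convention: leaves are nodes
    ``0 .. n-1``; the *i*-th merge creates node ``n + i`` from
    ``(left, right, height)``.  Heights are non-decreasing for the
    monotone linkages provided here.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if n == 0:
            raise ValidationError("a dendrogram needs at least one leaf")
        if len(self.merges) != n - 1:
            raise ValidationError(
                f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}"
            )
        heights = [h for _, _, h in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    # -- derived structures -------------------------------------------------

    def node_heights(self) -> list[float]:
        """Height of every node (0 for leaves, merge height for internals)."""
        return [0.0] * len(self.leaves) + [h for _, _, h in self.merges]

    def members(self) -> list[list[int]]:
        """Leaf indices under every node."""
        n = len(self.leaves)
        out: list[list[int]] = [[i] for i in range(n)]
        for left, right, _ in self.merges:
            out.append(out[left] + out[right])
        return out

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Merge height at which each leaf pair first joins."""
        n = len(self.leaves)
        coph = np.zeros((n, n))
        members = [[i] for i in range(n)]
        for left, right, h in self.merges:
            for a in members[left]:
                for b in members[right]:
                    coph[a, b] = coph[b, a] = h
            members.append(members[left] + members[right])
        return pd.DataFrame(coph, index=self.leaves, columns=self.leaves)

    def cut(self, k: int | None = None, height: float | None = None) -> dict[str, int]:
        """Partition leaves into clusters at ``k`` clusters or a height.

        Returns a strain -> cluster-id map; cluster ids are 1-based and
        numbered by each cluster's first leaf in leaf order.
        """
        n = len(self.leaves)
        if (k is None) == (height is None):
            raise ValidationError("specify exactly one of k or height")
        if k is not None:
            if not 1 <= k <= n:
                raise ValidationError(f"k must be in [1, {n}], got {k}")
            n_merges = n - k
        else:
            n_merges = sum(1 for _, _, h in self.merges if h <= height)
        parent = list(range(n + n_merges))
        members = [[i] for i in range(n)]
        roots = set(range(n))
        for i, (left, right, _) in enumerate(self.merges[:n_merges]):
            node = n + i
            parent.append(node)
            members.append(members[left] + members[right])
            roots.discard(left)
            roots.discard(right)
            roots.add(node)
        cluster_of = {}
        # number clusters by first leaf index for reproducibility
        ordered = sorted(roots, key=lambda r: min(members[r]))
        for cid, r in enumerate(ordered, start=1):
            for leaf in members[r]:
                cluster_of[self.leaves[leaf]] = cid
        return cluster_of

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        n = len(self.leaves)
        heights = self.node_heights()
        reprs: list[str] = list(self.leaves)
        for i, (left, right, h) in enumerate(self.merges):
            bl_l = h - heights[left]
            bl_r = h - heights[right]
            reprs.append(f"({reprs[left]}:{bl_l:.12g},{reprs[right]}:{bl_r:.12g})")
        if n == 1:
            return f"{self.leaves[0]};"
        return reprs[-1] + ";"


def _validate_distance(distances: pd.DataFrame) -> np.ndarray:
    d = distances.to_numpy(dtype=np.float64)
    if d.shape[0] != d.shape[1]:
        raise ValidationError("distance table must be square")
    if d.shape[0] < 2:
        raise ValidationError("need at least 2 strains to cluster")
    if list(distances.index) != list(distances.columns):
        raise ValidationError("distance table rows and columns must agree")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValidationError("distance table must be symmetric")
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValidationError("distance table diagonal must be zero")
    if (d < -1e-12).any():
        raise ValidationError("distances must be non-negative")
    return (d + d.T) / 2.0


def hierarchical_cluster(
    distances: pd.DataFrame, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering with Lance-Williams distance updates.

    Supported linkages: ``average`` (UPGMA), ``complete`` and ``ward``.
    When several pairs are at the minimum distance, the merged pair is the
    one whose (smaller, larger) pair of lexicographically-smallest member
    strain ids sorts first; the result is therefore label-deterministic.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    labels = list(distances.index)
    d0 = _validate_distance(distances)
    n = len(labels)

    size = {i: 1 for i in range(n)}
    minlab = {i: labels[i] for i in range(n)}
    active = list(range(n))
    # working matrix indexed by node id; grows as merges create nodes
    big = np.full((2 * n - 1, 2 * n - 1), np.inf)
    big[:n, :n] = d0
    np.fill_diagonal(big, np.inf)

    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        # minimum distance among active pairs
        sub = big[np.ix_(active, active)]
        dmin = sub.min()
        best: tuple[str, str] | None = None
        best_pair: tuple[int, int] | None = None
        ii, jj = np.nonzero(sub == dmin)
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            i, j = active[a], active[b]
            key = tuple(sorted((minlab[i], minlab[j])))
            if best is None or key < best:
                best = key
                best_pair = (i, j)
        assert best_pair is not None
        i, j = best_pair
        # keep the lexicographically smaller side on the left
        if minlab[j] < minlab[i]:
            i, j = j, i
        node = n + step
        ni, nj = size[i], size[j]
        others = [k for k in active if k not in (i, j)]
        dik = big[i, others]
        djk = big[j, others]
        if linkage == "average":
            dnew = (ni * dik + nj * djk) / (ni + nj)
        elif linkage == "complete":
            dnew = np.maximum(dik, djk)
        else:  # ward
            nk = np.array([size[k] for k in others], dtype=np.float64)
            dij = big[i, j]
            dnew = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
        big[node, others] = dnew
        big[others, node] = dnew
        size[node] = ni + nj
        minlab[node] = min(minlab[i], minlab[j])
        active = [k for k in active if k not in (i, j)] + [node]
        merges.append((i, j, float(dmin)))
    return Dendrogram(leaves=labels, merges=merges)


@dataclass(frozen=True)
class ClusterReport:
    """Focal co-clustering summary at one cut of the dendrogram.

    ``focal_purity`` is the fraction of focal strains inside the cluster
    holding most of them; ``focal_single_cluster`` is True when one
    cluster contains the entire focal set.
    """

    k: int
    assignments: dict[str, int]
    focal_purity: float
    focal_single_cluster: bool


def evaluate_focal_cluster(
    dendrogram: Dendrogram,
    focal: Iterable[str],
    k: int | None = None,
    height: float | None = None,
) -> ClusterReport:
    """Cut the dendrogram and ask whether the focal set co-clusters."""
    focal = list(focal)
    missing = set(focal) - set(dendrogram.leaves)
    if missing:
        raise ValidationError(f"focal strains not in dendrogram: {sorted(missing)}")
    if not focal:
        raise ValidationError("focal set must be non-empty")
    assignments = dendrogram.cut(k=k, height=height)
    focal_clusters = [assignments[s] for s in focal]
    counts: dict[int, int] = {}
    for c in focal_clusters:
        counts[c] = counts.get(c, 0) + 1
    purity = max(counts.values()) / len(focal)
    return ClusterReport(
        k=len(set(assignments.values())),
        assignments=assignments,
        focal_purity=purity,
        focal_single_cluster=len(counts) == 1,
    )


def sweep_focal_cluster(
    dendrogram: Dendrogram, focal: Iterable[str], ks: Sequence[int]
) -> pd.DataFrame:
    """Sensitivity table of focal co-clustering across cut sizes ``ks``."""
    focal = list(focal)
    rows = []
    for k in ks:
        rep = evaluate_focal_cluster(dendrogram, focal, k=k)
        rows.append(
            {
                "k": k,
                "focal_single_cluster": rep.focal_single_cluster,
                "focal_purity": rep.focal_purity,
            }
        )
    return pd.DataFrame(rows)
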