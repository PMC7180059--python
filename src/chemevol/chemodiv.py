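"""Chemical-dissimilarity statistics over species profiles.

Species profiles are converted to proportions (compounds of a species sum to
one), compared with Bray-Curtis dissimilarities, clustered with Ward linkage
("ward.D": the update applied to the dissimilarities as given), and the
resulting chemogram clusters receive approximately-unbiased (AU) support from
multiscale bootstrap resampling of the compound columns. Classical PCoA,
Mantel matrix correlation, and tanglegram tip-matching statistics complete
the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, pearsonr
from skbio import DistanceMatrix


# --------------------------------------------------------------------------
# dissimilarity
# --------------------------------------------------------------------------


def to_proportions(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize non-negative profiles so each species sums to one."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("profile matrix must be non-negative")
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = list(matrix.index[sums <= 0])
        raise ValueError(f"all-zero rows have no proportions: {bad}")
    return matrix.div(matrix.sum(axis=1), axis=0)


def _bray_curtis_condensed(values: np.ndarray) -> np.ndarray:
    """Bray-Curtis on rows, tolerating all-zero rows (d(0,0) = 0)."""
    n = values.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        diff = np.abs(values[i + 1 :] - values[i]).sum(axis=1)
        tot = (values[i + 1 :] + values[i]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        out[k : k + n - 1 - i] = d
        k += n - 1 - i
    return out


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities of row-proportion profiles.

    The proportion conversion is part of this operation; rows must be
    non-negative with positive sums. Returns a labelled
    :class:`skbio.DistanceMatrix` with entries in [0, 1].
    """
    props = to_proportions(matrix)
    condensed = pdist(props.to_numpy(), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in matrix.index])


# --------------------------------------------------------------------------
# Ward clustering
# --------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """A merge tree over labelled objects (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list

    def cluster_sets(self) -> list:
        """Tip-label sets of the internal nodes, smallest first."""
        n = len(self.labels)
        members = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for k, (a, b, _h, _c) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            out.append(merged)
        return out

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cophenetic(self) -> DistanceMatrix:
        from scipy.cluster.hierarchy import cophenet

        return DistanceMatrix(
            squareform(cophenet(self.linkage)), ids=[str(l) for l in self.labels]
        )

    def leaf_order(self) -> list:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self, node_comments: Optional[dict] = None) -> str:
        """Newick string with merge heights as node depths.

        ``node_comments`` maps a cluster's frozenset of tip labels to a
        comment string stored at that internal node (e.g. AU/BP support).
        """
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: (self.labels[i], frozenset([self.labels[i]])) for i in range(n)}

        def render(idx, parent_height):
            label, members = nodes[idx]
            length = parent_height - heights[idx]
            if idx < n:
                return f"{label}:{length:.12g}"
            comment = ""
            if node_comments and members in node_comments:
                comment = f"[&{node_comments[members]}]"
            return f"{label}{comment}:{length:.12g}"

        children = {}
        for k, (a, b, h, _c) in enumerate(self.linkage):
            idx = n + k
            heights[idx] = float(h)
            members = nodes[int(a)][1] | nodes[int(b)][1]
            children[idx] = (int(a), int(b))
            nodes[idx] = ("", members)

        def build(idx, parent_height):
            if idx < n:
                return render(idx, parent_height)
            a, b = children[idx]
            inner = ",".join(build(c, heights[idx]) for c in (a, b))
            label, members = nodes[idx]
            comment = ""
            if node_comments and members in node_comments:
                comment = f"[&{node_comments[members]}]"
            length = parent_height - heights[idx]
            return f"({inner}){comment}:{length:.12g}"

        root = n + len(self.linkage) - 1
        return build(root, heights[root]) + ";"


def ward_dendrogram(dist: DistanceMatrix, variant: str = "ward.D") -> Dendrogram:
    """Agglomerative Ward clustering of a dissimilarity matrix.

    ``variant="ward.D"`` applies the Ward update to the dissimilarities as
    provided (heights on the input scale); ``"ward.D2"`` applies it to their
    squares and reports square-rooted heights. Ward.D is computed exactly by
    running the squared-update algorithm on sqrt-transformed input and
    squaring the resulting heights. Merge ties break deterministically
    (lowest cluster index pair, the linkage convention).
    """
    if len(dist.ids) < 2:
        raise ValueError("need at least two objects to cluster")
    condensed = dist.condensed_form()
    if variant == "ward.D":
        Z = hierarchy.linkage(np.sqrt(condensed), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    elif variant == "ward.D2":
        Z = hierarchy.linkage(condensed, method="ward")
    else:
        raise ValueError(f"unknown Ward variant {variant!r}")
    return Dendrogram(linkage=Z, labels=list(dist.ids))


# --------------------------------------------------------------------------
# multiscale bootstrap (AU) support
# --------------------------------------------------------------------------


@dataclass
class SupportedDendrogram:
    """A chemogram with per-cluster AU and BP support."""

    dendrogram: Dendrogram
    clusters: list  # frozensets, in linkage order
    au: np.ndarray
    bp: np.ndarray  # bootstrap probability at the scale closest to 1
    bp_table: pd.DataFrame  # clusters x scales
    flagged: np.ndarray  # True where AU was clamped or under-determined

    def to_newick(self) -> str:
        """Chemogram as Newick with AU/BP stored as node comments."""
        comments = {
            c: f"au={self.au[i]:.3f},bp={self.bp[i]:.3f}"
            for i, c in enumerate(self.clusters)
        }
        return self.dendrogram.to_newick(node_comments=comments)


def _fit_au(bp_by_scale: np.ndarray, scales: np.ndarray, n_boot: int):
    """AU from multiscale BP values.

    Fits z(r) = d*sqrt(r) + c/sqrt(r) to z = qnorm(1 - BP_r) by weighted
    least squares (delta-method binomial weights) and returns
    AU = 1 - Phi(d - c). Degenerate BP (0 or 1 at every scale) clamps AU to
    that bound and flags the cluster.
    """
    usable = (bp_by_scale > 0) & (bp_by_scale < 1)
    if usable.sum() < 2:
        if np.all(bp_by_scale >= 1):
            return 1.0, True
        if np.all(bp_by_scale <= 0):
            return 0.0, True
        # a single informative scale: fall back to its BP
        idx = int(np.argmin(np.abs(scales - 1.0)))
        return float(bp_by_scale[idx]), True
    r = scales[usable]
    bp = bp_by_scale[usable]
    z = norm.ppf(1.0 - bp)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    w = n_boot * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    WX = X * w[:, None]
    coef = np.linalg.solve(X.T @ WX, WX.T @ z)
    d, c = coef
    return float(1.0 - norm.cdf(d - c)), False


DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))


def multiscale_bootstrap_support(
    matrix: pd.DataFrame,
    scales: Sequence[float] = DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    variant: str = "ward.D",
) -> SupportedDendrogram:
    """AU/BP cluster support by multiscale bootstrap of compound columns.

    The full-data chemogram (proportions -> Bray-Curtis -> Ward) is fixed;
    at each resample-size ratio ``r`` the compound columns are resampled with
    replacement ``n_boot`` times, the chemogram recomputed, and BP_r recorded
    as the appearance frequency of each original cluster. AU follows from
    the weighted z(r) fit (see :func:`_fit_au`).
    """
    scales = np.asarray(list(scales), dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive resample-size ratios")
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap iterations per scale")
    rng = np.random.default_rng(seed)

    dist = bray_curtis(matrix)
    dendro = ward_dendrogram(dist, variant=variant)
    clusters = dendro.cluster_sets()
    informative = [c for c in clusters if len(c) < len(dendro.labels)]
    values = matrix.to_numpy(dtype=float)
    labels = list(matrix.index.astype(str))
    n_compounds = values.shape[1]

    bp_table = np.zeros((len(clusters), len(scales)))
    for si, r in enumerate(scales):
        m = max(2, int(round(n_compounds * r)))
        counts = {c: 0 for c in informative}
        for _ in range(n_boot):
            cols = rng.integers(0, n_compounds, size=m)
            sub = values[:, cols]
            sums = sub.sum(axis=1, keepdims=True)
            props = np.divide(sub, np.where(sums > 0, sums, 1.0))
            condensed = _bray_curtis_condensed(props)
            if variant == "ward.D":
                Z = hierarchy.linkage(np.sqrt(condensed), method="ward")
            else:
                Z = hierarchy.linkage(condensed, method="ward")
            boot_sets = set(Dendrogram(Z, labels).cluster_sets())
            for c in informative:
                if c in boot_sets:
                    counts[c] += 1
        for ci, c in enumerate(clusters):
            bp_table[ci, si] = (
                counts[c] / n_boot if c in counts else 1.0
            )  # the root cluster always appears

    au = np.zeros(len(clusters))
    flagged = np.zeros(len(clusters), dtype=bool)
    for ci in range(len(clusters)):
        au[ci], flagged[ci] = _fit_au(bp_table[ci], scales, n_boot)
    near_one = int(np.argmin(np.abs(scales - 1.0)))
    return SupportedDendrogram(
        dendrogram=dendro,
        clusters=clusters,
        au=au,
        bp=bp_table[:, near_one].copy(),
        bp_table=pd.DataFrame(
            bp_table,
            index=[";".join(sorted(c)) for c in clusters],
            columns=[f"r={r:g}" for r in scales],
        ),
        flagged=flagged,
    )


# --------------------------------------------------------------------------
# ordination
# --------------------------------------------------------------------------


@dataclass
class PCoAResult:
    """Classical-scaling embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame  # objects x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per positive axis, relative to positive sum


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Principal coordinate analysis (classical metric scaling).

    Double-centers -D^2/2, eigendecomposes, and returns coordinates
    eigvec * sqrt(eigval) for positive eigenvalues. Percent variance is
    relative to the sum of positive eigenvalues; negative eigenvalues are
    reported, not corrected. Axis signs are fixed by making each axis's
    largest-magnitude coordinate positive.
    """
    D = dist.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(np.abs(eigval).max(), 1.0) * 1e-10
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    for j in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    percent = 100.0 * eigval[pos] / eigval[pos].sum()
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords,
            index=list(dist.ids),
            columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=eigval,
        percent_variance=percent,
    )


# --------------------------------------------------------------------------
# Mantel test
# --------------------------------------------------------------------------


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: Optional[int] = None,
):
    """Mantel matrix correlation with a simultaneous row/column permutation.

    r is the Pearson correlation of the upper triangles; the two-sided
    p-value uses the add-one rule
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share labels")
    d2 = d2.filter(d1.ids)
    a = d1.data[np.triu_indices(len(d1.ids), k=1)]
    B = d2.data
    iu = np.triu_indices(len(d1.ids), k=1)
    b = B[iu]
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("constant off-diagonal entries: correlation undefined")
    r_obs = pearsonr(a, b)[0]
    rng = np.random.default_rng(seed)
    n = len(d1.ids)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B[np.ix_(perm, perm)][iu]
        if abs(pearsonr(a, bp)[0]) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r_obs), float(p)


# --------------------------------------------------------------------------
# tanglegram
# --------------------------------------------------------------------------


class _Node:
    __slots__ = ("children", "label")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []

    def leaves(self):
        if not self.children:
            return [self.label]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


def _from_linkage(dendro: Dendrogram) -> _Node:
    n = len(dendro.labels)
    nodes = {i: _Node(label=dendro.labels[i]) for i in range(n)}
    for k, (a, b, _h, _c) in enumerate(dendro.linkage):
        nodes[n + k] = _Node(children=[nodes[int(a)], nodes[int(b)]])
    return nodes[n + len(dendro.linkage) - 1]


def _from_dendropy(tree) -> _Node:
    def build(nd):
        if nd.is_leaf():
            return _Node(label=nd.taxon.label)
        return _Node(children=[build(ch) for ch in nd.child_nodes()])

    return build(tree.seed_node)


def _link_length(order_a, order_b):
    pos_b = {lab: i for i, lab in enumerate(order_b)}
    return sum(abs(i - pos_b[lab]) for i, lab in enumerate(order_a))


def _optimize_rotations(root_a, root_b, max_passes=50):
    def internal_nodes(root):
        stack, out = [root], []
        while stack:
            nd = stack.pop()
            if nd.children:
                out.append(nd)
                stack.extend(nd.children)
        return out

    best = _link_length(root_a.leaves(), root_b.leaves())
    for _ in range(max_passes):
        improved = False
        for root, other in ((root_a, root_b), (root_b, root_a)):
            for nd in internal_nodes(root):
                nd.children.reverse()
                cand = _link_length(root_a.leaves(), root_b.leaves())
                if cand < best:
                    best = cand
                    improved = True
                else:
                    nd.children.reverse()
        if not improved:
            break
    return best


@dataclass
class TanglegramResult:
    order_left: list
    order_right: list
    link_length: float
    p_value: Optional[float] = None


def tanglegram(
    tree,
    dendrogram,
    n_perm: int = 0,
    seed: Optional[int] = None,
) -> TanglegramResult:
    """Optimize vertical tip matching between a phylogeny and a chemogram.

    Both trees' node rotations are searched greedily to minimize the total
    vertical displacement between matched tips on unit-spaced ladders. With
    ``n_perm > 0`` a permutation null (tip labels of the chemogram shuffled,
    each shuffle re-optimized) yields an add-one p-value for the observed
    total link length.
    """
    import dendropy

    root_a = _from_dendropy(tree) if isinstance(tree, dendropy.Tree) else _from_linkage(tree)
    root_b = (
        _from_dendropy(dendrogram)
        if isinstance(dendrogram, dendropy.Tree)
        else _from_linkage(dendrogram)
    )
    tips_a, tips_b = set(root_a.leaves()), set(root_b.leaves())
    if tips_a != tips_b:
        raise ValueError("tip sets differ between the two trees")

    length = _optimize_rotations(root_a, root_b)
    result = TanglegramResult(
        order_left=root_a.leaves(), order_right=root_b.leaves(), link_length=float(length)
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        labels = root_b.leaves()
        count = 0
        for _ in range(n_perm):
            shuffled = list(rng.permutation(labels))
            mapping = dict(zip(labels, shuffled))
            _relabel(root_b, mapping)
            null_len = _optimize_rotations(root_a, root_b)
            _relabel(root_b, {v: k for k, v in mapping.items()})
            if null_len <= length:
                count += 1
        result.p_value = (1 + count) / (1 + n_perm)
    return result


def _relabel(root: _Node, mapping: dict):
    stack = [root]
    while stack:
        nd = stack.pop()
        if nd.children:
            stack.extend(nd.children)
        else:
            nd.label = mapping[nd.label]
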