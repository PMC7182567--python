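"""Correlation-distance hierarchical clustering and Ph-like labeling.

Samples are clustered on the housekeeping-normalized expression matrix with
one-minus-Pearson-correlation distance and average linkage (UPGMA), the
tree is cut into ``k`` flat clusters, and the cluster overexpressing the
up-markers (ECM1, ENAM, IGJ, CRLF2) while underexpressing MDFIC is labeled
BCR-ABL1-like (Ph-like).

Before computing correlations the matrix is, by default, log2-transformed
with a small pseudocount: Pearson on untransformed housekeeping ratios is
dominated by the most highly expressed genes.  Optional per-gene
median-centering (or no conditioning at all) can be selected instead.

UPGMA is implemented here rather than delegated so that the merge-order and
tie-break contract (lexicographically smallest pair of cluster ids, a
cluster's id being its smallest leaf index) is explicit and reproducible;
average inter-cluster distances are computed from the original pairwise
distances, which is algebraically identical to the Lance–Williams update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ExpressionMatrix, PanelDefinition, PanelError
from .stats import TestResult, mood_median_test

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "SignatureCall",
    "MarkerTestResult",
    "log_transform",
    "pearson_distance_matrix",
    "upgma",
    "cut_tree",
    "marker_tests",
    "label_phlike",
    "export_dendrogram",
    "classify_samples",
    "PH_LIKE",
    "NON_PH_LIKE",
]

PH_LIKE = "PH_LIKE"
NON_PH_LIKE = "NON_PH_LIKE"

#: pseudocount added before log2; chosen small relative to the ~1.0 scale of
#: housekeeping-normalized ratios
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_K = 2


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise-distance matrix over named entities."""

    values: np.ndarray
    ids: tuple[str, ...]
    metric: str = "one_minus_pearson"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero self-distance")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: two clusters joined at a height."""

    left: frozenset[int]
    right: frozenset[int]
    height: float

    @property
    def members(self) -> frozenset[int]:
        return self.left | self.right


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree recorded as an ordered list of merges.

    Leaf ``i`` corresponds to ``leaf_ids[i]``.  Merge heights are
    non-decreasing in merge order for average linkage.
    """

    leaf_ids: tuple[str, ...]
    merges: tuple[Merge, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> list[float]:
        return [m.height for m in self.merges]


@dataclass(frozen=True)
class SignatureCall:
    sample_id: str
    cluster: int
    label: str
    marker_score: float


@dataclass(frozen=True)
class MarkerTestResult:
    gene: str
    direction: str  # "up" or "down": expected direction in the Ph-like group
    p_value: float
    median_phlike: float
    median_rest: float
    method: str


# ---------------------------------------------------------------------------
# matrix conditioning and distances


def log_transform(
    m: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ExpressionMatrix:
    """Elementwise ``log2(x + pseudocount)``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return ExpressionMatrix(values=np.log2(m.values + pseudocount), stage="log")


def _median_center_rows(df: pd.DataFrame) -> pd.DataFrame:
    return df.sub(df.median(axis=1), axis=0)


def pearson_distance_matrix(m: ExpressionMatrix, axis: str = "samples") -> DistanceMatrix:
    """One-minus-Pearson-correlation distance between samples or genes."""
    if axis == "samples":
        data = m.values.to_numpy().T  # entities in rows
        ids = tuple(m.sample_ids)
    elif axis == "genes":
        data = m.values.to_numpy()
        ids = tuple(m.gene_ids)
    else:
        raise ValueError(f"axis must be 'samples' or 'genes', got {axis!r}")
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need >= 2 entities and >= 2 features")
    sd = data.std(axis=1)
    dead = [ids[i] for i in np.nonzero(sd == 0)[0]]
    if dead:
        raise ValueError(f"zero-variance entit(y/ies): {dead}")
    r = np.corrcoef(data)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, ids=ids)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with a deterministic tie-break.

    At each step the pair of clusters with minimal mean pairwise original
    distance is merged at that mean; among exactly tied pairs the pair with
    the lexicographically smallest (min-leaf-index) cluster ids wins.
    """
    n = d.n
    if n < 2:
        raise ValueError("need at least 2 entities to cluster")
    # cluster-average distances maintained by the Lance–Williams update,
    # which for average linkage equals the mean of the original pairwise
    # distances between the two clusters' members
    work = d.values.astype(float).copy()
    # active clusters keyed by their smallest leaf index
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges: list[Merge] = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best: tuple[float, int, int] | None = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                avg = work[a, b]
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        avg, a, b = best  # type: ignore[misc]
        merges.append(Merge(left=clusters[a], right=clusters[b], height=float(avg)))
        na, nb = len(clusters[a]), len(clusters[b])
        keep, drop = min(a, b), max(a, b)
        others = [k for k in keys if k not in (a, b)]
        if others:
            idx = np.array(others)
            merged = (na * work[a, idx] + nb * work[b, idx]) / (na + nb)
            work[keep, idx] = merged
            work[idx, keep] = merged
        clusters[keep] = clusters[a] | clusters[b]
        del clusters[drop]
    return Dendrogram(leaf_ids=d.ids, merges=tuple(merges))


def cut_tree(t: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into ``k`` flat clusters.

    The ``k - 1`` highest merges are removed; because average-linkage merge
    heights are non-decreasing in merge order, this keeps the first
    ``n - k`` merges (ties at the boundary resolved by merge order, later
    merges cut first).  Cluster ids are assigned 0, 1, ... in order of
    first leaf appearance.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in t.merges[: n - k]:
        ra = find(min(m.left))
        rb = find(min(m.right))
        parent[max(ra, rb)] = min(ra, rb)
    assignment: dict[str, int] = {}
    root_to_cluster: dict[int, int] = {}
    for i, leaf in enumerate(t.leaf_ids):
        r = find(i)
        if r not in root_to_cluster:
            root_to_cluster[r] = len(root_to_cluster)
        assignment[leaf] = root_to_cluster[r]
    return assignment


# ---------------------------------------------------------------------------
# marker-based labeling


def _marker_scores(
    m: ExpressionMatrix,
    assignment: dict[str, int],
    panel: PanelDefinition,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[int, float]:
    markers_up = [g for g in m.gene_ids if g in panel.markers_up]
    markers_down = [g for g in m.gene_ids if g in panel.markers_down]
    if not markers_up and not markers_down:
        raise PanelError("cannot label without markers: all marker genes absent")
    logm = m.values if m.stage == "log" else np.log2(m.values + pseudocount)
    sub = logm.loc[markers_up + markers_down, list(assignment)]
    sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    scores: dict[int, float] = {}
    for cl in sorted(set(assignment.values())):
        cols = [s for s, c in assignment.items() if c == cl]
        zc = z[cols].mean(axis=1)
        up = float(zc.loc[markers_up].mean()) if markers_up else 0.0
        down = float(zc.loc[markers_down].mean()) if markers_down else 0.0
        scores[cl] = up - down
    return scores


def label_phlike(
    m: ExpressionMatrix,
    assignment: dict[str, int],
    panel: PanelDefinition,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[SignatureCall]:
    """Label the cluster with the highest marker score as Ph-like.

    The marker score of a cluster is the mean (over up-markers) of the
    per-gene z-standardized log-scale cluster mean minus the same quantity
    over down-markers.  Exactly one cluster is labeled ``PH_LIKE``; score
    ties break toward the lowest cluster id with a warning.
    """
    if len(set(assignment.values())) < 2:
        raise ValueError("need k >= 2 clusters to label")
    scores = _marker_scores(m, assignment, panel, pseudocount)
    best = max(scores, key=lambda c: (scores[c], -c))
    ties = [c for c in scores if scores[c] == scores[best] and c != best]
    if ties:
        warnings.warn(f"marker-score tie between clusters {[best] + ties}; picking {best}")
    return [
        SignatureCall(
            sample_id=s,
            cluster=c,
            label=PH_LIKE if c == best else NON_PH_LIKE,
            marker_score=scores[c],
        )
        for s, c in assignment.items()
    ]


def marker_tests(
    m: ExpressionMatrix,
    assignment: dict[str, int],
    panel: PanelDefinition,
    phlike_cluster: int,
) -> list[MarkerTestResult]:
    """Mood's median test per marker gene, Ph-like cluster versus the rest."""
    in_cluster = [s for s, c in assignment.items() if c == phlike_cluster]
    rest = [s for s, c in assignment.items() if c != phlike_cluster]
    if not in_cluster or not rest:
        raise ValueError("both the candidate cluster and the rest must be nonempty")
    results: list[MarkerTestResult] = []
    for gene, direction in [(g, "up") for g in sorted(panel.markers_up)] + [
        (g, "down") for g in sorted(panel.markers_down)
    ]:
        if gene not in m.gene_ids:
            raise PanelError(f"marker gene {gene!r} absent from matrix")
        row = m.values.loc[gene]
        a = row[in_cluster].to_numpy(float)
        b = row[rest].to_numpy(float)
        res: TestResult = mood_median_test([a, b])
        results.append(
            MarkerTestResult(
                gene=gene,
                direction=direction,
                p_value=res.p_value,
                median_phlike=float(np.median(a)),
                median_rest=float(np.median(b)),
                method=res.method,
            )
        )
    return results


# ---------------------------------------------------------------------------
# export and the end-to-end classification step


def _newick(node: frozenset[int] | int, height: float, t: Dendrogram, by_members: dict) -> str:
    # each cluster sits at depth height/2 from its own leaves (ultrametric layout)
    if isinstance(node, int):
        return f"{t.leaf_ids[node]}:{height / 2:g}"
    sub = by_members[node]
    left = sub.left if len(sub.left) > 1 else next(iter(sub.left))
    right = sub.right if len(sub.right) > 1 else next(iter(sub.right))
    ls = _newick(left, sub.height, t, by_members)
    rs = _newick(right, sub.height, t, by_members)
    blen = (height - sub.height) / 2
    return f"({ls},{rs}):{blen:g}"


def leaf_order(t: Dendrogram) -> list[str]:
    """Leaf ids in dendrogram display order (left-to-right traversal)."""
    if not t.merges:
        return list(t.leaf_ids)
    by_members = {m.members: m for m in t.merges}

    def walk(node: frozenset[int]) -> list[int]:
        if len(node) == 1:
            return [next(iter(node))]
        m = by_members[node]
        return walk(m.left) + walk(m.right)

    return [t.leaf_ids[i] for i in walk(t.merges[-1].members)]


def export_dendrogram(t: Dendrogram, path: str | Path | None = None) -> str:
    """Serialize the dendrogram as a Newick string with ultrametric branch
    lengths (a leaf's depth below a merge at height h is h/2)."""
    by_members = {m.members: m for m in t.merges}
    if t.merges:
        root = t.merges[-1]
        left = root.left if len(root.left) > 1 else next(iter(root.left))
        right = root.right if len(root.right) > 1 else next(iter(root.right))
        ls = _newick(left, root.height, t, by_members)
        rs = _newick(right, root.height, t, by_members)
        s = f"({ls},{rs});"
    else:
        s = f"({t.leaf_ids[0]}:0);"
    if path is not None:
        Path(path).write_text(s + "\n", encoding="utf-8")
    return s


def classify_samples(
    normalized: ExpressionMatrix,
    panel: PanelDefinition,
    k: int = DEFAULT_K,
    transform: str = "log",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[list[SignatureCall], Dendrogram]:
    """Cluster the normalized matrix and label the Ph-like cluster.

    ``transform`` conditions the matrix before the correlation distance:
    ``"log_median_center"`` (default), ``"log"``, or ``"none"``.
    """
    if transform not in ("log_median_center", "log", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    work = normalized
    if transform != "none":
        work = log_transform(normalized, pseudocount)
        if transform == "log_median_center":
            work = ExpressionMatrix(values=_median_center_rows(work.values), stage="log")
    # genes constant across samples carry no correlation signal; drop them
    keep = work.values.std(axis=1) > 0
    work = ExpressionMatrix(values=work.values.loc[keep], stage=work.stage)
    d = pearson_distance_matrix(work, axis="samples")
    tree = upgma(d)
    assignment = cut_tree(tree, k)
    calls = label_phlike(normalized, assignment, panel, pseudocount)
    return calls, tree
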