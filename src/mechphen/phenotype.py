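"""Morpho-mechanical phenotype matrices and similarity clustering.

The phenotype of a culture condition is summarized as a vector of
Z-scores, one per morpho-mechanical property:

    z = (x_bar - x_bar_c) / sigma_c

where x_bar is the condition's mean of the property, and x_bar_c and
sigma_c are the mean and standard deviation of the control condition
(E_P-C_P-VimWT).  Stacking conditions gives the m x n matrix Z.  Cosine
similarity between its rows yields the condition-similarity matrix C,
between its columns the property-similarity matrix P.  Average-linkage
agglomerative clustering on cosine distance (1 - similarity), with the
number of clusters selected by mean silhouette, identifies blocks of
conditions/properties that respond alike; the cluster orderings are
used to reorganize Z into block form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.metrics import silhouette_score

from .core import Condition

__all__ = [
    "ZMatrix",
    "SimilarityMatrix",
    "ClusterResult",
    "compute_zmatrix",
    "cosine_similarity_matrix",
    "cluster_similarity",
    "reorder_zmatrix",
]


@dataclass
class ZMatrix:
    """Conditions x properties matrix of Z-scores vs the control condition."""

    values: pd.DataFrame  # index: condition_id, columns: property
    control_id: str
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("Z matrix entries must be finite")
        if self.control_id not in self.values.index:
            raise ValueError("control condition missing from Z matrix")

    @property
    def conditions(self) -> list[str]:
        return list(self.values.index)

    @property
    def properties(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SimilarityMatrix:
    """Square cosine-similarity matrix over conditions (C) or properties (P)."""

    values: pd.DataFrame
    axis: str  # "conditions" or "properties"

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(v > 1 + 1e-12) or np.any(v < -1 - 1e-12):
            raise ValueError("cosine similarities must lie in [-1, 1]")

    @property
    def items(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ClusterResult:
    """Unsupervised clustering of a similarity matrix.

    ``ordering`` permutes the input items so clusters form contiguous
    blocks (dendrogram leaf order); ``labels`` are per input item,
    renumbered from 0 in order of first appearance along the ordering.
    """

    items: list[str]
    ordering: np.ndarray
    labels: np.ndarray
    k: int
    linkage_matrix: np.ndarray

    @property
    def ordered_items(self) -> list[str]:
        return [self.items[i] for i in self.ordering]

    def labels_of(self, names: list[str]) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.items)}
        return np.array([self.labels[idx[n]] for n in names])


def compute_zmatrix(
    table: pd.DataFrame, control: Condition | str
) -> ZMatrix:
    """Z-score matrix of a replicate-level property table.

    ``table`` needs columns condition_id, property, value (and
    optionally category).  Every condition must report every property;
    the control condition needs >= 2 replicates and strictly positive
    SD per property (ddof=1).
    """
    control_id = control.condition_id if isinstance(control, Condition) else control
    required = {"condition_id", "property", "value"}
    if missing := required - set(table.columns):
        raise ValueError(f"property table lacks columns: {sorted(missing)}")
    if control_id not in set(table["condition_id"]):
        raise ValueError(f"control condition {control_id!r} not in table")

    means = table.pivot_table(
        index="condition_id", columns="property", values="value", aggfunc="mean"
    )
    if means.isna().any().any():
        holes = means.isna()
        bad = [
            f"{means.index[i]}/{means.columns[j]}"
            for i, j in zip(*np.nonzero(holes.to_numpy()))
        ]
        raise ValueError(f"missing (condition, property) cells: {bad[:5]}")

    ctrl = table[table["condition_id"] == control_id]
    counts = ctrl.groupby("property")["value"].count()
    if (counts < 2).any():
        raise ValueError(
            "control condition needs >= 2 replicates per property to define "
            "sigma_c"
        )
    sigma_c = ctrl.groupby("property")["value"].std(ddof=1)
    zero_sd = sigma_c[sigma_c <= 0]
    if len(zero_sd):
        raise ValueError(
            f"control SD is zero for properties: {list(zero_sd.index)}"
        )
    z = (means - means.loc[control_id]) / sigma_c
    z = z[sorted(z.columns)]

    categories = {}
    if "category" in table.columns:
        categories = (
            table.drop_duplicates("property")
            .set_index("property")["category"]
            .to_dict()
        )
    return ZMatrix(values=z, control_id=control_id, categories=categories)


def cosine_similarity_matrix(
    z: ZMatrix,
    axis: str = "conditions",
    exclude_control: bool = True,
) -> SimilarityMatrix:
    """Cosine similarity between condition rows (C) or property columns (P).

    The control row of Z is identically zero, so its cosine is
    undefined; for ``axis="conditions"`` it is excluded by default.
    Any remaining zero-norm vector raises an error naming the item.
    """
    if axis not in ("conditions", "properties"):
        raise ValueError("axis must be 'conditions' or 'properties'")
    df = z.values
    if axis == "conditions":
        if exclude_control:
            df = df.drop(index=z.control_id)
        mat = df.to_numpy()
        names = list(df.index)
    else:
        mat = df.to_numpy().T
        names = list(df.columns)

    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        bad = [names[i] for i in np.nonzero(norms == 0)[0]]
        raise ValueError(f"zero-norm vector(s) along {axis}: {bad}")
    unit = mat / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    return SimilarityMatrix(
        values=pd.DataFrame(sim, index=names, columns=names), axis=axis
    )


def cluster_similarity(
    s: SimilarityMatrix, k: int | str = "auto"
) -> ClusterResult:
    """Average-linkage agglomerative clustering on cosine distance.

    Distance is d = 1 - S.  For ``k="auto"`` the number of clusters
    maximizing the mean silhouette over k in {2, ..., m-1} is chosen,
    smallest k winning ties (including the degenerate flat-silhouette
    case, which deterministically yields k=2).  The returned ordering
    is the dendrogram leaf order, under which clusters are contiguous
    blocks.
    """
    d = 1.0 - s.values.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    m = d.shape[0]
    if m < 2:
        raise ValueError("clustering needs at least 2 items")
    condensed = d[np.triu_indices(m, k=1)]
    lk = linkage(condensed, method="average")

    if k == "auto":
        if m < 3:
            raise ValueError(
                "silhouette-based selection needs >= 3 items; pass k explicitly"
            )
        best_k, best_score = None, -np.inf
        for kk in range(2, m):
            lab = fcluster(lk, t=kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(d, lab, metric="precomputed")
            if score > best_score + 1e-12:  # strict: smallest k wins ties
                best_k, best_score = kk, score
        if best_k is None:
            best_k = 2
        k = best_k
    elif not (isinstance(k, (int, np.integer)) and 1 <= k <= m):
        raise ValueError("k must be 'auto' or an integer in [1, m]")

    labels_raw = fcluster(lk, t=k, criterion="maxclust") if k > 1 else np.ones(m, int)
    if k == 2 and len(np.unique(labels_raw)) == 1:
        # tied merge heights (e.g. all similarities equal): maxclust cannot
        # realize k=2, so split deterministically at the dendrogram root
        labels_raw = _root_split(lk, m)
    order = leaves_list(lk)
    # renumber labels by first appearance in leaf order
    remap: dict[int, int] = {}
    for i in order:
        remap.setdefault(int(labels_raw[i]), len(remap))
    labels = np.array([remap[int(l)] for l in labels_raw])
    # stable-sort the leaf order by label so clusters are blocks even if
    # fcluster cut and dendrogram order disagree on rare ties
    order = np.array(sorted(order, key=lambda i: (labels[i],)), dtype=int)
    return ClusterResult(
        items=list(s.values.index),
        ordering=order,
        labels=labels,
        k=int(len(np.unique(labels))),
        linkage_matrix=lk,
    )


def _root_split(lk: np.ndarray, m: int) -> np.ndarray:
    """Two-cluster labeling from the children of the last linkage merge."""
    members: dict[int, list[int]] = {i: [i] for i in range(m)}
    for row, (a, b, _, _) in enumerate(lk):
        members[m + row] = members[int(a)] + members[int(b)]
    left = members[int(lk[-1, 0])]
    labels = np.full(m, 2, dtype=int)
    labels[left] = 1
    return labels


def reorder_zmatrix(
    z: ZMatrix,
    condition_order: list[str] | ClusterResult | None = None,
    property_order: list[str] | ClusterResult | None = None,
) -> ZMatrix:
    """Permute Z's rows and columns per cluster orderings (values unchanged).

    Orderings may be ClusterResults or explicit name lists.  A
    condition ordering that omits the control row (the default C
    excludes it) is completed by placing the control first.
    """
    rows = _as_order(condition_order, z.conditions, allow_missing=[z.control_id])
    cols = _as_order(property_order, z.properties, allow_missing=[])
    return ZMatrix(
        values=z.values.loc[rows, cols],
        control_id=z.control_id,
        categories=z.categories,
    )


def _as_order(order, full: list[str], allow_missing: list[str]) -> list[str]:
    if order is None:
        return full
    names = order.ordered_items if isinstance(order, ClusterResult) else list(order)
    missing = [n for n in full if n not in names]
    if set(missing) - set(allow_missing) or set(names) - set(full):
        raise ValueError(
            "ordering is not a permutation of the matrix axis "
            f"(missing {missing}, extraneous {sorted(set(names) - set(full))})"
        )
    return missing + names
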