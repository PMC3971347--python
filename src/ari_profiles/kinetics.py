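"""Expression kinetics: trajectory scaling, fold changes, UPGMA clustering.

Kinetics plots in this analysis show, per gene, the mean log2 intensity in
each (group, timepoint) cell rescaled so that the maximum across all cells
of that gene is 1 and the minimum 0. Hierarchical clustering of log2
fold-change profiles uses Euclidean distance with unweighted average
linkage (UPGMA) and fully deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .errors import ValidationError


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def compute_trajectories(
    expr: pd.DataFrame, annotation: pd.DataFrame,
    groups=None, timepoints=None,
) -> pd.DataFrame:
    """Per-gene mean log2 intensity per (group, timepoint) cell.

    Columns are a (group, timepoint) MultiIndex in the given order.
    """
    groups = list(groups) if groups is not None else list(
        pd.unique(annotation["group"]))
    timepoints = list(timepoints) if timepoints is not None else list(
        pd.unique(annotation["timepoint"]))
    cols = {}
    for g in groups:
        for t in timepoints:
            samples = annotation.index[(annotation["group"] == g)
                                       & (annotation["timepoint"] == t)]
            if len(samples) == 0:
                raise ValidationError(f"cell ({g}, {t}) has no samples")
            cols[(g, t)] = expr[samples].mean(axis=1)
    traj = pd.DataFrame(cols)
    traj.columns = pd.MultiIndex.from_tuples(traj.columns,
                                             names=["group", "timepoint"])
    return traj


def minmax_scale_trajectories(
    traj: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each gene's trajectory row to [0, 1] across all cells jointly.

    Non-constant genes attain exactly 0 and exactly 1. Constant genes map
    to 0.5 everywhere and are flagged in the returned boolean Series.
    """
    if traj.shape[1] == 0 or traj.shape[0] == 0:
        raise ValidationError("empty trajectory matrix")
    if traj.shape[1] < 2:
        raise ValidationError("each gene needs >=2 cells to scale")
    vals = traj.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    constant = (span == 0).ravel()
    span_safe = np.where(span == 0, 1.0, span)
    scaled = (vals - lo) / span_safe
    scaled[constant] = 0.5
    out = pd.DataFrame(scaled, index=traj.index, columns=traj.columns)
    return out, pd.Series(constant, index=traj.index, name="constant")


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def compute_fold_change(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    group: str,
    transition: tuple,
) -> pd.Series:
    """Per-gene log2 fold change, later time point minus earlier, in a group.

    Uses subject-matched means when every subject present at either time
    point has both visits; falls back to cell means otherwise.
    """
    earlier, later = transition
    sub = annotation[annotation["group"] == group] if group != "all" else annotation
    a = sub[sub["timepoint"] == earlier]
    b = sub[sub["timepoint"] == later]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError(
            f"transition {transition} in group {group!r} has an empty time point")
    subj_a, subj_b = set(a["subject_id"]), set(b["subject_id"])
    if subj_a == subj_b and len(a) == len(b):
        # complete pairing: difference of per-subject values, averaged
        a_idx = a.sort_values("subject_id").index
        b_idx = b.sort_values("subject_id").index
        diff = expr[b_idx].to_numpy() - expr[a_idx].to_numpy()
        fc = diff.mean(axis=1)
    else:
        fc = expr[b.index].mean(axis=1).to_numpy() - expr[a.index].mean(axis=1).to_numpy()
    return pd.Series(fc, index=expr.index, name=f"{group}:{later}-{earlier}")


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Merge table (scipy linkage convention) plus deterministic leaf order.

    Leaves are numbered 0..n-1 in input row order; the cluster created at
    merge step i gets id n+i. Heights are average inter-cluster Euclidean
    distances and are nondecreasing.
    """

    labels: list
    merges: np.ndarray        # steps x 4: left id, right id, height, size
    leaf_order: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(1, len(self.merges) + 1),
            "left": self.merges[:, 0].astype(int),
            "right": self.merges[:, 1].astype(int),
            "height": self.merges[:, 2],
            "size": self.merges[:, 3].astype(int),
        })

    def newick(self) -> str:
        """Nested-parenthesis text form with merge heights as labels."""
        n = len(self.labels)

        def render(cid: int) -> str:
            if cid < n:
                return str(self.labels[cid])
            left, right, h, _ = self.merges[cid - n]
            return f"({render(int(left))},{render(int(right))}):{h:.6g}"

        return render(n + len(self.merges) - 1) + ";"


def average_linkage_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative UPGMA clustering on Euclidean row distances.

    Ties between candidate merges are broken by the smallest (left, right)
    cluster-id pair; each merge records the unweighted average distance
    between the two clusters' members. Missing values are rejected.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need >=2 rows to cluster")
    if not np.isfinite(X).all():
        raise ValidationError("missing or non-finite values in input")
    n = X.shape[0]
    D = squareform(pdist(X, metric="euclidean"))

    # active cluster id -> (size, index into the working distance table)
    dist: dict[tuple, float] = {}
    active: list[int] = list(range(n))
    sizes = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])

    merges = np.zeros((n - 1, 4))
    children: dict[int, tuple] = {}
    next_id = n
    for step in range(n - 1):
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (ci, cj), h = best
        si, sj = sizes[ci], sizes[cj]
        merges[step] = (ci, cj, h, si + sj)
        children[next_id] = (ci, cj)
        active.remove(ci)
        active.remove(cj)
        for ck in active:
            dik = dist.pop((min(ci, ck), max(ci, ck)))
            djk = dist.pop((min(cj, ck), max(cj, ck)))
            dist[(ck, next_id)] = (si * dik + sj * djk) / (si + sj)
        del dist[(ci, cj)]
        sizes[next_id] = si + sj
        active.append(next_id)
        next_id += 1

    def leaves(cid: int) -> list:
        if cid < n:
            return [cid]
        l, r = children[cid]
        return leaves(l) + leaves(r)

    order = leaves(next_id - 1) if n > 1 else [0]
    return Dendrogram(labels=list(matrix.index), merges=merges,
                      leaf_order=order)
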