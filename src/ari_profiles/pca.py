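"""Covariance PCA of the illness gene set and signature extraction.

PCA is run on the covariance matrix of log2 intensities (genes are
variables, samples observations; no variance scaling), computed through an
SVD of the centred matrix so that gene count >> sample count is handled.
PC1 is taken to carry the illness-associated variation; its sign is fixed
so that the symptomatic reference time point scores positive. Per group and
time-point transition, genes are ranked by PC1 loading and the top-N in the
focal direction form that group's signature profile. Profiles from the four
groups are intersected into a full Venn-region table: genes present in all
groups are "core", in exactly one group "distinct:<group>", in any strict
subset of >=2 groups "shared:<subset>".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import clinical
from .errors import (
    DecompositionError,
    DegenerateTestError,
    ValidationError,
)


@dataclass
class PCAResult:
    """Scores, loadings and variance-explained of a covariance PCA."""

    sample_ids: list
    gene_ids: list
    scores: np.ndarray          # n_samples x k
    loadings: np.ndarray        # n_genes x k, unit columns
    var_explained: np.ndarray   # k, proportions of total gene variance
    pc1_oriented: bool = False

    def pc1_scores(self) -> pd.Series:
        return pd.Series(self.scores[:, 0], index=self.sample_ids)

    def pc1_loadings(self) -> pd.Series:
        return pd.Series(self.loadings[:, 0], index=self.gene_ids)


@dataclass(frozen=True)
class TransitionSpec:
    """An ordered time-point pair within one group (or all samples)."""

    group: str                      # group label or "all"
    timepoints: tuple               # (earlier, later)
    reference: str                  # symptomatic time point (PC1 positive)
    focal: tuple                    # focal time point(s) for profiles

    def __post_init__(self) -> None:
        if len(self.timepoints) != 2:
            raise ValidationError("a transition joins exactly two time points")
        if self.reference not in self.timepoints:
            raise ValidationError("reference must be one of the two time points")
        for f in self.focal:
            if f not in self.timepoints:
                raise ValidationError("focal time points must belong to the pair")


#: The three stages of illness: peak (BL->D2), reduction (D2->D6),
#: resolution (D6->BL), each with its symptomatic reference and the focal
#: time point(s) whose profiles are compared across groups.
STANDARD_TRANSITIONS = (
    TransitionSpec("all", ("BL", "D2"), reference="D2", focal=("D2",)),
    TransitionSpec("all", ("D2", "D6"), reference="D2", focal=("D2", "D6")),
    TransitionSpec("all", ("D6", "BL"), reference="D6", focal=("D6",)),
)

STAGE_NAMES = {("BL", "D2"): "peak", ("D2", "D6"): "reduction",
               ("D6", "BL"): "resolution"}


@dataclass
class SignatureProfile:
    """Ranked top-N PC1-loading gene list for one group/focal time point."""

    group: str
    focal_timepoint: str
    direction: str                 # "positive" or "negative"
    gene_ids: list
    loadings: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.gene_ids) + 1),
            "gene_id": self.gene_ids,
            "loading": self.loadings,
            "direction": self.direction,
        })


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def run_covariance_pca(expr: pd.DataFrame) -> PCAResult:
    """Covariance-matrix PCA of a genes x samples block.

    Each gene is centred across samples; no scaling to unit variance.
    Components are computed from the SVD of the centred sample x gene
    matrix. Signs are canonicalised (largest-|loading| gene positive) so the
    decomposition is deterministic; PC1 orientation proper is applied by
    :func:`orient_pc1`.
    """
    Y = np.asarray(expr, dtype=float)
    n_genes, n_samples = Y.shape
    if n_samples < 2:
        raise DecompositionError("need >=2 samples")
    if n_genes < 2:
        raise DecompositionError("need >=2 genes")
    Xc = (Y - Y.mean(axis=1, keepdims=True)).T      # samples x genes
    total_var = float(np.sum(Xc ** 2) / (n_samples - 1))
    if total_var <= 0:
        raise DecompositionError("all genes constant; covariance is zero")

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_samples - 1, n_genes)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]

    loadings = Vt.T                                  # genes x k, unit columns
    scores = U * S
    # canonical sign: gene with the largest |loading| loads positively
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    var_explained = (S ** 2) / (n_samples - 1) / total_var
    return PCAResult(
        sample_ids=list(expr.columns), gene_ids=list(expr.index),
        scores=scores, loadings=loadings, var_explained=var_explained,
    )


def orient_pc1(pca: PCAResult, reference_samples: Sequence[str]) -> PCAResult:
    """Fix the PC1 sign so the symptomatic reference scores non-negative.

    Flipping twice is the identity. A reference mean of exactly zero keeps
    the current orientation with a warning.
    """
    ref = [s for s in reference_samples]
    if not ref:
        raise ValidationError("reference subset must be nonempty")
    pos = [pca.sample_ids.index(s) for s in ref]
    mean_score = float(np.mean(pca.scores[pos, 0]))
    scores = pca.scores.copy()
    loadings = pca.loadings.copy()
    if mean_score < 0:
        scores[:, 0] *= -1.0
        loadings[:, 0] *= -1.0
    elif mean_score == 0:
        warnings.warn("reference PC1 mean is exactly zero; orientation kept",
                      stacklevel=2)
    return replace(pca, scores=scores, loadings=loadings, pc1_oriented=True)


# ---------------------------------------------------------------------------
# separation testing
# ---------------------------------------------------------------------------

def test_pc1_separation(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    paired: bool = False,
) -> clinical.StatResult:
    """Compare PC1 scores of two time-point clusters.

    Paired t-test for subject-matched samples (in matching order);
    Mann-Whitney U otherwise (exact at small n).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not paired:
        return clinical.mann_whitney_u(a, b)
    if a.size != b.size:
        raise ValidationError("paired mode requires equal-length score vectors")
    if a.size < 2:
        raise ValidationError("paired mode requires >=2 complete pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        if np.all(d == 0):
            return clinical.StatResult("paired_t", 0.0, 1.0, (a.size,))
        raise DegenerateTestError("paired differences have zero variance")
    t = float(np.mean(d) / (sd / np.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), d.size - 1))
    return clinical.StatResult("paired_t", t, p, (a.size,))


# ---------------------------------------------------------------------------
# profile selection and membership
# ---------------------------------------------------------------------------

def select_loading_profile(
    pca: PCAResult,
    focal_samples: Sequence[str],
    n_top: int = 100,
    group: str = "all",
    focal_timepoint: str = "",
) -> SignatureProfile:
    """Top-N PC1-loading genes in the direction of the focal time point.

    Direction is positive when the focal samples' mean PC1 score is
    positive (rank by most positive loading, i.e. genes highest at the
    focal time point), negative otherwise (most negative loading). Ties are
    broken lexicographically by gene identifier.
    """
    if n_top <= 0:
        raise ValidationError("N must be >= 1")
    if not pca.pc1_oriented:
        warnings.warn("profile selected from an unoriented PCA", stacklevel=2)
    if not focal_samples:
        raise ValidationError("focal subset must be nonempty")
    pos = [pca.sample_ids.index(s) for s in focal_samples]
    mean_score = float(np.mean(pca.scores[pos, 0]))
    if abs(mean_score) < 1e-9:
        warnings.warn("focal PC1 mean ~ 0; defaulting to positive direction",
                      stacklevel=2)
        direction = "positive"
    else:
        direction = "positive" if mean_score > 0 else "negative"

    load = pca.loadings[:, 0]
    if direction == "positive":
        order = sorted(range(len(load)),
                       key=lambda i: (-load[i], pca.gene_ids[i]))
    else:
        order = sorted(range(len(load)),
                       key=lambda i: (load[i], pca.gene_ids[i]))
    top = order[:min(n_top, len(order))]
    return SignatureProfile(
        group=group, focal_timepoint=focal_timepoint, direction=direction,
        gene_ids=[pca.gene_ids[i] for i in top],
        loadings=load[top],
    )


def classify_membership(profiles: Mapping[str, SignatureProfile]) -> pd.DataFrame:
    """Full Venn classification of profile genes across groups.

    Returns a table with one row per gene in the union of profiles:
    ``groups`` (comma-joined members) and ``class`` in {core,
    shared:<subset>, distinct:<group>}.
    """
    if len(profiles) < 2:
        raise ValidationError("need profiles from >=2 groups")
    labels = list(profiles)
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate group labels")
    membership: dict[str, list] = {}
    for g in labels:
        for gene in profiles[g].gene_ids:
            membership.setdefault(gene, []).append(g)
    rows = []
    for gene in sorted(membership):
        present = membership[gene]
        if len(present) == len(labels):
            klass = "core"
        elif len(present) == 1:
            klass = f"distinct:{present[0]}"
        else:
            klass = "shared:" + "+".join(sorted(present))
        rows.append((gene, ",".join(sorted(present)), klass))
    return pd.DataFrame(rows, columns=["gene_id", "groups", "class"])


def venn_counts(membership: pd.DataFrame) -> pd.DataFrame:
    """Per Venn-region gene counts; regions sum to the union size."""
    counts = (membership.groupby("groups").size()
              .rename("count").reset_index().rename(columns={"groups": "region"}))
    return counts.sort_values("region", ignore_index=True)


def correlate_expression_with_loadings(
    delta_expr: Sequence[float],
    loadings: Sequence[float],
) -> clinical.StatResult:
    """Spearman correlation between expression change and PC1 loading."""
    d = np.asarray(delta_expr, dtype=float)
    l = np.asarray(loadings, dtype=float)
    if d.size < 3:
        raise ValidationError("need >=3 genes")
    return clinical.spearman(d, l)
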