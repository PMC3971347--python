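"""Blocked moderated differential expression over the 4 x 3 visit design.

Per gene, a cell-means linear model over the group x timepoint cells is fit
by generalized least squares under a block-equicorrelated covariance: repeat
visits of one subject share a single consensus correlation rho, subjects are
independent. rho itself is a robust average (trimmed mean on the atanh
scale) of per-gene method-of-moments estimates from the subject-blocked
ANOVA decomposition.

Residual variances are then shrunk across genes with the empirical-Bayes
hierarchy s_g^2 ~ s0^2 * F(d_g, d0): the prior (d0, s0^2) is estimated by
moment-matching the distribution of log s_g^2 through the digamma/trigamma
identities, the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t-statistic b_g / sqrt(s~_g^2 * v_g) is referred to a t
distribution on d0 + d_g degrees of freedom. Family-wise error over genes is
controlled per contrast with Holm's step-down adjustment (a Benjamini-
Hochberg FDR column is emitted alongside). The illness-associated ("ARI")
gene set is the union of Holm-significant genes over the contrasts, with no
fold-change cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .errors import (
    DegenerateVarianceError,
    EstimationError,
    ModelError,
    ValidationError,
)

DEFAULT_TRIM = 0.15
D0_CAP = 1e6


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Cell-means design over (group, timepoint) with subject blocking.

    ``contrasts`` maps a contrast name to a weight vector over the cells.
    The three time-point contrasts (e.g. "D2-BL") are time main effects
    averaged with equal weight over groups; "<group>:D2-BL" style contrasts
    are the same differences within one group.
    """

    sample_ids: list
    groups: tuple
    timepoints: tuple
    cells: list                      # ordered (group, timepoint) labels
    cell_index: np.ndarray           # per sample -> index into cells
    subjects: np.ndarray             # per sample subject label
    X: np.ndarray                    # n_samples x n_cells indicator matrix
    contrasts: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _timepoint_pairs(timepoints: Sequence[str]) -> list[tuple[str, str]]:
    pairs = [(timepoints[i + 1], timepoints[i])
             for i in range(len(timepoints) - 1)]
    if len(timepoints) >= 3:
        pairs.append((timepoints[-1], timepoints[0]))
    return pairs


def build_design(
    annotation: pd.DataFrame,
    groups: Sequence[str] | None = None,
    timepoints: Sequence[str] | None = None,
    group_contrasts: bool = True,
) -> DesignSpec:
    """Construct the cell-means design and standard contrasts from annotation.

    Raises ``ModelError`` listing aliased (empty) cells when any
    group x timepoint combination has no sample.
    """
    required = {"subject_id", "group", "timepoint"}
    if not required.issubset(annotation.columns):
        raise ValidationError(f"annotation needs columns {sorted(required)}")
    groups = tuple(groups) if groups else tuple(
        pd.unique(annotation["group"]))
    timepoints = tuple(timepoints) if timepoints else tuple(
        pd.unique(annotation["timepoint"]))

    subj_groups = annotation.groupby("subject_id")["group"].nunique()
    if (subj_groups > 1).any():
        bad = subj_groups[subj_groups > 1].index.tolist()
        raise ValidationError(f"subjects in multiple groups: {bad}")

    cells = [(g, t) for g in groups for t in timepoints]
    cell_pos = {c: i for i, c in enumerate(cells)}
    try:
        cell_index = np.array([
            cell_pos[(g, t)] for g, t in
            zip(annotation["group"], annotation["timepoint"])])
    except KeyError as exc:  # label outside declared factor levels
        raise ValidationError(f"sample with unknown cell {exc}") from exc

    counts = np.bincount(cell_index, minlength=len(cells))
    empty = [cells[i] for i in np.flatnonzero(counts == 0)]
    if empty:
        raise ModelError(f"design is rank deficient; aliased cells: {empty}")

    X = np.zeros((len(annotation), len(cells)))
    X[np.arange(len(annotation)), cell_index] = 1.0

    contrasts: dict[str, np.ndarray] = {}
    for later, earlier in _timepoint_pairs(timepoints):
        c = np.zeros(len(cells))
        for g in groups:
            c[cell_pos[(g, later)]] += 1.0 / len(groups)
            c[cell_pos[(g, earlier)]] -= 1.0 / len(groups)
        contrasts[f"{later}-{earlier}"] = c
        if group_contrasts and len(groups) > 1:
            for g in groups:
                cg = np.zeros(len(cells))
                cg[cell_pos[(g, later)]] = 1.0
                cg[cell_pos[(g, earlier)]] = -1.0
                contrasts[f"{g}:{later}-{earlier}"] = cg

    return DesignSpec(
        sample_ids=list(annotation.index),
        groups=groups, timepoints=timepoints,
        cells=cells, cell_index=cell_index,
        subjects=annotation["subject_id"].to_numpy(),
        X=X, contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# consensus within-subject correlation
# ---------------------------------------------------------------------------

@dataclass
class ConsensusCorrelation:
    """Robust average of per-gene within-subject correlations."""

    rho: float
    per_gene_estimates: np.ndarray
    trim_fraction: float


def robust_average(estimates, trim: float = DEFAULT_TRIM) -> float:
    """Trimmed mean of correlations on the atanh scale, back-transformed."""
    z = np.arctanh(np.asarray(estimates, dtype=float))
    return float(np.tanh(stats.trim_mean(z, trim)))


def estimate_consensus_correlation(
    expr: pd.DataFrame,
    design: DesignSpec,
    trim: float = DEFAULT_TRIM,
    clamp: tuple[float, float] = (-0.95, 0.99),
) -> ConsensusCorrelation:
    """Estimate the consensus correlation among repeat visits of a subject.

    Per gene, cell means (group x timepoint) are removed and the residuals
    are decomposed into between- and within-subject mean squares pooled over
    groups (method of moments); the intraclass correlation

        (MSB - MSW) / (MSB + (n0 - 1) * MSW)

    estimates rho. Only subjects with >=2 retained visits inform the
    estimate. The consensus is the two-sided trimmed mean on the
    inverse-hyperbolic-tangent scale, back-transformed.
    """
    Y = np.asarray(expr, dtype=float)
    if Y.shape[1] != design.n_samples:
        raise ValidationError("expression columns do not match design samples")

    subjects = design.subjects
    counts = pd.Series(subjects).value_counts()
    keep_subj = set(counts[counts >= 2].index)
    if len(keep_subj) < 2:
        raise EstimationError("need >=2 subjects with repeated visits")
    keep = np.array([s in keep_subj for s in subjects])

    Yk = Y[:, keep]
    cell_k = design.cell_index[keep]
    subj_k = pd.factorize(subjects[keep])[0]
    group_of_subj = {}
    grp_idx = {g: i for i, g in enumerate(design.groups)}
    for sid, ci in zip(subj_k, cell_k):
        group_of_subj[sid] = grp_idx[design.cells[ci][0]]

    n = Yk.shape[1]
    n_cells = len(design.cells)
    n_subj = subj_k.max() + 1

    # residuals about cell means (computed on the retained samples)
    C = np.zeros((n, n_cells))
    C[np.arange(n), cell_k] = 1.0
    cell_counts = C.sum(axis=0)
    cell_counts[cell_counts == 0] = 1.0
    cell_means = (Yk @ C) / cell_counts
    R = Yk - cell_means[:, cell_k]

    S = np.zeros((n, n_subj))
    S[np.arange(n), subj_k] = 1.0
    n_s = S.sum(axis=0)
    m = (R @ S) / n_s                       # per-gene subject means
    ssb = np.sum((m ** 2) * n_s, axis=1)
    D = R - m[:, subj_k]
    ssw = np.sum(D ** 2, axis=1)

    # pooled degrees of freedom (cell-mean centering costs T-1 df per group)
    df_b = 0.0
    df_w = 0.0
    n0_num = 0.0
    for gi in range(len(design.groups)):
        sids = [s for s, g in group_of_subj.items() if g == gi]
        if not sids:
            continue
        ns_g = n_s[sids]
        N_g = float(ns_g.sum())
        t_eff = len({design.cells[ci][1] for ci, si in zip(cell_k, subj_k)
                     if group_of_subj[si] == gi})
        df_b += len(sids) - 1
        df_w += float((ns_g - 1).sum()) - (t_eff - 1)
        n0_num += N_g - float((ns_g ** 2).sum()) / N_g
    if df_b <= 0 or df_w <= 0:
        raise EstimationError("not enough replication to separate "
                              "between- and within-subject variance")
    n0 = n0_num / df_b

    msb = ssb / df_b
    msw = ssw / df_w
    denom = msb + (n0 - 1.0) * msw
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msb - msw) / denom, 0.0)
    icc = np.clip(icc, clamp[0], clamp[1])

    consensus = robust_average(icc, trim)
    return ConsensusCorrelation(consensus, icc, trim)


# ---------------------------------------------------------------------------
# per-gene GLS fits
# ---------------------------------------------------------------------------

@dataclass
class GeneModelFits:
    """Vectorised per-gene fits: coefficients, variances, residual df."""

    gene_ids: list
    contrast_names: list
    coefficients: np.ndarray      # n_genes x n_contrasts (log2 fold changes)
    unscaled_var: np.ndarray      # n_contrasts (v_g; shared across genes)
    sigma2: np.ndarray            # n_genes residual variances
    df_residual: np.ndarray       # n_genes residual degrees of freedom


def fit_gene_models(
    expr: pd.DataFrame,
    design: DesignSpec,
    rho: ConsensusCorrelation | float = 0.0,
) -> GeneModelFits:
    """GLS cell-means fit per gene under within-subject equicorrelation.

    With rho = 0 this reduces exactly to ordinary least squares. The
    correlation matrix is block diagonal over subjects; a single Cholesky
    whitening is shared by all genes.
    """
    rho_val = rho.rho if isinstance(rho, ConsensusCorrelation) else float(rho)
    if not (-1.0 < rho_val < 1.0):
        raise ValidationError("rho must lie in (-1, 1)")
    Y = np.asarray(expr, dtype=float)
    n = design.n_samples
    if Y.shape[1] != n:
        raise ValidationError("expression columns do not match design samples")

    subj_codes = pd.factorize(design.subjects)[0]
    R = np.where(subj_codes[:, None] == subj_codes[None, :], rho_val, 0.0)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)

    Xw = linalg.solve_triangular(L, design.X, lower=True)
    Yw = linalg.solve_triangular(L, Y.T, lower=True)   # n x genes

    p = Xw.shape[1]
    if np.linalg.matrix_rank(Xw) < p:
        raise ModelError("whitened design is rank deficient")

    coef, _, _, _ = np.linalg.lstsq(Xw, Yw, rcond=None)   # p x genes
    resid = Yw - Xw @ coef
    rss = np.sum(resid ** 2, axis=0)
    d = n - p
    sigma2 = rss / d if d > 0 else np.zeros_like(rss)
    sigma2 = np.where(sigma2 < 0, 0.0, sigma2)

    names = list(design.contrasts)
    Cmat = np.array([design.contrasts[c] for c in names])  # C x p
    b = (Cmat @ coef).T                                    # genes x C
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    v = np.einsum("cp,pq,cq->c", Cmat, xtx_inv, Cmat)

    return GeneModelFits(
        gene_ids=list(expr.index), contrast_names=names,
        coefficients=b, unscaled_var=v, sigma2=sigma2,
        df_residual=np.full(Y.shape[0], float(d)),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModerationPrior:
    """Prior degrees of freedom and variance of the variance hierarchy."""

    d0: float
    s0_squared: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("d0 must be >= 0")
        if self.s0_squared < 0:
            raise ValidationError("s0^2 must be >= 0")


def _trigamma_inverse(y: float, iters: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return D0_CAP
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(iters):
        tri = float(special.polygamma(1, x))
        tetra = float(special.polygamma(2, x))
        delta = (tri - y) / tetra
        x -= delta
        if x <= 0:
            x = 1e-8
        if abs(delta) < 1e-10 * x:
            break
    return x


def estimate_prior(
    sigma2: np.ndarray,
    df: np.ndarray,
    d0_cap: float = D0_CAP,
) -> ModerationPrior:
    """Moment-match (d0, s0^2) from the spread of log residual variances.

    Under the scaled-F hierarchy, e_g = log s_g^2 - digamma(d_g/2) +
    log(d_g/2) has mean log s0^2 + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2) beyond the sampling term trigamma(d_g/2). When
    the observed dispersion is at or below its theoretical minimum, d0 is
    capped (no shrinkage spread: s~^2 -> s0^2-weighted with huge d0).
    """
    ok = (df > 0) & (sigma2 > 0)
    if not np.any(df > 0):
        raise EstimationError("no gene has residual degrees of freedom")
    if not np.any(sigma2[df > 0] > 0):
        raise DegenerateVarianceError("all residual variances are zero")
    s2 = sigma2[ok]
    d = df[ok]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if d0 >= d0_cap:
            d0 = d0_cap
            s0 = math.exp(emean)
        else:
            s0 = math.exp(emean + float(special.digamma(d0 / 2.0))
                          - math.log(d0 / 2.0))
    else:
        # dispersion at/below its sampling minimum: no evidence of spread in
        # the true variances; the prior variance is their geometric mean so
        # that identical s_g^2 shrink to themselves
        d0 = d0_cap
        s0 = math.exp(float(np.mean(z)))
    return ModerationPrior(d0=d0, s0_squared=s0)


def moderate_statistics(
    fits: GeneModelFits,
    prior: ModerationPrior | None = None,
    alpha: float = 0.05,
    prior_de_proportion: float = 0.01,
    prior_var_ratio: float = 10.0,
) -> tuple[ModerationPrior, pd.DataFrame]:
    """Moderated t-statistics, raw/Holm/BH p-values and B per contrast.

    The returned tidy table has one row per (gene, contrast); the Holm
    family is all genes within one contrast. ``prior`` may be supplied to
    bypass estimation (d0 = 0 recovers the ordinary t-statistic exactly).
    The B column is the log posterior odds of differential expression with
    a fixed prior DE proportion and prior variance ratio; it is reported
    but never used for selection.
    """
    if prior is None:
        if int(np.sum(fits.df_residual > 0)) < 10:
            raise EstimationError(
                "prior estimation needs >=10 genes with residual df")
        prior = estimate_prior(fits.sigma2, fits.df_residual)
    d0, s02 = prior.d0, prior.s0_squared

    d = fits.df_residual
    s2_post = (d0 * s02 + d * fits.sigma2) / np.maximum(d0 + d, 1e-300)
    df_total = d0 + d
    flagged_no_df = d <= 0

    frames = []
    k = 1.0 / (1.0 + prior_var_ratio)
    logit_p1 = math.log(prior_de_proportion / (1.0 - prior_de_proportion))
    for ci, cname in enumerate(fits.contrast_names):
        b = fits.coefficients[:, ci]
        se = np.sqrt(s2_post * fits.unscaled_var[ci])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, b / se, 0.0)
        p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)
        p_raw = np.clip(p_raw, 0.0, 1.0)
        lods = (logit_p1 + 0.5 * math.log(k)
                + stats.t.logpdf(t * math.sqrt(k), df_total)
                - stats.t.logpdf(t, df_total))
        frames.append(pd.DataFrame({
            "gene_id": fits.gene_ids,
            "contrast": cname,
            "logFC": b,
            "t_moderated": t,
            "s2_posterior": s2_post,
            "p_raw": p_raw,
            "p_holm": holm_adjust(p_raw),
            "p_bh": bh_adjust(p_raw),
            "B": lods,
            "no_residual_df": flagged_no_df,
        }))
    table = pd.concat(frames, ignore_index=True)
    return prior, table


def moderated_t(
    b: float, v: float, s2: float, d: float, prior: ModerationPrior,
) -> tuple[float, float]:
    """Single-gene moderated t and its total degrees of freedom."""
    s2_post = (prior.d0 * prior.s0_squared + d * s2) / (prior.d0 + d)
    return b / math.sqrt(s2_post * v), prior.d0 + d


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    adj_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending order
    statistics; monotone nondecreasing in that order and never below the
    raw p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    mult = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(mult))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def select_ari_genes(
    tables: Iterable[pd.DataFrame] | pd.DataFrame,
    alpha: float = 0.05,
) -> set:
    """Union of Holm-significant genes over the contrast tables.

    No fold-change cutoff is applied. ``tables`` is either a list of
    per-contrast tables or one tidy table with a ``contrast`` column; all
    families must share the gene universe.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    if isinstance(tables, pd.DataFrame):
        tables = [t for _, t in tables.groupby("contrast", sort=True)]
    tables = list(tables)
    if not tables:
        raise ValidationError("no contrast tables supplied")
    universe = None
    selected: set = set()
    for t in tables:
        genes = frozenset(t["gene_id"])
        if universe is None:
            universe = genes
        elif genes != universe:
            raise ValidationError("contrast tables have mismatched gene universes")
        selected |= set(t.loc[t["p_holm"] < alpha, "gene_id"])
    return selected
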