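"""Clinical statistics for the longitudinal cold study.

This module holds the a-priori asthma-exacerbation adjudicator and the small
set of nonparametric tests used throughout the analysis: the Friedman
repeated-measures rank test (three visits per subject), the Mann-Whitney U
test for between-group comparisons (exact by enumeration at small n),
Spearman rank correlation, and the two-reference-gene qPCR normalisation.

The adjudicator encodes the study's a-priori definition of an asthma
exacerbation during acute respiratory illness: either (1) an escalation of
care (started/increased corticosteroids or sought medical care), or (2) a
rise in chest/asthma symptom score of >=10 points over the baseline-week
daily average for >=2 days, together with at least one objective change:
>=4 extra albuterol puffs/day above baseline average for >=2 days, a >=10%
fall in FEV1 at an illness visit relative to baseline, or a >=20% fall in
PEF below the best baseline-week value for >=2 days.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateTestError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)

#: Study groups treated as asthmatic by the adjudicator.
ASTHMATIC_GROUPS = ("AsmNoEx", "AsmEx")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ClinicalSeries:
    """Per-subject diary and spirometry record.

    Diary entries are daily values (twice-daily entries are averaged to one
    value per day before they reach this container). PEF is in L/min, FEV1
    in % predicted, symptom scores in points.
    """

    subject_id: str
    group: str
    baseline_symptoms: np.ndarray
    baseline_puffs: np.ndarray
    baseline_pef: np.ndarray
    illness_symptoms: np.ndarray
    illness_puffs: np.ndarray
    illness_pef: np.ndarray
    baseline_fev1: float
    illness_fev1: dict  # visit label ("D2"/"D6") -> FEV1
    eno: dict | None = None
    care_seeking: bool = False

    def __post_init__(self) -> None:
        for name in ("baseline_symptoms", "baseline_puffs", "baseline_pef",
                     "illness_symptoms", "illness_puffs", "illness_pef"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.baseline_symptoms.size < 2:
            raise ValidationError(
                f"{self.subject_id}: baseline week needs >=2 diary days")
        if self.illness_symptoms.size < 2:
            raise ValidationError(
                f"{self.subject_id}: illness window needs >=2 diary days")
        if np.any(self.baseline_pef <= 0) or np.any(self.illness_pef <= 0):
            raise ValidationError(f"{self.subject_id}: PEF must be positive")
        if self.baseline_fev1 <= 0:
            raise ValidationError(f"{self.subject_id}: FEV1 must be positive")


@dataclass(frozen=True)
class ExacerbationCriteria:
    """Thresholds of the a-priori exacerbation definition (defaults as printed)."""

    symptom_delta_min: float = 10.0   # points above baseline daily average
    symptom_days_min: int = 2
    albuterol_extra_puffs_min: float = 4.0  # puffs/day above baseline average
    albuterol_days_min: int = 2
    fev1_decline_min: float = 0.10    # fraction of baseline FEV1
    pef_decline_min: float = 0.20     # fraction of best baseline PEF
    pef_days_min: int = 2

    def __post_init__(self) -> None:
        vals = (self.symptom_delta_min, self.symptom_days_min,
                self.albuterol_extra_puffs_min, self.albuterol_days_min,
                self.fev1_decline_min, self.pef_decline_min, self.pef_days_min)
        if any(v <= 0 for v in vals):
            raise ValidationError("all exacerbation thresholds must be > 0")


@dataclass
class ExacerbationCall:
    """Adjudicator verdict with a per-day evidence trace."""

    subject_id: str
    verdict: bool
    criterion_1_met: bool
    criterion_2_met: bool
    objective_changes_met: frozenset
    evidence: dict = field(default_factory=dict)
    note: str = ""


@dataclass(frozen=True)
class StatResult:
    """A named test statistic with its p-value and sample sizes."""

    name: str
    statistic: float
    pvalue: float
    n: tuple

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or math.isnan(self.pvalue)):
            raise ValidationError(f"p-value {self.pvalue} outside [0, 1]")


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well set: target Ct plus the two housekeeping Cts (GAPDH, PPIA)."""

    sample_id: str
    target_ct: float
    reference_cts: tuple  # (GAPDH, PPIA)

    def __post_init__(self) -> None:
        for ct in (self.target_ct, *self.reference_cts):
            if not (0.0 < ct < 45.0):
                raise ValidationError(f"Ct {ct} outside (0, 45) cycles")
        if len(self.reference_cts) != 2:
            raise ValidationError("exactly two reference Cts expected")


# ---------------------------------------------------------------------------
# exacerbation adjudication
# ---------------------------------------------------------------------------

def classify_exacerbation(
    series: ClinicalSeries,
    criteria: ExacerbationCriteria = ExacerbationCriteria(),
    asthmatic_groups: Sequence[str] = ASTHMATIC_GROUPS,
) -> ExacerbationCall:
    """Apply the a-priori exacerbation definition to one subject.

    Criterion 1 is the care-seeking / corticosteroid-escalation flag.
    Criterion 2 requires the symptom condition plus >=1 objective change.
    Non-asthmatic subjects are trivially negative (with a note).
    """
    if series.group not in asthmatic_groups:
        return ExacerbationCall(
            subject_id=series.subject_id, verdict=False,
            criterion_1_met=False, criterion_2_met=False,
            objective_changes_met=frozenset(),
            note=f"group {series.group!r} is non-asthmatic; "
                 "exacerbation not adjudicated",
        )
    if series.baseline_symptoms.size < 2:
        raise InsufficientDataError(
            f"{series.subject_id}: baseline averages need >=2 diary days")

    base_sym = float(np.mean(series.baseline_symptoms))
    base_puffs = float(np.mean(series.baseline_puffs))
    best_pef = float(np.max(series.baseline_pef))

    sym_days = series.illness_symptoms >= base_sym + criteria.symptom_delta_min
    symptom_ok = int(sym_days.sum()) >= criteria.symptom_days_min

    puff_days = series.illness_puffs >= base_puffs + criteria.albuterol_extra_puffs_min
    albuterol_ok = int(puff_days.sum()) >= criteria.albuterol_days_min

    fev1_ok = False
    if series.illness_fev1:
        min_fev1 = min(series.illness_fev1.values())
        fev1_ok = min_fev1 <= (1.0 - criteria.fev1_decline_min) * series.baseline_fev1

    pef_days = series.illness_pef <= (1.0 - criteria.pef_decline_min) * best_pef
    pef_ok = int(pef_days.sum()) >= criteria.pef_days_min

    objective = frozenset(
        name for name, ok in
        (("albuterol", albuterol_ok), ("fev1", fev1_ok), ("pef", pef_ok)) if ok)
    criterion_1 = bool(series.care_seeking)
    criterion_2 = symptom_ok and bool(objective)

    return ExacerbationCall(
        subject_id=series.subject_id,
        verdict=criterion_1 or criterion_2,
        criterion_1_met=criterion_1,
        criterion_2_met=criterion_2,
        objective_changes_met=objective,
        evidence={
            "baseline_symptom_mean": base_sym,
            "baseline_puff_mean": base_puffs,
            "best_baseline_pef": best_pef,
            "symptom_days_over": sym_days.astype(bool).tolist(),
            "albuterol_days_over": puff_days.astype(bool).tolist(),
            "pef_days_under": pef_days.astype(bool).tolist(),
            "min_illness_fev1": (min(series.illness_fev1.values())
                                 if series.illness_fev1 else None),
        },
    )


# ---------------------------------------------------------------------------
# Friedman repeated-measures rank test
# ---------------------------------------------------------------------------

def friedman_test(blocks) -> StatResult:
    """Friedman test across k matched conditions (rows = subjects/blocks).

    Within-block midranks; the tie-corrected statistic

        chi2 = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

    is referred to chi-square with k-1 degrees of freedom. Blocks with any
    missing value are dropped with a warning.
    """
    table = np.asarray(blocks, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValidationError("blocks must be a 2-D table with >=2 conditions")
    complete = ~np.isnan(table).any(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} incomplete block(s)",
                      stacklevel=2)
    table = table[complete]
    n, k = table.shape
    if n < 2:
        raise InsufficientDataError("need >=2 complete blocks")

    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:  # every block entirely tied
        return StatResult("friedman_chi2", 0.0, 1.0, (n, k))
    chi2 = float(numer / denom)
    p = float(stats.chi2.sf(chi2, k - 1))
    return StatResult("friedman_chi2", chi2, p, (n, k))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Return (U_x, U_y) using midranks (ties count half)."""
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    return u_x, n1 * n2 - u_x


def _exact_u_distribution(values: np.ndarray, n1: int) -> dict[int, int]:
    """Distribution of 2*U_x over all C(N, n1) group assignments.

    Dynamic programme over tie groups of the sorted pooled sample: choosing
    c of the t tied values for sample x contributes c * (#y so far) whole
    pairs and c*(t-c)/2 tied half-pairs. Keys are 2*U (integral even with
    midranks); values are assignment counts.
    """
    vals, counts = np.unique(values, return_counts=True)
    # state: (x chosen so far) -> {2U: ways}
    states: dict[int, dict[int, int]] = {0: {0: 1}}
    total_before = 0
    for t in counts.tolist():
        new_states: dict[int, dict[int, int]] = {}
        for x_before, dist in states.items():
            y_before = total_before - x_before
            for c in range(0, min(t, n1 - x_before) + 1):
                ways_here = comb(t, c)
                du2 = 2 * c * y_before + c * (t - c)  # 2 * U contribution
                tgt = new_states.setdefault(x_before + c, {})
                for u2, w in dist.items():
                    tgt[u2 + du2] = tgt.get(u2 + du2, 0) + w * ways_here
        total_before += t
        states = new_states
    return states[n1]


def mann_whitney_u(x, y, exact_max_n: int = 8) -> StatResult:
    """Two-sided Mann-Whitney U test.

    U = min(U_x, U_y). Exact p by complete enumeration of the permutation
    distribution when both samples have <= ``exact_max_n`` observations;
    otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs >=2 observations")
    n1, n2 = len(x), len(y)
    u_x, u_y = _u_statistic(x, y)
    u = min(u_x, u_y)

    if n1 <= exact_max_n and n2 <= exact_max_n:
        dist = _exact_u_distribution(np.concatenate([x, y]), n1)
        total = comb(n1 + n2, n1)
        u2_obs = int(round(2 * u_x))
        lo = min(u2_obs, 2 * n1 * n2 - u2_obs)
        hi = 2 * n1 * n2 - lo
        p = sum(w for u2, w in dist.items() if u2 <= lo or u2 >= hi) / total
        return StatResult("mannwhitney_U", u, min(1.0, float(p)), (n1, n2))

    # tie-corrected normal approximation
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        raise DegenerateTestError("all pooled observations identical")
    mu = n1 * n2 / 2.0
    z = (u - mu + 0.5) / math.sqrt(sigma2)  # continuity-corrected, u <= mu
    p = float(min(1.0, 2.0 * stats.norm.cdf(z)))
    return StatResult("mannwhitney_U", u, p, (n1, n2))


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x, y, exact_max_n: int = 7) -> StatResult:
    """Spearman rank correlation (Pearson correlation of midranks).

    Exact permutation p for n <= ``exact_max_n``; t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _pearson(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    r = _pearson(rx, ry)

    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_pearson(rx, ry[list(perm)])) >= abs(r) - 1e-12:
                count += 1
        p = count / total
    elif abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return StatResult("spearman_rs", r, min(1.0, p), (n,))


# ---------------------------------------------------------------------------
# qPCR normalisation
# ---------------------------------------------------------------------------

def normalize_qpcr(m: QpcrMeasurement) -> float:
    """Normalised copy number 2^-(Ct_target - mean(reference Cts)).

    Averaging the two housekeeping Cts equals normalising to the geometric
    mean of the two reference abundances.
    """
    ref_ct = float(np.mean(m.reference_cts))
    return float(2.0 ** -(m.target_ct - ref_ct))


def qpcr_fold_change(a: QpcrMeasurement, b: QpcrMeasurement) -> float:
    """Fold change of normalised copy number, sample ``a`` over sample ``b``."""
    return normalize_qpcr(a) / normalize_qpcr(b)
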