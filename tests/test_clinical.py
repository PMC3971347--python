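"""Exacerbation adjudication and the nonparametric clinical tests."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from ari_profiles.clinical import (
    ClinicalSeries,
    ExacerbationCriteria,
    QpcrMeasurement,
    classify_exacerbation,
    friedman_test,
    mann_whitney_u,
    normalize_qpcr,
    qpcr_fold_change,
    spearman,
)
from ari_profiles.errors import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# adjudicator
# ---------------------------------------------------------------------------

def _series(group="AsmEx", care=False, sym_delta=0.0, sym_days=0,
            puff_delta=0.0, puff_days=0, fev1_frac=1.0, pef_frac=1.0,
            pef_days=0):
    """Construct a series whose baseline week is flat at known means."""
    nb, ni = 7, 10
    base_sym = np.full(nb, 20.0)
    base_puffs = np.full(nb, 2.0)
    base_pef = np.full(nb, 400.0)
    ill_sym = np.full(ni, 20.0)
    ill_sym[:sym_days] = 20.0 + sym_delta
    ill_puffs = np.full(ni, 2.0)
    ill_puffs[:puff_days] = 2.0 + puff_delta
    ill_pef = np.full(ni, 390.0)
    ill_pef[:pef_days] = pef_frac * 400.0
    return ClinicalSeries(
        subject_id="s", group=group,
        baseline_symptoms=base_sym, baseline_puffs=base_puffs,
        baseline_pef=base_pef,
        illness_symptoms=ill_sym, illness_puffs=ill_puffs,
        illness_pef=ill_pef,
        baseline_fev1=95.0,
        illness_fev1={"D2": fev1_frac * 95.0, "D6": 0.99 * 95.0},
        care_seeking=care,
    )


BRANCHES = [
    # (series kwargs, verdict, via)
    (dict(care=True), True, "criterion1"),
    (dict(sym_delta=12, sym_days=3, puff_delta=5, puff_days=2), True, "albuterol"),
    (dict(sym_delta=12, sym_days=2, fev1_frac=0.85), True, "fev1"),
    (dict(sym_delta=12, sym_days=2, pef_frac=0.75, pef_days=2), True, "pef"),
    (dict(sym_delta=12, sym_days=3), False, "no objective change"),
    (dict(puff_delta=5, puff_days=3, fev1_frac=0.8), False, "no symptom rise"),
    (dict(sym_delta=12, sym_days=1, puff_delta=5, puff_days=2), False,
     "symptom rise on too few days"),
    (dict(sym_delta=9, sym_days=5, puff_delta=5, puff_days=2), False,
     "symptom rise below 10 points"),
    (dict(sym_delta=12, sym_days=2, puff_delta=5, puff_days=1), False,
     "albuterol on too few days"),
    (dict(sym_delta=12, sym_days=2, fev1_frac=0.95), False,
     "FEV1 decline below 10%"),
    (dict(sym_delta=12, sym_days=2, pef_frac=0.85, pef_days=4), False,
     "PEF decline below 20%"),
    (dict(sym_delta=12, sym_days=2, pef_frac=0.75, pef_days=1), False,
     "PEF low on too few days"),
]


@pytest.mark.parametrize("kwargs, verdict, via", BRANCHES,
                         ids=[b[2] for b in BRANCHES])
def test_adjudicator_branch(kwargs, verdict, via):
    call = classify_exacerbation(_series(**kwargs))
    assert call.verdict == verdict
    assert call.verdict == (call.criterion_1_met or call.criterion_2_met)
    if verdict and via in ("albuterol", "fev1", "pef"):
        assert via in call.objective_changes_met


def test_adjudicator_non_asthmatic_trivially_negative():
    call = classify_exacerbation(_series(group="Healthy", care=True,
                                         sym_delta=20, sym_days=5,
                                         puff_delta=6, puff_days=4))
    assert not call.verdict and "non-asthmatic" in call.note


def test_adjudicator_threshold_boundaries_inclusive():
    """Thresholds are >= / <= as printed: exactly +10 points, exactly 0.9x
    FEV1 and exactly 0.8x best PEF all count."""
    assert classify_exacerbation(
        _series(sym_delta=10, sym_days=2, puff_delta=4, puff_days=2)).verdict
    assert classify_exacerbation(
        _series(sym_delta=10, sym_days=2, fev1_frac=0.9)).verdict
    assert classify_exacerbation(
        _series(sym_delta=10, sym_days=2, pef_frac=0.8, pef_days=2)).verdict


def test_criteria_validation():
    with pytest.raises(ValidationError):
        ExacerbationCriteria(symptom_delta_min=0.0)


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

def test_friedman_monotone_blocks_chi2_six():
    table = [[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [0.1, 0.2, 0.3]]
    res = friedman_test(table)
    assert res.statistic == pytest.approx(6.0)
    assert res.pvalue == pytest.approx(float(sps.chi2.sf(6.0, 2)))


def test_friedman_all_tied_and_block_exchangeability(rng):
    res = friedman_test(np.full((4, 3), 2.0))
    assert res.statistic == 0.0 and res.pvalue == 1.0
    table = rng.normal(size=(6, 3))
    base = friedman_test(table).statistic
    shuffled = table[rng.permutation(6)]
    assert friedman_test(shuffled).statistic == pytest.approx(base)


def test_friedman_matches_scipy_without_ties(rng):
    for _ in range(5):
        table = rng.normal(size=(5, 3))
        ours = friedman_test(table)
        ref_stat, ref_p = sps.friedmanchisquare(*table.T)
        assert ours.statistic == pytest.approx(ref_stat)
        assert ours.pvalue == pytest.approx(ref_p)


def test_friedman_incomplete_blocks_dropped():
    table = [[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [np.nan, 1.0, 2.0]]
    with pytest.warns(UserWarning, match="incomplete"):
        res = friedman_test(table)
    assert res.n == (2, 3)
    with pytest.raises(InsufficientDataError):
        friedman_test([[1.0, 2.0, 3.0], [np.nan, 1.0, 2.0]])


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_bruteforce_p(x, y):
    """Enumerate every assignment of the pooled values to the two samples."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)

    u_obs = u_of(range(n1))
    lo = min(u_obs, n1 * (n - n1) - u_obs)
    hi = n1 * (n - n1) - lo
    us = [u_of(c) for c in itertools.combinations(range(n), n1)]
    return sum(1 for u in us if u <= lo + 1e-9 or u >= hi - 1e-9) / len(us)


def test_mwu_hand_examples():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0 and res.pvalue == pytest.approx(0.1)
    same = mann_whitney_u([1, 2, 5], [1, 2, 5])
    assert same.statistic == pytest.approx(9 / 2.0)
    a = mann_whitney_u([1, 3, 7, 9], [2, 4, 6, 8])
    b = mann_whitney_u([2, 6, 14, 18], [4, 8, 12, 16])
    assert a.statistic == b.statistic and a.pvalue == b.pvalue
    with pytest.raises(ValidationError):
        mann_whitney_u([1.0], [2.0, 3.0])


def test_mwu_exact_matches_enumeration(rng):
    """Exact p equals brute-force enumeration for all n1, n2 <= 6,
    with and without ties."""
    for n1 in range(2, 7):
        for n2 in range(2, 7):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney_u(x, y)
            assert res.pvalue == pytest.approx(_mwu_bruteforce_p(x, y))
            xt = np.round(rng.normal(size=n1))   # heavy ties
            yt = np.round(rng.normal(size=n2))
            res_t = mann_whitney_u(xt, yt)
            assert res_t.pvalue == pytest.approx(_mwu_bruteforce_p(xt, yt))


def test_mwu_exact_matches_scipy_without_ties(rng):
    x = rng.normal(size=6)
    y = rng.normal(size=5)
    ours = mann_whitney_u(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert ours.pvalue == pytest.approx(ref.pvalue)


def test_mwu_normal_approximation_reasonable(rng):
    x = rng.normal(0, 1, 30)
    y = rng.normal(0.8, 1, 30)
    ours = mann_whitney_u(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert ours.pvalue == pytest.approx(ref.pvalue, rel=0.05)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_hand_examples():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
    assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == -1.0
    tied = spearman([1, 2, 3], [1, 1, 2])
    assert tied.statistic == pytest.approx(np.sqrt(3) / 2)   # ~0.866
    with pytest.raises(UndefinedCorrelationError):
        spearman([1, 1, 1], [1, 2, 3])


def test_spearman_matches_scipy(rng):
    x = rng.normal(size=20)
    y = x + rng.normal(size=20)
    ours = spearman(x, y)
    ref = sps.spearmanr(x, y)
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.pvalue == pytest.approx(ref.pvalue, rel=0.01)


def test_spearman_exact_small_n_permutation():
    res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
    # r = 0.8; exact two-sided permutation p over 24 orderings
    perms = itertools.permutations([1, 3, 2, 4])
    rs = [sps.spearmanr([1, 2, 3, 4], p).statistic for p in perms]
    expected = np.mean([abs(r) >= 0.8 - 1e-9 for r in rs])
    assert res.pvalue == pytest.approx(expected)


# ---------------------------------------------------------------------------
# qPCR normalisation
# ---------------------------------------------------------------------------

def test_qpcr_hand_example_and_invariances():
    m = QpcrMeasurement("s1", target_ct=25.0, reference_cts=(20.0, 22.0))
    assert normalize_qpcr(m) == pytest.approx(0.0625)
    centred = QpcrMeasurement("s1", 21.0, (21.0, 21.0))
    assert normalize_qpcr(centred) == pytest.approx(1.0)
    shifted = QpcrMeasurement("s1", 28.0, (23.0, 25.0))
    assert normalize_qpcr(shifted) == pytest.approx(normalize_qpcr(m))
    assert qpcr_fold_change(m, m) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        QpcrMeasurement("s1", 46.0, (20.0, 22.0))
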