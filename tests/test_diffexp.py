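"""Blocked GLS fits, consensus correlation, moderation and Holm adjustment."""

from __future__ import annotations

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ari_profiles import diffexp
from ari_profiles.cohort import CohortConfig, generate_expression
from ari_profiles.diffexp import (
    GeneModelFits,
    ModerationPrior,
    bh_adjust,
    build_design,
    estimate_consensus_correlation,
    estimate_prior,
    fit_gene_models,
    holm_adjust,
    moderate_statistics,
    moderated_t,
    robust_average,
    select_ari_genes,
)
from ari_profiles.errors import (
    EstimationError,
    ModelError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def test_design_contrasts_average_over_groups(small_cohort):
    _, _, annot, _ = small_cohort
    design = build_design(annot)
    assert len(design.cells) == 12
    c = design.contrasts["D2-BL"]
    # +1/4 on every (group, D2) cell, -1/4 on every (group, BL) cell
    for i, (g, t) in enumerate(design.cells):
        expected = 0.25 if t == "D2" else (-0.25 if t == "BL" else 0.0)
        assert c[i] == pytest.approx(expected)
    assert "AsmEx:D6-D2" in design.contrasts


def test_design_empty_cell_is_aliased(paired_toy_annotation):
    broken = paired_toy_annotation.drop(index=["s1_D2", "s2_D2"])
    broken = pd.concat([broken, pd.DataFrame(
        {"subject_id": ["s3"], "group": ["Healthy"], "timepoint": ["D2"]},
        index=pd.Index(["s3_D2"], name="sample_id"))])
    broken.loc["s3_D2", "timepoint"] = "D6"  # leaves (Healthy, D2) empty
    with pytest.raises(ModelError, match="aliased"):
        build_design(broken, timepoints=("BL", "D2", "D6"))


# ---------------------------------------------------------------------------
# consensus correlation
# ---------------------------------------------------------------------------

def test_robust_average_constant_and_hand_value():
    assert robust_average([0.3, 0.3, 0.3], trim=0.15) == pytest.approx(0.3)
    expect = math.tanh(np.mean(np.arctanh([0.1, 0.3, 0.5])))
    assert robust_average([0.1, 0.3, 0.5], trim=0.0) == pytest.approx(expect)
    assert expect == pytest.approx(0.309, abs=5e-4)


def test_consensus_recovers_simulated_rho():
    cfg = CohortConfig(n_genes=2000, n_subjects_per_group=8,
                       n_core_d2=0, n_shared_d6=0, n_distinct_d6=0,
                       within_subject_rho=0.3, seed=31)
    expr, annot, _ = generate_expression(cfg)
    cc = estimate_consensus_correlation(expr, build_design(annot))
    assert 0.25 <= cc.rho <= 0.35
    assert -1 < cc.rho < 1


def test_consensus_needs_repeated_measures(paired_toy_annotation):
    annot = paired_toy_annotation.iloc[[0, 2]]  # one visit per subject
    expr = pd.DataFrame(np.arange(20, dtype=float).reshape(10, 2),
                        columns=annot.index)
    with pytest.raises(EstimationError):
        estimate_consensus_correlation(
            expr, build_design(annot, timepoints=("BL",)))


# ---------------------------------------------------------------------------
# GLS fits
# ---------------------------------------------------------------------------

def test_gls_with_zero_rho_equals_ols(small_cohort):
    _, expr, annot, _ = small_cohort
    design = build_design(annot)
    fits = fit_gene_models(expr, design, rho=0.0)
    beta, *_ = np.linalg.lstsq(design.X, expr.to_numpy().T, rcond=None)
    c = design.contrasts["D2-BL"]
    ci = fits.contrast_names.index("D2-BL")
    np.testing.assert_allclose(fits.coefficients[:, ci], c @ beta,
                               rtol=0, atol=1e-12)


def test_constant_gene_yields_zero_contrasts(small_cohort):
    _, expr, annot, _ = small_cohort
    expr = expr.copy()
    expr.iloc[0] = 7.0
    fits = fit_gene_models(expr, build_design(annot), rho=0.4)
    np.testing.assert_allclose(fits.coefficients[0], 0.0, atol=1e-10)
    assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-18)


def test_paired_toy_contrast_is_mean_paired_difference(paired_toy_annotation):
    # s1: BL=1, D2=3 (diff 2); s2: BL=2, D2=6 (diff 4) -> contrast 3
    expr = pd.DataFrame([[1.0, 3.0, 2.0, 6.0]], index=["g0"],
                        columns=paired_toy_annotation.index)
    design = build_design(paired_toy_annotation)
    for rho in (0.0, 0.5, 0.8):
        fits = fit_gene_models(expr, design, rho=rho)
        ci = fits.contrast_names.index("D2-BL")
        assert fits.coefficients[0, ci] == pytest.approx(3.0, abs=1e-10)


# ---------------------------------------------------------------------------
# moderation
# ---------------------------------------------------------------------------

def _fits_from_arrays(b, v, s2, d):
    n = len(s2)
    return GeneModelFits(
        gene_ids=[f"g{i}" for i in range(n)], contrast_names=["c"],
        coefficients=np.asarray(b, dtype=float).reshape(n, 1),
        unscaled_var=np.array([v], dtype=float),
        sigma2=np.asarray(s2, dtype=float),
        df_residual=np.full(n, float(d)),
    )


def test_moderated_t_hand_example():
    t, df = moderated_t(b=1.0, v=0.25, s2=1.0, d=4,
                        prior=ModerationPrior(4.0, 1.0))
    assert t == pytest.approx(2.0)
    assert df == pytest.approx(8.0)


def test_zero_prior_df_recovers_ordinary_t(rng):
    s2 = rng.chisquare(4, size=50) / 4
    b = rng.normal(size=50)
    fits = _fits_from_arrays(b, 0.25, s2, 4)
    _, table = moderate_statistics(fits, prior=ModerationPrior(0.0, 1.0))
    ordinary = b / np.sqrt(s2 * 0.25)
    np.testing.assert_allclose(table["t_moderated"], ordinary, rtol=1e-12)


def test_identical_variances_hit_cap_and_shrink_to_themselves():
    fits = _fits_from_arrays(np.ones(40), 0.25, np.full(40, 0.7), 6)
    prior, table = moderate_statistics(fits)
    assert prior.d0 == diffexp.D0_CAP
    np.testing.assert_allclose(table["s2_posterior"], 0.7, rtol=1e-6)


def test_large_residual_df_approaches_ordinary_t(rng):
    d = 200
    s2 = rng.chisquare(d, size=200) / d
    b = rng.normal(size=200)
    fits = _fits_from_arrays(b, 0.25, s2, d)
    _, table = moderate_statistics(fits, prior=ModerationPrior(4.0, 1.0))
    ordinary = b / np.sqrt(s2 * 0.25)
    rel = np.abs(table["t_moderated"].to_numpy() - ordinary) / np.abs(ordinary)
    assert np.max(rel) < 0.01


def test_prior_recovery_moment_matching(rng):
    """estimate_prior recovers a known (d0, s0^2) from scaled-F variances."""
    d0_true, s0_true, d = 8.0, 0.5, 6
    n = 20000
    s2 = (s0_true * rng.chisquare(d, n) / d) / (rng.chisquare(d0_true, n)
                                                / d0_true)
    prior = estimate_prior(s2, np.full(n, float(d)))
    assert prior.d0 == pytest.approx(d0_true, rel=0.15)
    assert prior.s0_squared == pytest.approx(s0_true, rel=0.05)


# ---------------------------------------------------------------------------
# Holm / BH adjustment
# ---------------------------------------------------------------------------

def _holm_oracle(p):
    """Literal step-down definition, O(m^2)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank, i in enumerate(order):
        adj[i] = max(min(1.0, (m - j) * p[order[j]])
                     for j in range(rank + 1))
    return adj


def test_holm_hand_examples():
    np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]),
                               [0.03, 0.06, 0.06])
    np.testing.assert_allclose(holm_adjust([1.0, 1.0]), [1.0, 1.0])
    with pytest.raises(ValidationError):
        holm_adjust([0.5, 1.5])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=20))
def test_holm_matches_bruteforce_and_dominates_raw(p):
    adj = holm_adjust(p)
    np.testing.assert_allclose(adj, _holm_oracle(p), rtol=0, atol=1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-15)


def test_bh_is_statsmodels_equivalent_shape(rng):
    p = rng.uniform(size=100)
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert np.all(adj >= p - 1e-12)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _table(genes, sig):
    return pd.DataFrame({"gene_id": genes, "contrast": "c",
                         "p_holm": [0.01 if g in sig else 0.9
                                    for g in genes]})


def test_select_union_and_validation():
    genes = ["a", "b", "c"]
    sel = select_ari_genes([_table(genes, {"a", "b"}),
                            _table(genes, {"b", "c"}),
                            _table(genes, set())])
    assert sel == {"a", "b", "c"}
    assert select_ari_genes([_table(genes, set())]) == set()
    with pytest.raises(ValidationError):
        select_ari_genes([_table(genes, set()), _table(["a", "b"], set())])


def test_planted_genes_are_selected(small_cohort):
    """Power check: planted 1.5 log2 effects survive Holm selection."""
    _, expr, annot, truth = small_cohort
    design = build_design(annot)
    cc = estimate_consensus_correlation(expr, design)
    fits = fit_gene_models(expr, design, cc)
    _, table = moderate_statistics(fits)
    selected = select_ari_genes(table, alpha=0.05)
    planted = {g for g, lab in zip(truth.gene_ids, truth.labels)
               if lab != "null"}
    assert len(selected & planted) / len(planted) >= 0.95


# ---------------------------------------------------------------------------
# independent oracle: limma via Rscript
# ---------------------------------------------------------------------------

_R_EBAYES = textwrap.dedent("""
    suppressMessages(library(limma))
    args <- commandArgs(trailingOnly = TRUE)
    y <- as.matrix(read.delim(args[1], row.names = 1))
    X <- as.matrix(read.delim(args[2], row.names = 1))
    contrast <- scan(args[3], quiet = TRUE)
    fit <- lmFit(y, X)
    fit2 <- contrasts.fit(fit, contrast)
    fit2 <- eBayes(fit2)
    out <- data.frame(t = fit2$t[, 1], p = fit2$p.value[, 1],
                      d0 = fit2$df.prior, s0 = fit2$s2.prior)
    write.table(out, args[4], sep = "\\t", quote = FALSE)
""")


def test_moderated_t_matches_limma(tmp_path, small_cohort):
    """Our GLS + moderation pipeline reproduces limma's eBayes at rho = 0."""
    _, expr, annot, _ = small_cohort
    expr = expr.iloc[:120]
    design = build_design(annot)
    fits = fit_gene_models(expr, design, rho=0.0)
    prior, table = moderate_statistics(fits)
    ours = table[table["contrast"] == "D2-BL"].set_index("gene_id")

    ypath, xpath = tmp_path / "y.tsv", tmp_path / "X.tsv"
    cpath, opath = tmp_path / "c.txt", tmp_path / "out.tsv"
    expr.to_csv(ypath, sep="\t")
    pd.DataFrame(design.X, index=expr.columns,
                 columns=[f"c{i}" for i in range(design.X.shape[1])]
                 ).to_csv(xpath, sep="\t")
    np.savetxt(cpath, design.contrasts["D2-BL"])
    script = tmp_path / "ebayes.R"
    script.write_text(_R_EBAYES)
    subprocess.run(["Rscript", str(script), str(ypath), str(xpath),
                    str(cpath), str(opath)], check=True, capture_output=True)
    limma = pd.read_csv(opath, sep="\t")
    limma.index = expr.index

    np.testing.assert_allclose(ours["t_moderated"], limma["t"], rtol=1e-5)
    np.testing.assert_allclose(ours["p_raw"], limma["p"], rtol=1e-4, atol=1e-12)
    assert prior.d0 == pytest.approx(float(limma["d0"].iloc[0]), rel=0.05)
    assert prior.s0_squared == pytest.approx(float(limma["s0"].iloc[0]),
                                             rel=0.02)


_R_DUPCOR = textwrap.dedent("""
    suppressMessages(library(limma))
    args <- commandArgs(trailingOnly = TRUE)
    y <- as.matrix(read.delim(args[1], row.names = 1))
    X <- as.matrix(read.delim(args[2], row.names = 1))
    block <- scan(args[3], what = "", quiet = TRUE)
    dc <- duplicateCorrelation(y, X, block = block)
    cat(dc$consensus.correlation, file = args[4])
""")


def test_consensus_correlation_close_to_limma_reml(tmp_path):
    """Method-of-moments consensus tracks limma's REML duplicateCorrelation."""
    cfg = CohortConfig(n_genes=300, n_subjects_per_group=6,
                       n_core_d2=0, n_shared_d6=0, n_distinct_d6=0,
                       within_subject_rho=0.4, seed=77)
    expr, annot, _ = generate_expression(cfg)
    design = build_design(annot)
    ours = estimate_consensus_correlation(expr, design)

    ypath, xpath = tmp_path / "y.tsv", tmp_path / "X.tsv"
    bpath, opath = tmp_path / "block.txt", tmp_path / "rho.txt"
    expr.to_csv(ypath, sep="\t")
    pd.DataFrame(design.X, index=expr.columns,
                 columns=[f"c{i}" for i in range(design.X.shape[1])]
                 ).to_csv(xpath, sep="\t")
    bpath.write_text("\n".join(annot["subject_id"]))
    script = tmp_path / "dupcor.R"
    script.write_text(_R_DUPCOR)
    subprocess.run(["Rscript", str(script), str(ypath), str(xpath),
                    str(bpath), str(opath)], check=True, capture_output=True)
    reml = float(opath.read_text())
    assert ours.rho == pytest.approx(reml, abs=0.08)
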