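"""Blocked moderated differential expression over the three transitions.

Reads the cohort written by 01 (regenerating it if absent), estimates the
consensus within-subject correlation, fits the GLS cell-means model per
gene, moderates the variances and selects the illness-associated gene set
as the Holm < 0.05 union over the time-point contrasts.

Writes results/de/{contrast_table.tsv, ari_genes.txt, de_summary.tsv}.
"""

import os

from _common import COHORT, results_dir

from ari_profiles import diffexp, io
from ari_profiles.cohort import generate_expression


def load_cohort():
    cohort_dir = results_dir("cohort")
    ep = os.path.join(cohort_dir, "expression.tsv")
    ap = os.path.join(cohort_dir, "annotation.tsv")
    if os.path.exists(ep) and os.path.exists(ap):
        return io.read_expression_table(ep, ap)
    expr, annot, _ = generate_expression(COHORT)
    return expr, annot


def main() -> None:
    out = results_dir("de")
    expr, annot = load_cohort()
    design = diffexp.build_design(annot)
    consensus = diffexp.estimate_consensus_correlation(expr, design)
    fits = diffexp.fit_gene_models(expr, design, consensus)
    prior, table = diffexp.moderate_statistics(fits)
    ari = sorted(diffexp.select_ari_genes(table, alpha=0.05))

    table.to_csv(os.path.join(out, "contrast_table.tsv"), sep="\t",
                 index=False, float_format=io.FLOAT_FORMAT)
    with open(os.path.join(out, "ari_genes.txt"), "w") as fh:
        fh.write("".join(g + "\n" for g in ari))
    with open(os.path.join(out, "de_summary.tsv"), "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"consensus_rho\t{consensus.rho:.6g}\n")
        fh.write(f"prior_d0\t{prior.d0:.6g}\n")
        fh.write(f"prior_s0_squared\t{prior.s0_squared:.6g}\n")
        fh.write(f"n_ari_genes\t{len(ari)}\n")

    print(f"consensus within-subject correlation: {consensus.rho:.4f}")
    print(f"variance prior: d0 = {prior.d0:.1f}, s0^2 = {prior.s0_squared:.4f}")
    per_contrast = (table[table['p_holm'] < 0.05]
                    .groupby('contrast').size().sort_values(ascending=False))
    print("Holm-significant genes per contrast (top 5):")
    print(per_contrast.head().to_string())
    print(f"ARI gene set (union over contrasts): {len(ari)} genes -> {out}")


if __name__ == "__main__":
    main()
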