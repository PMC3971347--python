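"""Generate the synthetic study cohort: expression, annotation, diaries.

Writes results/cohort/{expression,annotation,planted_truth,clinical_*}.tsv
and reports the cohort dimensions and planted gene programme sizes.
"""

import os

import pandas as pd

from _common import COHORT, SEED, results_dir

from ari_profiles import io
from ari_profiles.cohort import ClinicalSimConfig, generate_clinical, generate_expression


def main() -> None:
    out = results_dir("cohort")
    expr, annot, truth = generate_expression(COHORT)
    io.write_expression_table(expr, annot,
                              os.path.join(out, "expression.tsv"),
                              os.path.join(out, "annotation.tsv"))
    truth.to_frame().to_csv(os.path.join(out, "planted_truth.tsv"),
                            sep="\t", index=False, float_format=io.FLOAT_FORMAT)
    series = generate_clinical(ClinicalSimConfig(seed=SEED), annot)
    io.write_clinical_tables(series,
                             os.path.join(out, "clinical_diary.tsv"),
                             os.path.join(out, "clinical_visits.tsv"))

    classes = pd.Series(truth.labels).value_counts()
    print(f"cohort: {expr.shape[0]} genes x {expr.shape[1]} samples "
          f"({len(annot['subject_id'].unique())} subjects, seed {SEED})")
    print("planted programmes:",
          ", ".join(f"{k}={v}" for k, v in classes.items() if k != "null"))
    print(f"clinical diaries for {len(series)} subjects "
          f"({sum(1 for s in series.values() if s.group == 'AsmEx')} planted "
          "exacerbations)")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
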