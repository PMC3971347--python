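"""Exacerbation adjudication of the synthetic diaries and the association
between exacerbation-signature expression change and airway obstruction.

Writes results/clinical/{exacerbation_calls.tsv, obstruction_association.tsv}
and prints the confusion against the planted verdicts.
"""

import os

import numpy as np
import pandas as pd

from _common import COHORT, SEED, results_dir

from ari_profiles import clinical as clin
from ari_profiles import io
from ari_profiles.cohort import ClinicalSimConfig, generate_clinical, generate_expression
from ari_profiles.evaluation import classify_cohort


def main() -> None:
    out = results_dir("clinical")
    expr, annot, _ = generate_expression(COHORT)
    series = generate_clinical(ClinicalSimConfig(seed=SEED), annot)

    calls = {sid: clin.classify_exacerbation(series[sid])
             for sid in sorted(series)}
    table = pd.DataFrame({
        "subject_id": list(calls),
        "group": [series[s].group for s in calls],
        "verdict": [c.verdict for c in calls.values()],
        "criterion_1": [c.criterion_1_met for c in calls.values()],
        "criterion_2": [c.criterion_2_met for c in calls.values()],
        "objective_changes": [",".join(sorted(c.objective_changes_met))
                              for c in calls.values()],
    })
    table.to_csv(os.path.join(out, "exacerbation_calls.tsv"), sep="\t",
                 index=False)
    planted = {s: series[s].group == "AsmEx" for s in calls}
    agree = sum(calls[s].verdict == planted[s] for s in calls)
    print(f"adjudicator agreement with planted truth: {agree}/{len(calls)}")
    print(table.groupby(["group", "verdict"]).size().to_string())

    # Spearman: mean exacerbation-signature change (D6 - D2) vs PEF drop
    membership, _, _ = classify_cohort(expr, annot, COHORT.group_names)
    tab = membership[("reduction", "D2")]
    sig = tab.loc[tab["class"] == "distinct:AsmEx", "gene_id"].tolist()
    rows = []
    for g in COHORT.group_names:
        deltas, obstruction = [], []
        for sid, s in series.items():
            if s.group != g:
                continue
            d2 = annot.index[(annot["subject_id"] == sid)
                             & (annot["timepoint"] == "D2")]
            d6 = annot.index[(annot["subject_id"] == sid)
                             & (annot["timepoint"] == "D6")]
            if len(d2) != 1 or len(d6) != 1:
                continue
            deltas.append(float(expr.loc[sig, d6[0]].mean()
                                - expr.loc[sig, d2[0]].mean()))
            best = float(np.max(s.baseline_pef))
            obstruction.append((float(np.min(s.illness_pef)) - best) / best)
        if len(deltas) >= 4:
            st = clin.spearman(deltas, obstruction)
            rows.append((g, len(deltas), st.statistic, st.pvalue))
    assoc = pd.DataFrame(rows, columns=["group", "n", "spearman_rs", "p"])
    assoc.to_csv(os.path.join(out, "obstruction_association.tsv"), sep="\t",
                 index=False, float_format=io.FLOAT_FORMAT)
    print(f"\nexacerbation-signature ({len(sig)} genes) change vs PEF drop:")
    print(assoc.round(3).to_string(index=False))
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
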