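"""Printed study-population counts and derived descriptive statistics.

The per-group participant counts of the source cohort (Healthy, allergic
rhinitis, asthma without exacerbation, asthma with exacerbation) ship with
the package as a small TSV so descriptive percentages can be recomputed
rather than restated.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

GROUP_ORDER = ("Healthy", "AllrgRhin", "AsmNoEx", "AsmEx")


def load_demographics() -> pd.DataFrame:
    """Per-group counts of the study population, indexed by variable."""
    with resources.files("ari_profiles").joinpath(
            "data/study_demographics.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def participant_percentages() -> pd.Series:
    """Per-group participant shares (percent), plus the total (100%)."""
    counts = load_demographics().loc["participants", list(GROUP_ORDER)]
    total = counts.sum()
    pct = (100.0 * counts / total).astype(float)
    pct["Total"] = 100.0 * total / total
    return pct
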