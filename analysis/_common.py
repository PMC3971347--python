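"""Shared configuration of the analysis drivers.

All drivers analyse the same deterministic synthetic cohort: the default
study conditions (4 groups x 8 subjects x 3 visits, 5,000 genes, planted
core/shared/distinct programmes at +/-1.5 log2 units, noise 0.5, within-
subject correlation 0.3) at seed 1. Outputs go under results/.
"""

from __future__ import annotations

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), os.pardir, "src"))

from ari_profiles.cohort import CohortConfig  # noqa: E402

SEED = 1
COHORT = CohortConfig(seed=SEED)
RESULTS = os.path.join(os.path.dirname(__file__), os.pardir, "results")


def results_dir(name: str) -> str:
    path = os.path.join(RESULTS, name)
    os.makedirs(path, exist_ok=True)
    return path
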