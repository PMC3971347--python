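"""Synthetic longitudinal nasal-transcriptome cohorts with planted signal.

The generator emulates the structure of a naturally-acquired cold study:
four clinical groups (Healthy, allergic rhinitis, asthma without and with
exacerbation), three matched visits per subject (asymptomatic baseline BL,
illness days D2 and D6), log2-scale expression with a subject-level random
intercept inducing a known within-subject correlation, and three planted
gene programmes with known ground truth:

* ``core_d2``     -- induced at D2 in every group (the shared innate response
                     at the peak of symptoms),
* ``shared_d6``   -- induced at D6 in three designated groups (the mucosal
                     repair programme absent in exacerbating asthmatics),
* ``distinct_d6`` -- perturbed at D6 in the exacerbation group only (the
                     exacerbation-specific signature).

Defaults are the cohort the downstream analyses are validated on:
4 x 8 subjects, 5,000 genes, 60/70/90 planted genes at +/-1.5 log2 units,
residual noise 0.5 log2 units, within-subject correlation 0.3.

Clinical diaries are generated alongside, constructed so that subjects
flagged as exacerbating satisfy criterion 2 of the a-priori definition
(symptom rise >=10 points for >=2 days plus one objective change) and
subjects flagged as non-exacerbating satisfy neither criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .clinical import ClinicalSeries
from .errors import ConfigurationError, UnknownSubjectError

DEFAULT_GROUPS = ("Healthy", "AllrgRhin", "AsmNoEx", "AsmEx")
DEFAULT_TIMEPOINTS = ("BL", "D2", "D6")
GENE_CLASSES = ("core_d2", "shared_d6", "distinct_d6", "null")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and noise parameters of the synthetic cohort."""

    n_genes: int = 5000
    n_subjects_per_group: int = 8
    group_names: tuple = DEFAULT_GROUPS
    timepoints: tuple = DEFAULT_TIMEPOINTS
    n_core_d2: int = 60
    core_d2_effect: float = 1.5          # log2 units, at D2 in all groups
    n_shared_d6: int = 70
    shared_d6_effect: float = 1.5        # log2 units, at D6 in shared_d6_groups
    shared_d6_groups: tuple = ("Healthy", "AllrgRhin", "AsmNoEx")
    n_distinct_d6: int = 90
    distinct_d6_effect: float = -1.5     # log2 units, at D6 in distinct group only
    distinct_d6_group: str = "AsmEx"
    noise_sd: float = 0.5                # residual SD, log2 units
    within_subject_rho: float = 0.3      # equicorrelation of repeat visits
    missing_visit_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_subjects_per_group < 2:
            raise ConfigurationError("need >=2 subjects per group")
        if len(set(self.group_names)) != len(self.group_names):
            raise ConfigurationError("duplicate group names")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ConfigurationError("duplicate time points")
        planted = self.n_core_d2 + self.n_shared_d6 + self.n_distinct_d6
        if planted > self.n_genes:
            raise ConfigurationError(
                f"planted sets overlap: {planted} planted genes exceed "
                f"the {self.n_genes}-gene universe")
        if not (0.0 <= self.within_subject_rho < 1.0):
            raise ConfigurationError("within_subject_rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not (0.0 <= self.missing_visit_prob < 1.0):
            raise ConfigurationError("missing_visit_prob must lie in [0, 1)")
        for g in self.shared_d6_groups:
            if g not in self.group_names:
                raise ConfigurationError(f"unknown shared group {g!r}")
        if self.distinct_d6_group not in self.group_names:
            raise ConfigurationError(
                f"unknown distinct group {self.distinct_d6_group!r}")
        if "D2" in self.timepoints and "BL" not in self.timepoints:
            raise ConfigurationError("BL time point required")


@dataclass
class PlantedTruth:
    """Ground-truth gene classes and (group x timepoint) offsets."""

    gene_ids: list
    labels: np.ndarray                # one of GENE_CLASSES per gene
    offsets: np.ndarray               # (n_genes, n_groups, n_timepoints), log2
    group_names: tuple
    timepoints: tuple

    def genes_in_class(self, label: str) -> list:
        if label not in GENE_CLASSES:
            raise ConfigurationError(f"unknown gene class {label!r}")
        return [g for g, lab in zip(self.gene_ids, self.labels) if lab == label]

    def to_frame(self) -> pd.DataFrame:
        cols = {"gene_id": self.gene_ids, "class": self.labels}
        for gi, g in enumerate(self.group_names):
            for ti, t in enumerate(self.timepoints):
                cols[f"offset_{g}_{t}"] = self.offsets[:, gi, ti]
        return pd.DataFrame(cols)


def generate_expression(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate the expression matrix, sample annotation and planted truth.

    Returns ``(expr, annotation, truth)`` where ``expr`` is a genes x samples
    log2 matrix, and ``annotation`` (indexed by sample id) carries subject,
    group, timepoint, a medication flag and a virus-detection flag.

    Noise model: per gene, value = baseline mean (uniform on [4, 14] log2)
    + planted offset + subject intercept + residual. The intercept variance
    is rho/(1-rho) * noise_sd**2, so repeat visits of one subject have
    equicorrelation rho, matching the blocked GLS the inference stage fits.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_plant, rng_means, rng_subj, rng_noise, rng_miss, rng_annot = (
        np.random.default_rng(s) for s in ss.spawn(6))

    n_g = config.n_genes
    groups, tps = config.group_names, config.timepoints
    width = len(str(n_g))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_g)]

    # planted classes: disjoint segments of one permutation
    labels = np.array(["null"] * n_g, dtype=object)
    perm = rng_plant.permutation(n_g)
    n_core, n_shared, n_dist = (config.n_core_d2, config.n_shared_d6,
                                config.n_distinct_d6)
    core_idx = perm[:n_core]
    shared_idx = perm[n_core:n_core + n_shared]
    dist_idx = perm[n_core + n_shared:n_core + n_shared + n_dist]
    labels[core_idx] = "core_d2"
    labels[shared_idx] = "shared_d6"
    labels[dist_idx] = "distinct_d6"

    offsets = np.zeros((n_g, len(groups), len(tps)))
    d2 = tps.index("D2") if "D2" in tps else None
    d6 = tps.index("D6") if "D6" in tps else None
    if d2 is not None:
        offsets[core_idx, :, d2] = config.core_d2_effect
    if d6 is not None:
        for g in config.shared_d6_groups:
            offsets[shared_idx, groups.index(g), d6] = config.shared_d6_effect
        offsets[dist_idx, groups.index(config.distinct_d6_group), d6] = (
            config.distinct_d6_effect)
    truth = PlantedTruth(gene_ids, labels, offsets, groups, tps)

    base = rng_means.uniform(4.0, 14.0, size=n_g)

    subjects = [(f"{g}_s{i:02d}", gi)
                for gi, g in enumerate(groups)
                for i in range(config.n_subjects_per_group)]
    sd_b = config.noise_sd * np.sqrt(
        config.within_subject_rho / (1.0 - config.within_subject_rho))
    intercepts = rng_subj.normal(0.0, sd_b, size=(n_g, len(subjects)))

    # retained subject-visits (missing visits drop the whole sample)
    keep = rng_miss.random((len(subjects), len(tps))) >= config.missing_visit_prob
    rows = []
    for si, (subj, gi) in enumerate(subjects):
        for ti, tp in enumerate(tps):
            if keep[si, ti]:
                rows.append((f"{subj}_{tp}", subj, si, gi, ti, tp))
    if not rows:
        raise ConfigurationError("all visits missing; nothing to simulate")

    sample_ids = [r[0] for r in rows]
    s_arr = np.array([r[2] for r in rows])
    g_arr = np.array([r[3] for r in rows])
    t_arr = np.array([r[4] for r in rows])

    noise = rng_noise.normal(0.0, config.noise_sd, size=(n_g, len(rows)))
    values = (base[:, None] + offsets[:, g_arr, t_arr]
              + intercepts[:, s_arr] + noise)
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=sample_ids)

    # subject-level annotation flags (descriptive only)
    med_p = {g: (0.6 if g.startswith("Asm") else 0.2 if g == "AllrgRhin" else 0.0)
             for g in groups}
    on_meds = {subj: bool(rng_annot.random() < med_p[groups[gi]])
               for subj, gi in subjects}
    virus = {subj: bool(rng_annot.random() < 0.6) for subj, _ in subjects}
    annotation = pd.DataFrame(
        {
            "subject_id": [r[1] for r in rows],
            "group": [groups[r[3]] for r in rows],
            "timepoint": [r[5] for r in rows],
            "on_meds": [on_meds[r[1]] for r in rows],
            "virus_detected": [virus[r[1]] for r in rows],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return expr, annotation, truth


# ---------------------------------------------------------------------------
# clinical diaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalSimConfig:
    """Diary/spirometry simulation settings (days, points, L/min, % predicted)."""

    baseline_week_length: int = 7
    illness_days: int = 10
    symptom_base: float = 15.0
    puff_base: float = 2.0
    pef_base: float = 450.0
    fev1_base: float = 95.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_week_length < 2:
            raise ConfigurationError("baseline week needs >=2 days")
        if self.illness_days < 7:
            raise ConfigurationError("illness window must cover D2 and D6")


def generate_clinical(
    config: ClinicalSimConfig,
    annotation: pd.DataFrame,
    planted_exacerbation: Mapping[str, bool] | None = None,
) -> dict[str, ClinicalSeries]:
    """Simulate per-subject diaries consistent with the planted verdicts.

    ``planted_exacerbation`` maps asthmatic subject ids to the intended
    adjudicator verdict; by default every subject of the ``AsmEx`` group is
    planted positive and every other subject negative. Positive subjects
    meet criterion 2 by construction (symptoms +12 points for 3 days plus
    one objective change, rotating between the albuterol, FEV1 and PEF
    branches); negative subjects are kept well inside every threshold.
    """
    config.validate()
    subj_info = (annotation[["subject_id", "group"]]
                 .drop_duplicates("subject_id").set_index("subject_id"))
    if planted_exacerbation is None:
        planted_exacerbation = {s: subj_info.loc[s, "group"] == "AsmEx"
                                for s in subj_info.index}
    for s in planted_exacerbation:
        if s not in subj_info.index:
            raise UnknownSubjectError(s)

    ss = np.random.SeedSequence(config.seed)
    series: dict[str, ClinicalSeries] = {}
    branch_cycle = ("albuterol", "fev1", "pef")
    planted_i = 0
    for s, child in zip(subj_info.index, ss.spawn(len(subj_info.index))):
        rng = np.random.default_rng(child)
        group = str(subj_info.loc[s, "group"])
        nb, ni = config.baseline_week_length, config.illness_days
        base_sym = config.symptom_base + rng.uniform(-1, 1, nb)
        base_puffs = np.clip(config.puff_base + rng.uniform(-0.2, 0.2, nb), 0, None)
        base_pef = config.pef_base + rng.uniform(-10, 10, nb)
        sym_mean = float(base_sym.mean())
        puff_mean = float(base_puffs.mean())
        best_pef = float(base_pef.max())

        ill_sym = sym_mean + rng.uniform(-1, 1, ni)
        ill_puffs = np.clip(puff_mean + rng.uniform(-0.2, 0.2, ni), 0, None)
        ill_pef = 0.95 * best_pef + rng.uniform(-5, 5, ni)
        fev1 = {"D2": 0.97 * config.fev1_base, "D6": 0.98 * config.fev1_base}

        positive = bool(planted_exacerbation.get(s, False))
        if positive:
            ill_sym[1:4] = sym_mean + 12.0 + rng.uniform(-1, 1, 3)
            branch = branch_cycle[planted_i % len(branch_cycle)]
            planted_i += 1
            if branch == "albuterol":
                ill_puffs[2:4] = puff_mean + 5.0 + rng.uniform(-0.2, 0.2, 2)
            elif branch == "fev1":
                fev1["D2"] = 0.85 * config.fev1_base
            else:  # pef
                ill_pef[2:4] = 0.75 * best_pef + rng.uniform(-3, 3, 2)
        else:
            # mild cold: symptom rise stays < 5 points, no objective change
            ill_sym[1:4] = sym_mean + 3.0 + rng.uniform(-1, 1, 3)

        series[s] = ClinicalSeries(
            subject_id=s, group=group,
            baseline_symptoms=base_sym, baseline_puffs=base_puffs,
            baseline_pef=base_pef,
            illness_symptoms=ill_sym, illness_puffs=ill_puffs,
            illness_pef=ill_pef,
            baseline_fev1=config.fev1_base, illness_fev1=fev1,
            eno={"BL": 20.0, "D2": 35.0, "D6": 30.0},
            care_seeking=False,
        )
    return series
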