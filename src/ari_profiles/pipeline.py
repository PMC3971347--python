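"""End-to-end orchestration of the illness-profile analysis.

Stage order follows the narrative of the study: consensus correlation ->
blocked GLS fits -> empirical-Bayes moderation and Holm selection of the
illness ("ARI") gene set -> all-sample covariance PCA -> per-group
transition PCAs with orientation and cluster-separation tests -> top-N
loading profiles at the focal time points (peak: D2; reduction: D2 and D6;
resolution: D6) -> core/shared/distinct membership -> kinetics scaling and
UPGMA clustering of the signature sets -> exacerbation adjudication and the
association between signature expression change and airway obstruction.

Every stage logs its outcome and registers its output files in the run
manifest. All data tables are byte-deterministic for a fixed configuration
and seed; the manifest itself carries a timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import clinical as clin
from . import diffexp, io, kinetics, pca
from .cohort import ClinicalSimConfig, CohortConfig, generate_clinical, generate_expression
from .errors import ConfigurationError
from .pca import STAGE_NAMES, STANDARD_TRANSITIONS

log = logging.getLogger("ari_profiles")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings: selection threshold, profile size, trim, seed."""

    alpha: float = 0.05        # Holm-adjusted significance threshold
    n_top: int = 100           # profile size N (top PC1 loadings)
    trim: float = 0.15         # consensus-correlation trim fraction per tail
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_top < 1:
            raise ConfigurationError("N must be >= 1")
        if not (0.0 <= self.trim < 0.5):
            raise ConfigurationError("trim must lie in [0, 0.5)")


_COHORT_KEYS = {f.name for f in dataclasses.fields(CohortConfig)}
_PIPELINE_KEYS = {"alpha", "n_top", "trim", "seed"}


def load_config(path: str) -> PipelineConfig:
    """Parse a flat key=value config file; unknown keys are errors."""
    pipe_kwargs: dict = {}
    cohort_kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in _PIPELINE_KEYS:
                pipe_kwargs[key] = value
            elif key in _COHORT_KEYS:
                cohort_kwargs[key] = value
            else:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")

    def convert(val: str, typ):
        if typ is int:
            return int(val)
        if typ is float:
            return float(val)
        if typ is tuple:
            return tuple(v.strip() for v in val.split(","))
        return val

    field_types = {f.name: f.type for f in dataclasses.fields(CohortConfig)}
    typed_cohort = {}
    for k, v in cohort_kwargs.items():
        t = {"int": int, "float": float, "tuple": tuple, "str": str}.get(
            str(field_types[k]), str)
        typed_cohort[k] = convert(v, t)
    typed_pipe = {}
    for k, v in pipe_kwargs.items():
        typed_pipe[k] = int(v) if k in ("n_top", "seed") else float(v)
    if "seed" in typed_pipe and "seed" not in typed_cohort:
        typed_cohort["seed"] = typed_pipe["seed"]
    return PipelineConfig(cohort=CohortConfig(**typed_cohort), **typed_pipe)


@dataclass
class RunManifest:
    """Config snapshot, stage statuses and output registry of one run."""

    config: dict
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def record(self, stage: str, status: str, **outputs) -> None:
        self.stages.append({"stage": stage, "status": status})
        self.outputs.update(outputs)
        log.info("stage %-22s %s", stage, status)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _write(df: pd.DataFrame, path: str, **kw) -> str:
    df.to_csv(path, sep="\t", float_format=io.FLOAT_FORMAT,
              index=kw.pop("index", False), **kw)
    return path


def run_pipeline(
    config: PipelineConfig,
    out_dir: str,
    expr: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    clinical_series: dict | None = None,
) -> RunManifest:
    """Run every analysis stage, writing tables under ``out_dir``.

    With no input tables supplied, a synthetic cohort is generated from
    ``config.cohort`` (including clinical diaries). An empty ARI selection
    aborts the PCA stages gracefully with a "skipped" status.
    """
    os.makedirs(out_dir, exist_ok=True)
    fh = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    manifest = RunManifest(
        config={"alpha": config.alpha, "n_top": config.n_top,
                "trim": config.trim, "seed": config.seed,
                "cohort": dataclasses.asdict(config.cohort)},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    try:
        _run_stages(config, out_dir, manifest, expr, annotation,
                    clinical_series)
    finally:
        with open(os.path.join(out_dir, "manifest.json"), "w") as out:
            out.write(manifest.to_json())
        log.removeHandler(fh)
        fh.close()
    return manifest


def _run_stages(config, out_dir, manifest, expr, annotation, clinical_series):
    join = lambda *p: os.path.join(out_dir, *p)

    # --- cohort -----------------------------------------------------------
    truth = None
    if expr is None or annotation is None:
        expr, annotation, truth = generate_expression(config.cohort)
        if clinical_series is None:
            clinical_series = generate_clinical(
                ClinicalSimConfig(seed=config.cohort.seed), annotation)
    io.write_expression_table(expr, annotation,
                              join("expression.tsv"), join("annotation.tsv"))
    outputs = {"expression": join("expression.tsv"),
               "annotation": join("annotation.tsv")}
    if truth is not None:
        _write(truth.to_frame(), join("planted_truth.tsv"))
        outputs["planted_truth"] = join("planted_truth.tsv")
    manifest.record("cohort", "complete", **outputs)

    # --- differential expression -----------------------------------------
    design = diffexp.build_design(annotation)
    consensus = diffexp.estimate_consensus_correlation(expr, design,
                                                       trim=config.trim)
    log.info("consensus within-subject correlation: %.4f", consensus.rho)
    fits = diffexp.fit_gene_models(expr, design, consensus)
    prior, table = diffexp.moderate_statistics(fits, alpha=config.alpha)
    _write(table, join("contrast_table.tsv"))
    ari_genes = sorted(diffexp.select_ari_genes(table, alpha=config.alpha))
    with open(join("ari_genes.txt"), "w") as out:
        out.write("".join(g + "\n" for g in ari_genes))
    with open(join("de_summary.tsv"), "w") as out:
        out.write("key\tvalue\n")
        out.write(f"consensus_rho\t{consensus.rho:.6g}\n")
        out.write(f"prior_d0\t{prior.d0:.6g}\n")
        out.write(f"prior_s0_squared\t{prior.s0_squared:.6g}\n")
        out.write(f"n_ari_genes\t{len(ari_genes)}\n")
    manifest.record("differential_expression", "complete",
                    contrast_table=join("contrast_table.tsv"),
                    ari_genes=join("ari_genes.txt"),
                    de_summary=join("de_summary.tsv"))

    if not ari_genes:
        log.warning("ARI gene set is empty at alpha=%g; "
                    "PCA stages skipped", config.alpha)
        for stage in ("pca_all", "pca_transitions", "signatures",
                      "kinetics", "clinical"):
            manifest.record(stage, "skipped (empty ARI set)")
        return

    ari_expr = expr.loc[ari_genes]

    # --- all-sample PCA ---------------------------------------------------
    pca_all = pca.run_covariance_pca(ari_expr)
    scores = pd.DataFrame(pca_all.scores[:, :3],
                          columns=["PC1", "PC2", "PC3"][:pca_all.scores.shape[1]],
                          index=pca_all.sample_ids)
    scores.insert(0, "sample_id", scores.index)
    _write(scores, join("pca_all_scores.tsv"))
    manifest.record("pca_all", "complete",
                    pca_all_scores=join("pca_all_scores.tsv"))

    # --- per-group transition PCAs, profiles, membership ------------------
    groups = list(config.cohort.group_names)
    sep_rows = []
    membership_tables: dict[tuple, pd.DataFrame] = {}
    profile_frames = []
    for spec in STANDARD_TRANSITIONS:
        stage_name = STAGE_NAMES[spec.timepoints]
        profiles_by_focal: dict[str, dict] = {f: {} for f in spec.focal}
        for g in groups:
            mask = (annotation["group"] == g) & (
                annotation["timepoint"].isin(spec.timepoints))
            samples = annotation.index[mask]
            sub = ari_expr[samples]
            res = pca.run_covariance_pca(sub)
            ref_samples = annotation.index[
                mask & (annotation["timepoint"] == spec.reference)]
            res = pca.orient_pc1(res, list(ref_samples))

            t0, t1 = spec.timepoints
            ann_sub = annotation.loc[samples]
            a_ids = ann_sub.index[ann_sub["timepoint"] == t0]
            b_ids = ann_sub.index[ann_sub["timepoint"] == t1]
            s = res.pc1_scores()
            subj = ann_sub["subject_id"]
            paired_subjects = sorted(set(subj[a_ids]) & set(subj[b_ids]))
            complete = (len(paired_subjects) == len(a_ids) == len(b_ids)
                        and len(paired_subjects) >= 2)
            if complete:
                a_sorted = a_ids[np.argsort(subj[a_ids].to_numpy())]
                b_sorted = b_ids[np.argsort(subj[b_ids].to_numpy())]
                stat = pca.test_pc1_separation(
                    s[a_sorted].to_numpy(), s[b_sorted].to_numpy(), paired=True)
            else:
                stat = pca.test_pc1_separation(
                    s[a_ids].to_numpy(), s[b_ids].to_numpy(), paired=False)
            sep_rows.append((stage_name, g, stat.name, stat.statistic,
                             stat.pvalue))

            for focal in spec.focal:
                focal_ids = ann_sub.index[ann_sub["timepoint"] == focal]
                prof = pca.select_loading_profile(
                    res, list(focal_ids), n_top=config.n_top,
                    group=g, focal_timepoint=focal)
                profiles_by_focal[focal][g] = prof
                pf = prof.to_frame()
                pf.insert(0, "stage", stage_name)
                pf.insert(1, "group", g)
                pf.insert(2, "focal_timepoint", focal)
                profile_frames.append(pf)

        for focal, profs in profiles_by_focal.items():
            membership = pca.classify_membership(profs)
            membership_tables[(stage_name, focal)] = membership
            _write(membership, join(f"membership_{stage_name}_{focal}.tsv"))
            _write(pca.venn_counts(membership),
                   join(f"venn_{stage_name}_{focal}.tsv"))

    _write(pd.DataFrame(sep_rows, columns=[
        "stage", "group", "test", "statistic", "pvalue"]),
        join("pc1_separation.tsv"))
    _write(pd.concat(profile_frames, ignore_index=True),
           join("signature_profiles.tsv"))
    manifest.record("pca_transitions", "complete",
                    pc1_separation=join("pc1_separation.tsv"))
    manifest.record(
        "signatures", "complete",
        signature_profiles=join("signature_profiles.tsv"),
        **{f"membership_{s}_{f}": join(f"membership_{s}_{f}.tsv")
           for (s, f) in membership_tables})

    # --- kinetics ---------------------------------------------------------
    traj = kinetics.compute_trajectories(ari_expr, annotation,
                                         groups=groups,
                                         timepoints=config.cohort.timepoints)
    scaled, _const = kinetics.minmax_scale_trajectories(traj)
    long = scaled.stack(["group", "timepoint"], future_stack=True).rename(
        "scaled_value").reset_index()
    _write(long, join("scaled_trajectories.tsv"))

    kin_outputs = {"scaled_trajectories": join("scaled_trajectories.tsv")}
    for (stage_name, focal), membership in membership_tables.items():
        sig_genes = membership["gene_id"].tolist()
        if len(sig_genes) < 2:
            continue
        spec = next(s for s in STANDARD_TRANSITIONS
                    if STAGE_NAMES[s.timepoints] == stage_name)
        fc = pd.concat(
            [kinetics.compute_fold_change(expr.loc[sig_genes], annotation, g,
                                          spec.timepoints) for g in groups],
            axis=1)
        dendro = kinetics.average_linkage_cluster(fc)
        path = join(f"dendrogram_{stage_name}_{focal}.tsv")
        _write(dendro.to_frame(), path)
        kin_outputs[f"dendrogram_{stage_name}_{focal}"] = path
    manifest.record("kinetics", "complete", **kin_outputs)

    # --- clinical ---------------------------------------------------------
    if clinical_series is None:
        manifest.record("clinical", "skipped (no clinical series)")
        return
    io.write_clinical_tables(clinical_series, join("clinical_diary.tsv"),
                             join("clinical_visits.tsv"))
    calls = [clin.classify_exacerbation(s) for s in (
        clinical_series[k] for k in sorted(clinical_series))]
    calls_df = pd.DataFrame({
        "subject_id": [c.subject_id for c in calls],
        "verdict": [c.verdict for c in calls],
        "criterion_1": [c.criterion_1_met for c in calls],
        "criterion_2": [c.criterion_2_met for c in calls],
        "objective_changes": [",".join(sorted(c.objective_changes_met))
                              for c in calls],
        "note": [c.note for c in calls],
    })
    _write(calls_df, join("exacerbation_calls.tsv"))

    # association of exacerbation-signature expression change with airway
    # obstruction change, per group (Spearman)
    assoc_rows = []
    distinct_set = membership_tables.get(("reduction", "D2"))
    sig = []
    if distinct_set is not None:
        sig = distinct_set.loc[distinct_set["class"].str.startswith("distinct:"),
                               "gene_id"].tolist()
    if sig:
        for g in groups:
            deltas, obstruction = [], []
            for sid, series in clinical_series.items():
                if series.group != g:
                    continue
                d2 = annotation.index[(annotation["subject_id"] == sid)
                                      & (annotation["timepoint"] == "D2")]
                d6 = annotation.index[(annotation["subject_id"] == sid)
                                      & (annotation["timepoint"] == "D6")]
                if len(d2) != 1 or len(d6) != 1:
                    continue
                deltas.append(float(expr.loc[sig, d6[0]].mean()
                                    - expr.loc[sig, d2[0]].mean()))
                best = float(np.max(series.baseline_pef))
                obstruction.append((float(np.min(series.illness_pef)) - best)
                                   / best)
            if len(deltas) >= 4 and np.ptp(deltas) > 0 and np.ptp(obstruction) > 0:
                st = clin.spearman(deltas, obstruction)
                assoc_rows.append((g, len(deltas), st.statistic, st.pvalue))
    _write(pd.DataFrame(assoc_rows, columns=[
        "group", "n_subjects", "spearman_rs", "pvalue"]),
        join("obstruction_association.tsv"))
    manifest.record("clinical", "complete",
                    exacerbation_calls=join("exacerbation_calls.tsv"),
                    obstruction_association=join("obstruction_association.tsv"))
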