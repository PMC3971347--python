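"""TSV dialects of the pipeline: expression, annotation, clinical tables.

All tables are plain tab-delimited text. The expression table has gene ids
in the first column and sample ids in the header; the annotation table maps
each sample id to subject, group, timepoint and the two boolean flags.
Writing then reading a table is the identity on canonical files, and output
is byte-deterministic ("%.10g" float formatting).
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .clinical import ClinicalSeries
from .errors import FormatError

FLOAT_FORMAT = "%.10g"
ANNOTATION_COLUMNS = ("subject_id", "group", "timepoint",
                      "on_meds", "virus_detected")


def write_expression_table(
    expr: pd.DataFrame, annotation: pd.DataFrame,
    expr_path: str, annot_path: str,
) -> None:
    expr.to_csv(expr_path, sep="\t", float_format=FLOAT_FORMAT,
                index_label="gene_id")
    annotation.to_csv(annot_path, sep="\t", index_label="sample_id")


def read_expression_table(
    expr_path: str, annot_path: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the expression and annotation tables.

    Raises ``FormatError`` for empty files, duplicate gene ids, non-numeric
    cells (named by row and column) and sample-id mismatches between the
    two files.
    """
    for path in (expr_path, annot_path):
        if not os.path.exists(path) or os.path.getsize(path) == 0:
            raise FormatError(f"empty or missing file: {path}")

    raw = pd.read_csv(expr_path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise FormatError(f"{expr_path}: no sample columns")
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{expr_path}: duplicate gene ids {dups[:5]}")
    try:
        expr = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                gene = raw.index[bad.to_numpy()][0]
                raise FormatError(
                    f"{expr_path}: non-numeric cell at gene {gene!r}, "
                    f"sample {col!r}") from None
        raise
    expr.index.name = "gene_id"

    annot = pd.read_csv(annot_path, sep="\t", index_col=0)
    missing_cols = [c for c in ("subject_id", "group", "timepoint")
                    if c not in annot.columns]
    if missing_cols:
        raise FormatError(f"{annot_path}: missing columns {missing_cols}")
    annot.index.name = "sample_id"

    expr_samples = list(expr.columns)
    annot_samples = set(annot.index.astype(str))
    for s in expr_samples:
        if s not in annot_samples:
            raise FormatError(f"sample {s!r} missing from annotation")
    extra = annot_samples - set(expr_samples)
    if extra:
        raise FormatError(
            f"annotation samples absent from expression: {sorted(extra)[:5]}")
    annot = annot.loc[expr_samples]
    return expr, annot


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def write_clinical_tables(
    series: Mapping[str, ClinicalSeries],
    diary_path: str, visit_path: str,
) -> None:
    """Write the per-day diary table and the per-visit spirometry table."""
    diary_rows = []
    visit_rows = []
    for sid in sorted(series):
        s = series[sid]
        for phase, sym, puffs, pef in (
                ("baseline", s.baseline_symptoms, s.baseline_puffs,
                 s.baseline_pef),
                ("illness", s.illness_symptoms, s.illness_puffs,
                 s.illness_pef)):
            for day in range(len(sym)):
                diary_rows.append((sid, s.group, phase, day,
                                   sym[day], puffs[day], pef[day],
                                   int(s.care_seeking)))
        visit_rows.append((sid, "BL", s.baseline_fev1,
                           (s.eno or {}).get("BL", "")))
        for visit, fev1 in sorted(s.illness_fev1.items()):
            visit_rows.append((sid, visit, fev1, (s.eno or {}).get(visit, "")))
    pd.DataFrame(diary_rows, columns=[
        "subject_id", "group", "phase", "day_index", "symptom_score",
        "puffs", "pef", "care_seeking"]).to_csv(
            diary_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    pd.DataFrame(visit_rows, columns=[
        "subject_id", "visit", "fev1", "eno"]).to_csv(
            visit_path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_clinical_tables(
    diary_path: str, visit_path: str,
) -> dict[str, ClinicalSeries]:
    diary = pd.read_csv(diary_path, sep="\t")
    visits = pd.read_csv(visit_path, sep="\t")
    out: dict[str, ClinicalSeries] = {}
    for sid, d in diary.groupby("subject_id"):
        base = d[d["phase"] == "baseline"].sort_values("day_index")
        ill = d[d["phase"] == "illness"].sort_values("day_index")
        v = visits[visits["subject_id"] == sid].set_index("visit")
        if "BL" not in v.index:
            raise FormatError(f"subject {sid!r}: no baseline visit row")
        eno = {visit: float(row["eno"]) for visit, row in v.iterrows()
               if pd.notna(row.get("eno", np.nan)) and row.get("eno", "") != ""}
        out[str(sid)] = ClinicalSeries(
            subject_id=str(sid), group=str(d["group"].iloc[0]),
            baseline_symptoms=base["symptom_score"].to_numpy(),
            baseline_puffs=base["puffs"].to_numpy(),
            baseline_pef=base["pef"].to_numpy(),
            illness_symptoms=ill["symptom_score"].to_numpy(),
            illness_puffs=ill["puffs"].to_numpy(),
            illness_pef=ill["pef"].to_numpy(),
            baseline_fev1=float(v.loc["BL", "fev1"]),
            illness_fev1={visit: float(v.loc[visit, "fev1"])
                          for visit in v.index if visit != "BL"},
            eno=eno or None,
            care_seeking=bool(d["care_seeking"].iloc[0]),
        )
    return out
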