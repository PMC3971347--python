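"""Optional GEO series-matrix import (never required by the pipeline).

The study's microarray data are deposited in the Gene Expression Omnibus
under a GSE accession; this module can parse a series-matrix file into the
pipeline's expression/annotation tables, and can download one when network
access is available. Nothing else in the package depends on it and no test
exercises the network path.
"""

from __future__ import annotations

import gzip
import re
import warnings

import pandas as pd

from .errors import FetchError, ValidationError

_ACCESSION_RE = re.compile(r"^GSE\d+$")


def parse_series_matrix(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a GEO series-matrix text file.

    Returns ``(expr, annotation)``; annotation holds the sample titles and
    any ``!Sample_characteristics_ch1`` lines as ``characteristics_<i>``
    columns (empty, with a warning, when the file carries none).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    meta: dict[str, list] = {}
    table_lines: list[str] = []
    in_table = False
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key = line.split("\t", 1)[0]
                vals = [v.strip('"') for v in line.split("\t")[1:]]
                meta.setdefault(key, []).append(vals)
    if not table_lines:
        raise FetchError(f"{path}: no series_matrix table found")

    header = [h.strip('"') for h in table_lines[0].split("\t")]
    rows = [ln.split("\t") for ln in table_lines[1:] if ln]
    expr = pd.DataFrame(
        [[r[0].strip('"')] + [float(x) if x not in ("", "null", "NA") else float("nan")
                              for x in r[1:]] for r in rows],
        columns=header).set_index(header[0])
    expr.index.name = "gene_id"

    sample_ids = list(expr.columns)
    annot = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    titles = meta.get("!Sample_title")
    if titles:
        annot["title"] = titles[0][:len(sample_ids)]
    chars = meta.get("!Sample_characteristics_ch1")
    if chars:
        for i, vals in enumerate(chars):
            annot[f"characteristics_{i}"] = vals[:len(sample_ids)]
    else:
        warnings.warn("no sample-characteristics lines; annotation fields empty",
                      stacklevel=2)
    return expr, annot


def fetch_geo_series(accession: str, dest_dir: str = ".") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Download and parse a GEO series matrix (requires network access)."""
    if not _ACCESSION_RE.match(accession or ""):
        raise ValidationError(f"malformed GEO accession {accession!r}")
    import os
    import urllib.request

    stub = accession[:-3] + "nnn"
    url = (f"https://ftp.ncbi.nlm.nih.gov/geo/series/{stub}/{accession}/matrix/"
           f"{accession}_series_matrix.txt.gz")
    target = os.path.join(dest_dir, f"{accession}_series_matrix.txt.gz")
    try:
        urllib.request.urlretrieve(url, target)
    except Exception as exc:  # pragma: no cover - network path
        raise FetchError(f"download of {accession} failed: {exc}") from exc
    return parse_series_matrix(target)
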