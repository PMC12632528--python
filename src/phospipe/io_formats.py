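"""Readers and writers for every file format the pipeline touches.

Long reports and tidy result tables are TSV, design manifests CSV,
kinase-substrate maps TSV or GMT, ground truth and signatures JSON.
Column names follow canonical lower-snake conventions with an alias
table accepting Spectronaut-style report headers (``PG.ProteinGroups``,
``EG.ModifiedSequence``, ``EG.PTMAssayProbability``, ``R.FileName`` ...).

Missing values are written as empty fields and read back from empty or
``NaN`` fields, so tables survive spreadsheet round-trips.  All writers
emit stable row orderings (feature id, then sample id, lexicographic)
so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from phospipe.containers import (
    FormatError,
    IntensityMatrix,
    ManifestMismatchError,
)

logger = logging.getLogger(__name__)

SITE_KEY_RE = re.compile(r"^\S+_[STY]\d+$")

#: Spectronaut-style (v18-v20) and other common header aliases.
COLUMN_ALIASES = {
    "R.FileName": "sample_id",
    "R.Label": "sample_id",
    "PG.ProteinGroups": "protein_group",
    "PG.ProteinAccessions": "protein_group",
    "PEP.StrippedSequence": "stripped_sequence",
    "EG.ModifiedSequence": "modified_sequence",
    "EG.PrecursorId": "modified_sequence",
    "EG.PTMAssayProbability": "localization_probability",
    "EG.PTMLocalizationProbabilities": "localization_probability",
    "EG.TotalQuantity (Settings)": "intensity",
    "FG.Quantity": "intensity",
    "PTM.SiteKey": "site_key",
}

REPORT_REQUIRED = ["sample_id", "protein_group", "modified_sequence", "intensity"]
REPORT_COLUMNS = REPORT_REQUIRED + [
    "stripped_sequence", "site_key", "localization_probability", "is_phospho",
]

DESIGN_REQUIRED = ["sample_id", "genotype", "donor", "replicate",
                   "treatment", "dose", "timepoint", "assay", "cell_type"]


def _read_table(path, sep):
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None


def read_long_report(path) -> pd.DataFrame:
    """Read a long-format DIA report (TSV), normalizing header dialects.

    Rows with missing, non-numeric or non-positive intensity are dropped
    with a logged count.  Unknown columns are ignored.
    """
    raw = _read_table(path, sep="\t")
    raw = raw.rename(columns=COLUMN_ALIASES)
    missing = [c for c in REPORT_REQUIRED if c not in raw.columns]
    if missing:
        raise FormatError(
            f"long report {path} missing required column(s): {', '.join(missing)}"
        )
    report = pd.DataFrame(index=raw.index)
    for col in ("sample_id", "protein_group", "stripped_sequence",
                "modified_sequence", "site_key"):
        report[col] = raw[col] if col in raw.columns else ""
    report["localization_probability"] = (
        pd.to_numeric(raw.get("localization_probability", np.nan),
                      errors="coerce")
        if "localization_probability" in raw.columns else np.nan
    )
    intensity = pd.to_numeric(raw["intensity"], errors="coerce")
    keep = intensity.notna() & (intensity > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_long_report: dropped %d row(s) with missing or "
                    "non-positive intensity", n_dropped)
    report["intensity"] = intensity
    if "is_phospho" in raw.columns:
        report["is_phospho"] = raw["is_phospho"].str.lower().isin(
            ("true", "1", "yes", "t")
        )
    else:
        report["is_phospho"] = report["site_key"].astype(str) != ""
    report = report[keep].reset_index(drop=True)
    bad_p = report["localization_probability"].dropna()
    if ((bad_p < 0) | (bad_p > 1)).any():
        raise FormatError("localization probabilities outside [0, 1]")
    return report[REPORT_COLUMNS]


def write_long_report(report: pd.DataFrame, path) -> None:
    out = report.copy()
    out = out.sort_values(
        ["sample_id", "protein_group", "modified_sequence"], kind="stable"
    )
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_design(path) -> pd.DataFrame:
    """Read a sample design manifest (CSV)."""
    raw = _read_table(path, sep=",")
    missing = [c for c in DESIGN_REQUIRED if c not in raw.columns]
    if missing:
        raise FormatError(
            f"design {path} missing required column(s): {', '.join(missing)}"
        )
    d = raw.copy()
    for col in ("dose", "timepoint", "cell_input"):
        if col in d.columns:
            d[col] = pd.to_numeric(d[col], errors="coerce")
    d["replicate"] = pd.to_numeric(d["replicate"], errors="raise").astype(int)
    if d["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in design manifest")
    if "cell_input" not in d.columns:
        d["cell_input"] = np.nan
    return d


def write_design(design: pd.DataFrame, path) -> None:
    design.sort_values("sample_id", kind="stable").to_csv(
        path, index=False, na_rep=""
    )


def pivot_to_matrix(
    report: pd.DataFrame, design: pd.DataFrame, level: str = "protein"
) -> IntensityMatrix:
    """Pivot a long report into a feature x sample intensity matrix.

    Protein level sums precursor intensities per (protein, sample); site
    level first collapses precursors per (sample, site_key) by the
    maximum-intensity rule (see :func:`phospipe.preprocess.collapse_to_sites`).
    Absent measurements become NaN, never zero.  Columns cover every
    design sample in sorted order.
    """
    unknown = set(report["sample_id"]) - set(design["sample_id"])
    if unknown:
        raise ManifestMismatchError(
            "report references sample(s) absent from design: "
            + ", ".join(sorted(unknown)[:5])
        )
    if level == "protein":
        feature_col = "protein_group"
        agg = (report.groupby([feature_col, "sample_id"], sort=True)["intensity"]
               .sum())
    elif level == "site":
        from phospipe.preprocess import collapse_to_sites
        collapsed = collapse_to_sites(report)
        phospho = collapsed[collapsed["is_phospho"]]
        feature_col = "site_key"
        agg = (phospho.groupby([feature_col, "sample_id"], sort=True)["intensity"]
               .max())
    else:
        raise ValueError(f"unknown level {level!r}")
    mat = agg.unstack("sample_id")
    mat = mat.reindex(
        index=sorted(mat.index),
        columns=sorted(design["sample_id"]),
    )
    meta = _feature_meta(mat.index, level, design["assay"].iloc[0])
    return IntensityMatrix(mat, "linear", meta)


def _feature_meta(features, level, assay) -> pd.DataFrame:
    rows = []
    for f in features:
        if level == "site" and SITE_KEY_RE.match(str(f)):
            prot, _, respos = str(f).rpartition("_")
            rows.append({"protein": prot, "residue": respos[0],
                         "position": int(respos[1:]), "assay": assay})
        else:
            rows.append({"protein": str(f), "residue": "",
                         "position": -1, "assay": assay})
    return pd.DataFrame(rows, index=pd.Index(features, name="feature_id"))


def read_kinase_substrate_map(path) -> dict[str, set[str]]:
    """Read a kinase -> substrate-site annotation (TSV or GMT).

    TSV needs columns ``kinase`` plus either ``site_key`` or
    ``protein`` + ``site`` (residue letter and 1-based position, e.g.
    ``Y701``).  GMT rows are ``kinase<TAB>description<TAB>site_key...``.
    Duplicate pairs are deduplicated; malformed site keys raise a
    format error naming the line.
    """
    path = str(path)
    if path.endswith(".gmt"):
        return _read_ks_gmt(path)
    return _read_ks_tsv(path)


def _check_site_key(sk: str, lineno: int, path: str) -> str:
    if not SITE_KEY_RE.match(sk):
        raise FormatError(f"{path}:{lineno}: malformed site key {sk!r}")
    return sk


def _read_ks_gmt(path) -> dict[str, set[str]]:
    ks: dict[str, set[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"empty file: {path}")
    for i, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{i}: GMT row needs name, "
                              "description and >=1 member")
        kinase, members = parts[0], parts[2:]
        sites = {_check_site_key(m, i, path) for m in members if m}
        ks.setdefault(kinase, set()).update(sites)
    return {k: v for k, v in ks.items() if v}


def _read_ks_tsv(path) -> dict[str, set[str]]:
    tab = _read_table(path, sep="\t")
    if "kinase" not in tab.columns:
        raise FormatError(f"{path}: missing required column: kinase")
    ks: dict[str, set[str]] = {}
    for i, row in enumerate(tab.itertuples(index=False), start=2):
        d = row._asdict()
        if "site_key" in d and d["site_key"]:
            sk = d["site_key"]
        elif "protein" in d and "site" in d:
            sk = f"{d['protein']}_{d['site']}"
        else:
            raise FormatError(
                f"{path}: need site_key or protein+site columns"
            )
        ks.setdefault(d["kinase"], set()).add(_check_site_key(sk, i, path))
    return ks


def write_kinase_substrate_map(ks_map: dict[str, set[str]], path) -> None:
    rows = [{"kinase": k, "site_key": s}
            for k in sorted(ks_map) for s in sorted(ks_map[k])]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_matrix(path, scale: str) -> IntensityMatrix:
    """Read a feature x sample matrix (TSV, first column feature id)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if raw.empty and raw.columns.empty:
        raise FormatError(f"empty file: {path}")
    return IntensityMatrix(raw.astype(float), scale)


def write_matrix(matrix: IntensityMatrix, path, header_lines=()) -> None:
    out = matrix.values.reindex(
        index=sorted(matrix.features), columns=sorted(matrix.samples)
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", na_rep="", index_label="feature_id")
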