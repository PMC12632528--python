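"""Site collapse, localization and replicate-presence filtering,
normalization, and sample-level quality-control metrics.

The preprocessing contract mirrors standard DIA phosphoproteomics
practice: precursors are collapsed to one record per (sample, phosphosite)
by maximum intensity, sites are kept only when confidently localized
(Class I, localization probability strictly above 0.75), features must be
quantified in enough replicates of at least one condition, and intensities
are log2-transformed and median-centered per sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phospipe.containers import (
    ConfigError,
    DesignError,
    FormatError,
    IntensityMatrix,
    condition_table,
)

logger = logging.getLogger(__name__)

CLASS1_THRESHOLD = 0.75


def collapse_to_sites(report: pd.DataFrame) -> pd.DataFrame:
    """Collapse precursor records to one record per (sample, phosphosite).

    Intensity and localization probability are each the maximum over the
    contributing precursors — an order-independent rule.  Non-phospho
    records pass through unchanged.
    """
    phospho = report[report["is_phospho"]]
    rest = report[~report["is_phospho"]]
    if (phospho["site_key"].astype(str) == "").any():
        raise FormatError("phospho record lacking a site key")
    collapsed = (
        phospho.groupby(["sample_id", "site_key"], as_index=False, sort=True)
        .agg(
            protein_group=("protein_group", "first"),
            stripped_sequence=("stripped_sequence", "first"),
            modified_sequence=("modified_sequence", "first"),
            localization_probability=("localization_probability", "max"),
            intensity=("intensity", "max"),
        )
    )
    collapsed["is_phospho"] = True
    out = pd.concat([collapsed, rest], ignore_index=True)
    return out[report.columns.intersection(out.columns).tolist()
               + [c for c in out.columns if c not in report.columns]]


def filter_class1(report: pd.DataFrame,
                  threshold: float = CLASS1_THRESHOLD) -> pd.DataFrame:
    """Keep phosphosite records with localization probability strictly
    greater than ``threshold`` (Class I).  The boundary is strict: a
    probability exactly at the threshold is dropped."""
    keep = ~report["is_phospho"] | (
        report["localization_probability"] > threshold
    )
    return report[keep].reset_index(drop=True)


def _resolve_rule(min_present, n_cond: int) -> int:
    """Turn a (k, n) pair, bare integer or fraction into a required count."""
    if isinstance(min_present, tuple):
        return int(min_present[0])
    if isinstance(min_present, float) and 0 < min_present <= 1:
        return max(1, math.ceil(min_present * n_cond))
    return int(min_present)


def filter_by_replicates(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    min_present=(3, 4),
) -> IntensityMatrix:
    """Keep features quantified in at least ``k`` replicates of at least
    one condition.

    A condition is a (genotype, treatment, dose, timepoint, cell_type)
    cell of the design.  ``min_present`` is an integer pair ``(k, n)``,
    a bare integer ``k``, or a fraction of the condition's samples.
    """
    d = condition_table(design, matrix.samples)
    if d.empty:
        raise DesignError("no design samples present in the matrix")
    observed = matrix.mask
    keep = pd.Series(False, index=matrix.features)
    for cond, grp in d.groupby("condition", sort=False):
        cols = grp["sample_id"].tolist()
        if not cols:
            raise DesignError(f"condition {cond} has no samples")
        k = _resolve_rule(min_present, len(cols))
        keep |= observed[cols].sum(axis=1) >= k
    out = matrix.values.loc[keep]
    meta = (None if matrix.feature_meta is None
            else matrix.feature_meta.loc[keep])
    logger.info("filter_by_replicates: kept %d/%d features",
                int(keep.sum()), len(keep))
    return IntensityMatrix(out, matrix.scale, meta)


def normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Log2-transform and median-center each sample column.

    Linear input is log2-transformed first; log2 input is only
    re-centered, which makes the operation idempotent.  Each column is
    shifted so the median of its observed values is zero; missing entries
    are untouched.  All-missing columns pass through with a warning.
    """
    # linear-scale positivity is enforced by the IntensityMatrix contract
    logged = matrix.to_log2() if matrix.scale == "linear" else matrix.copy()
    values = logged.values
    medians = values.median(axis=0, skipna=True)
    empty = medians.isna()
    if empty.any():
        logger.warning("normalize: %d all-missing column(s) left unchanged",
                       int(empty.sum()))
    centered = values.sub(medians.fillna(0.0), axis=1)
    return IntensityMatrix(centered, "log2", logged.feature_meta)


@dataclass
class QCBundle:
    """Quality-control metrics of a run.

    ``enrichment_purity``: per-sample fraction of phospho precursors;
    ``localized_site_count``: per-sample Class-I site count;
    ``cv``: per-(feature, condition) coefficient of variation on linear
    intensities; ``replicate_correlation``: Pearson r per within-condition
    sample pair on log2 intensities over mutually observed features;
    ``linearity``: per-feature Pearson r of linear intensity vs cell
    input (features observed at >= 3 input levels), or None when the
    design carries no cell input.
    """

    enrichment_purity: pd.Series
    localized_site_count: pd.Series
    cv: pd.DataFrame
    replicate_correlation: pd.DataFrame
    linearity: pd.Series | None


def qc_metrics(
    report: pd.DataFrame,
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    include_linearity: bool | None = None,
) -> QCBundle:
    """Compute the QC bundle for a processed run.

    ``include_linearity=True`` without ``cell_input`` in the design raises
    a configuration error; ``None`` auto-detects.
    """
    purity = (report.groupby("sample_id")["is_phospho"].mean()
              .rename("enrichment_purity"))
    class1 = report[report["is_phospho"]
                    & (report["localization_probability"] > CLASS1_THRESHOLD)]
    site_count = (class1.groupby("sample_id")["site_key"].nunique()
                  .reindex(purity.index, fill_value=0)
                  .rename("localized_site_count"))

    linear = matrix.to_linear().values
    log2v = matrix.to_log2().values
    d = condition_table(design, matrix.samples)

    cv_rows = []
    corr_rows = []
    for cond, grp in d.groupby("condition", sort=False):
        cols = grp["sample_id"].tolist()
        sub = linear[cols]
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        cv = sd / mean
        cv_rows.append(pd.DataFrame({
            "feature_id": matrix.features,
            "condition": [cond] * len(matrix.features),
            "cv": cv.to_numpy(),
        }))
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                a, b = log2v[cols[i]], log2v[cols[j]]
                both = a.notna() & b.notna()
                r = (a[both].corr(b[both]) if both.sum() >= 3 else np.nan)
                corr_rows.append({"sample_a": cols[i], "sample_b": cols[j],
                                  "condition": cond, "pearson_r": r})
    cv_frame = (pd.concat(cv_rows, ignore_index=True).dropna(subset=["cv"])
                if cv_rows else pd.DataFrame(columns=["feature_id",
                                                      "condition", "cv"]))
    corr_frame = pd.DataFrame(corr_rows)

    has_input = ("cell_input" in design.columns
                 and design["cell_input"].notna().any())
    if include_linearity is True and not has_input:
        raise ConfigError("linearity requested but design has no cell_input")
    want_linearity = has_input if include_linearity is None else include_linearity
    linearity = _input_linearity(linear, design) if want_linearity else None

    return QCBundle(purity, site_count, cv_frame, corr_frame, linearity)


def _input_linearity(linear: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Per-feature Pearson r of linear intensity vs cell input amount."""
    d = design[design["sample_id"].isin(linear.columns)]
    d = d[d["cell_input"].notna()]
    inputs = d.set_index("sample_id")["cell_input"]
    out = {}
    for f in linear.index:
        row = linear.loc[f, inputs.index]
        obs = row.notna()
        levels = inputs[obs]
        if levels.nunique() < 3:
            continue
        out[f] = float(np.corrcoef(row[obs], levels)[0, 1])
    return pd.Series(out, name="linearity_r", dtype=float)
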