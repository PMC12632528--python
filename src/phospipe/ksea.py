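"""Kinase-substrate enrichment analysis (KSEA) and substrate coverage.

Kinase activity is inferred from the fold changes of a kinase's
annotated substrate sites relative to the whole-dataset background:

    z = (mean(FC substrates) - mean(FC all sites)) * sqrt(m) / sd(FC all sites)

where m is the number of quantified substrates.  Two-sided p-values come
from the standard normal; BH adjustment is applied across kinases within
each comparison.  Kinases with fewer than ``min_substrates`` quantified
substrates are omitted (not reliably quantifiable) and logged.
Substrate matching is exact on site key.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from phospipe.containers import ConfigError
from phospipe.differential import COMPARISON_KEYS, bh_adjust

logger = logging.getLogger(__name__)


def ksea_z(
    diff: pd.DataFrame,
    ks_map: dict[str, set[str]],
    min_substrates: int = 3,
) -> pd.DataFrame:
    """Mean-based KSEA z-scores per kinase per comparison.

    ``diff`` is a differential table over phosphosites (feature ids are
    site keys).  The background is the fold-change distribution over all
    quantified sites of the comparison, substrates included.
    """
    keys = [k for k in COMPARISON_KEYS if k in diff.columns]
    rows = []
    for cond, grp in (diff.groupby(keys, sort=True) if keys
                      else [((), diff)]):
        grp = grp[np.isfinite(grp["log2fc"])]
        fcs = grp.set_index("feature_id")["log2fc"]
        bg_mean = float(fcs.mean())
        bg_sd = float(fcs.std(ddof=1))
        for kinase in sorted(ks_map):
            quantified = sorted(ks_map[kinase] & set(fcs.index))
            m = len(quantified)
            if m < min_substrates:
                logger.info("ksea_z: kinase %s not quantifiable "
                            "(%d < %d substrates)", kinase, m, min_substrates)
                continue
            sub_mean = float(fcs.loc[quantified].mean())
            z = (sub_mean - bg_mean) * np.sqrt(m) / bg_sd
            p = float(2.0 * stats.norm.sf(abs(z)))
            row = {"kinase": kinase, "z": float(z),
                   "p_value": max(p, np.finfo(float).tiny),
                   "m": m, "mean_substrate_fc": sub_mean,
                   "background_mean": bg_mean, "background_sd": bg_sd}
            for key, val in zip(keys, cond if isinstance(cond, tuple) else (cond,)):
                row[key] = val
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["kinase", "z", "p_value", "adj_p", "m",
                                     "mean_substrate_fc", "background_mean",
                                     "background_sd"] + keys)
    out = pd.DataFrame(rows)
    out["adj_p"] = np.nan
    for _, idx in out.groupby(keys, sort=False).groups.items() if keys else [
        (None, out.index)
    ]:
        out.loc[idx, "adj_p"] = bh_adjust(out.loc[idx, "p_value"])
    return out


def substrate_coverage(
    detections: dict[str, set[str]],
    ks_map: dict[str, set[str]],
    reference: str | None = None,
) -> pd.DataFrame:
    """Absolute and relative substrate coverage per kinase per condition.

    ``detections`` maps a condition label to the set of site keys
    detected there.  Relative coverage divides by the count in the
    ``reference`` condition (capped at 1 for display); without a
    reference only absolute counts are returned.
    """
    if reference is not None and reference not in detections:
        raise ConfigError(f"reference condition {reference!r} not among "
                          "detections")
    rows = []
    for cond in sorted(detections):
        detected = set(detections[cond])
        for kinase in sorted(ks_map):
            count = len(ks_map[kinase] & detected)
            row = {"condition": cond, "kinase": kinase, "count": count}
            if reference is not None:
                ref_count = len(ks_map[kinase] & set(detections[reference]))
                row["relative_coverage"] = (
                    min(count / ref_count, 1.0) if ref_count else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
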