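"""Differential abundance statistics.

Donor centering, time-matched log2 fold changes, pooled Student's t
tests, empirical-Bayes moderated t statistics with variance shrinkage,
and Benjamini-Hochberg adjustment applied per comparison.

The moderated statistic follows the standard hierarchical model for
feature-wise residual variances: ``s_g^2 | sigma_g^2 ~
sigma_g^2 * chi^2_{d_g} / d_g`` with a scaled inverse-chi-square prior
``1/sigma_g^2 ~ chi^2_{d0} / (d0 * s0^2)``.  The prior degrees of
freedom ``d0`` and prior variance ``s0^2`` are estimated by method of
moments on ``log s_g^2`` via digamma/trigamma inversion; the posterior
variance ``s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` replaces the
sample variance in the t statistic, which is then referred to a t
distribution with ``d0 + d_g`` degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from phospipe.containers import DesignError, IntensityMatrix, ScaleError

logger = logging.getLogger(__name__)

VEHICLE = "vehicle"

COMPARISON_KEYS = ["genotype", "treatment", "dose", "timepoint"]


def center_by_donor(
    matrix: IntensityMatrix, design: pd.DataFrame
) -> IntensityMatrix:
    """Subtract each donor's per-feature mean (batch centering).

    Removes additive donor offsets while leaving every within-donor
    treated-minus-control contrast unchanged.  With fewer than two donors
    this is the identity.
    """
    if matrix.scale != "log2":
        raise ScaleError("donor centering requires a log2-scale matrix")
    d = design[design["sample_id"].isin(matrix.samples)]
    donors = d["donor"].unique()
    if len(donors) < 2:
        return matrix.copy()
    values = matrix.values.copy()
    for donor, grp in d.groupby("donor", sort=False):
        cols = grp["sample_id"].tolist()
        means = values[cols].mean(axis=1, skipna=True)
        values[cols] = values[cols].sub(means.fillna(0.0), axis=0)
    return IntensityMatrix(values, "log2", matrix.feature_meta)


def comparison_groups(
    design: pd.DataFrame,
    samples,
    vehicle_label: str = VEHICLE,
) -> list[dict]:
    """Enumerate treated-vs-time-matched-vehicle comparisons.

    Each treated (genotype, treatment, dose, timepoint) condition is
    paired with the vehicle condition sharing genotype, timepoint and
    cell type.  A treated condition without its matched vehicle raises a
    design error naming the condition.
    """
    d = design[design["sample_id"].isin(samples)]
    treated = d[d["treatment"] != vehicle_label]
    vehicle = d[d["treatment"] == vehicle_label]
    out = []
    for cond, grp in treated.groupby(COMPARISON_KEYS, sort=True):
        genotype, treatment, dose, timepoint = cond
        ctrl = vehicle[
            (vehicle["genotype"] == genotype)
            & (vehicle["timepoint"] == timepoint)
        ]
        if "cell_type" in d.columns:
            ctrl = ctrl[ctrl["cell_type"].isin(grp["cell_type"])]
        if ctrl.empty:
            raise DesignError(
                f"no time-matched vehicle for condition genotype={genotype}, "
                f"treatment={treatment}, dose={dose}, timepoint={timepoint}"
            )
        out.append({
            "genotype": genotype, "treatment": treatment,
            "dose": dose, "timepoint": timepoint,
            "treated_samples": sorted(grp["sample_id"]),
            "control_samples": sorted(ctrl["sample_id"]),
        })
    return out


def fold_change_vs_control(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    vehicle_label: str = VEHICLE,
) -> pd.DataFrame:
    """Per-feature log2 fold change of each treated condition against its
    time-matched vehicle: mean(log2 treated) - mean(log2 vehicle)."""
    if matrix.scale != "log2":
        raise ScaleError("fold changes require a log2-scale matrix")
    rows = []
    for cmp_ in comparison_groups(design, matrix.samples, vehicle_label):
        t = matrix.values[cmp_["treated_samples"]].mean(axis=1, skipna=True)
        c = matrix.values[cmp_["control_samples"]].mean(axis=1, skipna=True)
        frame = pd.DataFrame({
            "feature_id": matrix.features,
            "log2fc": (t - c).to_numpy(),
        })
        for key in COMPARISON_KEYS:
            frame[key] = cmp_[key]
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def student_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided pooled-variance (Student's) t test.

    Degenerate zero-variance inputs: equal means give (0, 1); unequal
    means give a signed infinite t with p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        logger.warning("student_t: zero pooled variance with unequal means")
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


@dataclass
class VariancePrior:
    """Empirical-Bayes variance prior: degrees of freedom and scale."""

    d0: float
    s0_2: float


def fit_variance_prior(s2, df) -> VariancePrior:
    """Method-of-moments fit of (d0, s0^2) from feature variances.

    Uses the exact moments of ``log s_g^2`` under the hierarchical model:
    ``E[log s^2] = log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) +
    log(d0/2)`` and ``Var[log s^2] = trigamma(d/2) + trigamma(d0/2)``.
    When the observed spread of log variances does not exceed its
    sampling expectation the prior is degenerate (d0 = inf): every
    feature shares s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, d / 2.0).mean()
    if excess <= 0:
        return VariancePrior(d0=np.inf, s0_2=float(np.exp(emean)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return VariancePrior(d0=float(d0), s0_2=float(s0_2))


def moderate_variances(s2, df, prior: VariancePrior) -> np.ndarray:
    """Posterior (shrunken) variances given the fitted prior."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(prior.d0):
        return np.full_like(s2, prior.s0_2)
    if prior.d0 == 0:
        return s2.copy()
    return (prior.d0 * prior.s0_2 + df * s2) / (prior.d0 + df)


def moderated_t(
    log2fc,
    s2,
    df,
    stderr_scale,
    prior: VariancePrior | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t statistics for a set of features.

    Parameters
    ----------
    log2fc, s2, df
        Per-feature effect estimate, pooled residual variance, and
        residual degrees of freedom.
    stderr_scale
        Per-feature sqrt(1/nA + 1/nB) (or the design-appropriate
        standard-error multiplier).
    prior
        Optional override of the fitted prior, e.g. for the
        moderation-free (d0=0) or complete-shrinkage (d0=inf) limits.

    Returns a frame with t, p, posterior variance, and the prior used.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    stderr_scale = np.broadcast_to(np.asarray(stderr_scale, dtype=float), s2.shape)
    if prior is None:
        prior = fit_variance_prior(s2, df)
    s2_post = moderate_variances(s2, df, prior)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / (np.sqrt(s2_post) * stderr_scale)
    df_total = prior.d0 + df
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    # zero posterior variance: degenerate, mirror student_t conventions
    degenerate = s2_post == 0
    t = np.where(degenerate & (log2fc == 0), 0.0, t)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(degenerate & (log2fc != 0), 0.0, p)
    return pd.DataFrame({
        "t": t, "p": p, "s2_post": s2_post,
        "d0": prior.d0, "s0_2": prior.s0_2,
    })


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    engine: str = "moderated",
    vehicle_label: str = VEHICLE,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Full differential analysis: one row per feature per comparison.

    For each treated-vs-time-matched-vehicle comparison, computes log2FC,
    the chosen t statistic (pooled Student or empirical-Bayes moderated),
    raw p, and BH-adjusted p within the comparison.  Features observed in
    fewer than ``min_per_group`` samples of either side are reported with
    NaN statistics and excluded from the BH universe.
    """
    if engine not in ("student", "moderated"):
        raise ValueError(f"unknown engine {engine!r}")
    if matrix.scale != "log2":
        raise ScaleError("differential analysis requires a log2-scale matrix")
    frames = []
    for cmp_ in comparison_groups(design, matrix.samples, vehicle_label):
        tcols, ccols = cmp_["treated_samples"], cmp_["control_samples"]
        tv = matrix.values[tcols].to_numpy(dtype=float)
        cv = matrix.values[ccols].to_numpy(dtype=float)
        n_t = (~np.isnan(tv)).sum(axis=1)
        n_c = (~np.isnan(cv)).sum(axis=1)
        ok = (n_t >= min_per_group) & (n_c >= min_per_group)

        tmean = np.nanmean(np.where(np.isnan(tv), np.nan, tv), axis=1)
        cmean = np.nanmean(np.where(np.isnan(cv), np.nan, cv), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tvar = _nanvar(tv)
            cvar = _nanvar(cv)
            df = n_t + n_c - 2
            s2 = ((n_t - 1) * tvar + (n_c - 1) * cvar) / df
            stderr_scale = np.sqrt(1.0 / n_t + 1.0 / n_c)
        fc = tmean - cmean

        t_stat = np.full(len(matrix.features), np.nan)
        p = np.full(len(matrix.features), np.nan)
        if ok.any():
            if engine == "student":
                with np.errstate(divide="ignore", invalid="ignore"):
                    tt = fc / (np.sqrt(s2) * stderr_scale)
                pp = 2.0 * stats.t.sf(np.abs(tt), df)
                zero = s2 == 0
                tt = np.where(zero & (fc == 0), 0.0, tt)
                pp = np.where(zero & (fc == 0), 1.0, pp)
                pp = np.where(zero & (fc != 0), 0.0, pp)
                t_stat[ok] = tt[ok]
                p[ok] = pp[ok]
            else:
                mod = moderated_t(fc[ok], s2[ok], df[ok], stderr_scale[ok])
                t_stat[ok] = mod["t"].to_numpy()
                p[ok] = mod["p"].to_numpy()
        adj = np.full(len(matrix.features), np.nan)
        usable = ok & np.isfinite(p) & (p > 0) & (p <= 1)
        # p == 0 can arise only from degenerate zero-variance contrasts;
        # keep them maximally significant after adjustment
        adj[usable] = bh_adjust(p[usable])
        adj[ok & (p == 0)] = 0.0

        frame = pd.DataFrame({
            "feature_id": matrix.features,
            "log2fc": fc,
            "t_statistic": t_stat,
            "p_value": p,
            "adj_p": adj,
            "n_treated": n_t,
            "n_control": n_c,
        })
        for key in COMPARISON_KEYS:
            frame[key] = cmp_[key]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _nanvar(x: np.ndarray) -> np.ndarray:
    """Row-wise sample variance ignoring NaN (ddof=1; NaN when < 2 obs)."""
    n = (~np.isnan(x)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=1)
        ss = np.nansum((x - mean[:, None]) ** 2, axis=1)
        return np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
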