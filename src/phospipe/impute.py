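"""Mechanism-aware missing-value imputation.

Missing entries are first classified by the partially-observed-value /
missing-in-entire-condition convention: a gap in a condition block with
at least one observed replicate is treated as missing at random (MAR); a
block that is entirely missing while the feature is quantified elsewhere
is treated as missing not at random (MNAR, i.e. below the detection
limit in that condition).  MAR gaps are filled by feature-space kNN
(global proteomics) or by SLSA — the replicate mean plus a sample-level
offset (phosphoproteomics); MNAR gaps are filled by downshift sampling
from a left-shifted, narrowed normal per sample column.

All imputation operates on log2-scale matrices and never alters an
observed entry.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from phospipe.containers import IntensityMatrix, ScaleError, condition_table

logger = logging.getLogger(__name__)

OBSERVED, MAR, MNAR = "observed", "MAR", "MNAR"


def _require_log2(matrix: IntensityMatrix) -> None:
    if matrix.scale != "log2":
        raise ScaleError("imputation requires a log2-scale matrix")


def classify_missingness(
    matrix: IntensityMatrix, design: pd.DataFrame
) -> pd.DataFrame:
    """Label every matrix entry as observed, MAR or MNAR.

    Within each feature x condition block: gaps are MAR when >= 1
    replicate of the block is observed, MNAR when the block is entirely
    missing.
    """
    _require_log2(matrix)
    d = condition_table(design, matrix.samples)
    labels = pd.DataFrame(OBSERVED, index=matrix.features,
                          columns=matrix.samples, dtype=object)
    observed = matrix.mask
    for _, grp in d.groupby("condition", sort=False):
        cols = grp["sample_id"].tolist()
        block_obs = observed[cols]
        n_obs = block_obs.sum(axis=1)
        gap = ~block_obs
        block_labels = np.where(
            gap,
            np.where((n_obs > 0).to_numpy()[:, None], MAR, MNAR),
            OBSERVED,
        )
        labels.loc[:, cols] = block_labels
    return labels


def _nan_euclidean(values: np.ndarray, min_shared: int) -> np.ndarray:
    """Pairwise feature distances over mutually observed samples.

    Squared differences over shared samples, rescaled by
    ``n_samples / n_shared`` (the nan-Euclidean convention) so distances
    over few shared coordinates are comparable to complete ones.  Pairs
    sharing fewer than ``min_shared`` samples get infinite distance.
    """
    mask = (~np.isnan(values)).astype(float)
    x0 = np.where(np.isnan(values), 0.0, values)
    shared = mask @ mask.T
    sq = x0 ** 2
    d2 = sq @ mask.T + mask @ sq.T - 2.0 * (x0 @ x0.T)
    n = values.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(shared >= min_shared, d2 * n / shared, np.inf)
    np.fill_diagonal(d2, np.inf)
    return np.sqrt(np.maximum(d2, 0.0))


def impute_knn(
    matrix: IntensityMatrix,
    mask: pd.DataFrame,
    k: int = 10,
    min_shared: int = 3,
) -> IntensityMatrix:
    """Fill MAR gaps by k-nearest-neighbour features.

    For each feature with MAR gaps, neighbours are the k features nearest
    by nan-Euclidean distance (>= ``min_shared`` mutually observed
    samples) among features observed in the gap's sample; the imputed
    value is the mean of the neighbours' observed values there.  With
    fewer than k candidates all are used (warned); with none the gap is
    left missing (warned).
    """
    _require_log2(matrix)
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.values.to_numpy(dtype=float).copy()
    marmask = (mask.to_numpy() == MAR) & np.isnan(values)
    if not marmask.any():
        return matrix.copy()
    dist = _nan_euclidean(matrix.values.to_numpy(dtype=float), min_shared)
    observed = ~np.isnan(matrix.values.to_numpy(dtype=float))
    short, empty = 0, 0
    for g in np.flatnonzero(marmask.any(axis=1)):
        order = np.argsort(dist[g], kind="stable")
        finite = order[np.isfinite(dist[g][order])]
        for j in np.flatnonzero(marmask[g]):
            cand = finite[observed[finite, j]]
            if cand.size == 0:
                empty += 1
                continue
            if cand.size < k:
                short += 1
            neighbors = cand[:k]
            values[g, j] = matrix.values.to_numpy(dtype=float)[neighbors, j].mean()
    if short:
        logger.warning("impute_knn: %d gap(s) had fewer than k=%d "
                       "candidate neighbours", short, k)
    if empty:
        logger.warning("impute_knn: %d gap(s) had no candidate neighbours "
                       "and were left missing", empty)
    out = pd.DataFrame(values, index=matrix.features, columns=matrix.samples)
    return IntensityMatrix(out, "log2", matrix.feature_meta)


def impute_slsa(
    matrix: IntensityMatrix,
    mask: pd.DataFrame,
    design: pd.DataFrame,
) -> IntensityMatrix:
    """Fill MAR gaps by replicate mean plus a sample-level offset.

    For a gap at (feature g, sample j) the imputed value is the mean of
    g's observed replicates in j's condition, plus offset(j): the median,
    over features fully observed in the condition block, of the value in
    j minus the mean of that feature's other replicates.  The offset
    captures systematic sample-level intensity shifts; a single-sample
    condition gets offset 0 with a warning.  Deterministic.
    """
    _require_log2(matrix)
    d = condition_table(design, matrix.samples)
    values = matrix.values.to_numpy(dtype=float).copy()
    marmask = (mask.to_numpy() == MAR) & np.isnan(values)
    if not marmask.any():
        return matrix.copy()
    col_index = {s: i for i, s in enumerate(matrix.samples)}
    for _, grp in d.groupby("condition", sort=False):
        cols = [col_index[s] for s in grp["sample_id"]]
        block = matrix.values.to_numpy(dtype=float)[:, cols]
        obs = ~np.isnan(block)
        full = obs.all(axis=1)
        nblock = len(cols)
        for jj, j in enumerate(cols):
            gaps = np.flatnonzero(marmask[:, j])
            if gaps.size == 0:
                continue
            if nblock == 1:
                offset = 0.0
                logger.warning("impute_slsa: single-sample condition, "
                               "offset set to 0")
            elif full.any():
                others = [c for c in range(nblock) if c != jj]
                deltas = block[full, jj] - block[full][:, others].mean(axis=1)
                offset = float(np.median(deltas))
            else:
                offset = 0.0
            for g in gaps:
                row = block[g]
                repmean = np.nanmean(np.delete(row, jj)) if nblock > 1 else np.nan
                if np.isnan(repmean):
                    continue  # MNAR-like block, not SLSA's job
                values[g, j] = repmean + offset
    out = pd.DataFrame(values, index=matrix.features, columns=matrix.samples)
    return IntensityMatrix(out, "log2", matrix.feature_meta)


def impute_downshift(
    matrix: IntensityMatrix,
    mask: pd.DataFrame,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> IntensityMatrix:
    """Fill MNAR gaps by downshift sampling.

    Per sample column with observed mean mu and standard deviation sigma,
    each MNAR gap is drawn from Normal(mu - shift*sigma, (width*sigma)^2)
    — the conventional left-shifted, narrowed distribution emulating
    values below the detection limit.  Columns with fewer than two
    observed values fall back to the global mean and sd with a warning.
    Deterministic given ``seed``.
    """
    _require_log2(matrix)
    if width < 0:
        raise ValueError("width must be >= 0")
    rng = np.random.default_rng(seed)
    values = matrix.values.to_numpy(dtype=float).copy()
    mnarmask = (mask.to_numpy() == MNAR) & np.isnan(values)
    if not mnarmask.any():
        return matrix.copy()
    obs_all = values[~np.isnan(values)]
    global_mu = float(obs_all.mean()) if obs_all.size else 0.0
    global_sd = float(obs_all.std(ddof=1)) if obs_all.size > 1 else 0.0
    for j in range(values.shape[1]):
        gaps = np.flatnonzero(mnarmask[:, j])
        if gaps.size == 0:
            continue
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            mu, sd = global_mu, global_sd
            logger.warning("impute_downshift: column %d has <2 observed "
                           "values; using global moments", j)
        else:
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        values[gaps, j] = rng.normal(mu - shift * sd, width * sd, size=gaps.size)
    out = pd.DataFrame(values, index=matrix.features, columns=matrix.samples)
    return IntensityMatrix(out, "log2", matrix.feature_meta)


def impute_mixed(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    mode: str = "phospho",
    k: int = 10,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Classify gaps and apply the matched imputation per mechanism.

    MAR gaps are filled by kNN (``mode='global'``) or SLSA
    (``mode='phospho'``); MNAR gaps by downshift sampling.  Returns the
    completed matrix and the missingness labels.
    """
    if mode not in ("global", "phospho"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = classify_missingness(matrix, design)
    if mode == "global":
        step1 = impute_knn(matrix, labels, k=k)
    else:
        step1 = impute_slsa(matrix, labels, design)
    step2 = impute_downshift(step1, labels, shift=shift, width=width, seed=seed)
    return step2, labels
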