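"""Shared in-memory containers and the package error hierarchy.

The pipeline's canonical tabular containers are plain :class:`pandas.DataFrame`
objects (long reports, design manifests, differential tables).  The one
structure that needs more than a frame is the feature-by-sample intensity
matrix, which carries a scale flag (linear vs log2) that the numeric
stages depend on; it is wrapped in :class:`IntensityMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PhospipeError(Exception):
    """Base class for all errors raised by this package."""


class InvalidDesignError(PhospipeError):
    """Design enumeration parameters are out of range."""


class FormatError(PhospipeError):
    """An input file does not conform to the expected schema."""


class ManifestMismatchError(PhospipeError):
    """A report references samples absent from the design manifest."""


class AnnotationMismatchError(PhospipeError):
    """Kinase-substrate annotations reference unknown features."""


class ScaleError(PhospipeError):
    """Matrix values are inconsistent with the declared intensity scale."""


class DesignError(PhospipeError):
    """The design manifest cannot support the requested computation."""


class ConfigError(PhospipeError):
    """A requested computation lacks required configuration or metadata."""


#: Sample-level columns that jointly define an experimental condition.
#: Replicates (and donors) of one condition share all of these.
CONDITION_KEYS = ["genotype", "treatment", "dose", "timepoint", "cell_type"]


@dataclass
class IntensityMatrix:
    """Feature x sample intensity matrix with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (protein id or site key) with one
        column per sample id.  ``NaN`` encodes a missing measurement —
        never zero.
    scale
        ``"linear"`` (raw, strictly positive) or ``"log2"``
        (log2-transformed; values may be non-positive).
    feature_meta
        Optional per-feature metadata (protein, residue, position, assay),
        indexed like ``values``.
    """

    values: pd.DataFrame
    scale: str
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ScaleError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise FormatError("duplicate feature ids in intensity matrix")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids in intensity matrix")
        if self.scale == "linear":
            vals = self.values.to_numpy(dtype=float)
            observed = vals[~np.isnan(vals)]
            if observed.size and (observed <= 0).any():
                raise ScaleError(
                    "linear-scale matrix contains non-positive intensities"
                )

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where a value is observed."""
        return self.values.notna()

    def copy(self) -> "IntensityMatrix":
        meta = None if self.feature_meta is None else self.feature_meta.copy()
        return IntensityMatrix(self.values.copy(), self.scale, meta)

    def to_log2(self) -> "IntensityMatrix":
        """Return a log2-scale copy (identity if already log2)."""
        if self.scale == "log2":
            return self.copy()
        meta = None if self.feature_meta is None else self.feature_meta.copy()
        return IntensityMatrix(np.log2(self.values), "log2", meta)

    def to_linear(self) -> "IntensityMatrix":
        if self.scale == "linear":
            return self.copy()
        meta = None if self.feature_meta is None else self.feature_meta.copy()
        return IntensityMatrix(2.0 ** self.values, "linear", meta)


def condition_table(design: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Group a design manifest by experimental condition.

    Returns the design restricted to ``samples`` (if given) with a
    ``condition`` column holding a hashable condition key tuple.
    """
    d = design if samples is None else design[design["sample_id"].isin(samples)]
    d = d.copy()
    keys = [k for k in CONDITION_KEYS if k in d.columns]
    d["condition"] = list(zip(*(d[k] for k in keys)))
    return d
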