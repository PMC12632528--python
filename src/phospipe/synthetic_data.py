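"""Synthetic perturbation-phosphoproteomics data generator.

Emulates the statistical structure of a DIA knockout screen: log-normal
precursor intensities, treatment-induced fold changes organised by
kinase-substrate membership (fast, phospho-level) and by an induced
protein set (slow, abundance-level, an interferon-stimulated-gene
analog), genotype-dependent pathway ablation, additive donor batch
effects, and a mixture of intensity-dependent (MNAR) and uniform (MAR)
dropout.  Every draw is deterministic given the ground-truth seed, and
the generator returns its own truth structure so downstream recovery is
directly checkable.

Generative model (log2 scale), for feature *f* in sample *s*::

    x[f, s] = b[f] + treated(s) * effect(f, s) * ablation[genotype(s)]
              + donor_offset[donor(s), f] + noise[f, s]

with ``b[f] ~ Normal(baseline_mean, baseline_sd)``,
``donor_offset ~ Normal(0, donor_sigma)`` constant across a donor's
samples, and ``noise ~ Normal(0, noise_sigma)`` i.i.d.  Reported linear
intensities are ``2**x``.  Induced-set effects apply only in treated
samples at timepoints at or past the induction onset; kinase effects
apply to annotated substrate sites at every treated timepoint.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from phospipe.containers import (
    AnnotationMismatchError,
    IntensityMatrix,
    InvalidDesignError,
    condition_table,
)

logger = logging.getLogger(__name__)

VEHICLE = "vehicle"


@dataclass
class GroundTruth:
    """True effect structure underlying a simulated dataset.

    Parameters
    ----------
    induced_set
        Protein/feature id -> log2 effect size for the stimulation-induced
        set (the simulated ISG analog).
    active_kinases
        Kinase name -> log2 activity effect applied to its substrates in
        treated samples.
    ablation_map
        Genotype -> multiplier in [0, 1] scaling all pathway effects in
        that genotype (0 = full pathway knockout, 1 = intact).  Genotypes
        not listed default to 1.
    donor_sigma, noise_sigma
        Standard deviations (log2 units) of the per-(donor, feature)
        offset and the residual noise.
    mnar_params
        ``(midpoint, slope)`` of the decreasing logistic dropout curve on
        log2 intensity.  A steep slope approximates a hard detection
        limit.
    mar_rate
        Uniform missing-at-random dropout probability.
    induction_onset
        Minutes; induced-set effects apply only at timepoints >= onset.
    ambiguous_fraction
        Fraction of phosphosites drawn as poorly localized
        (Beta(2, 2) localization probability) rather than confidently
        localized (Beta(9, 1)).
    """

    induced_set: dict[str, float] = field(default_factory=dict)
    active_kinases: dict[str, float] = field(default_factory=dict)
    ablation_map: dict[str, float] = field(default_factory=dict)
    donor_sigma: float = 0.5
    noise_sigma: float = 0.5
    mnar_params: tuple[float, float] = (17.0, 8.0)
    mar_rate: float = 0.05
    induction_onset: float = 240.0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    ambiguous_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for g, m in self.ablation_map.items():
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"ablation multiplier for {g!r} outside [0, 1]")
        if not (0.0 <= self.mar_rate <= 1.0):
            raise ValueError("mar_rate outside [0, 1]")
        if not (0.0 <= self.ambiguous_fraction <= 1.0):
            raise ValueError("ambiguous_fraction outside [0, 1]")
        for name, val in (("donor_sigma", self.donor_sigma),
                          ("noise_sigma", self.noise_sigma)):
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
        for eff in list(self.induced_set.values()) + list(self.active_kinases.values()):
            if not math.isfinite(eff):
                raise ValueError("effect sizes must be finite")
        self.mnar_params = (float(self.mnar_params[0]), float(self.mnar_params[1]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["mnar_params"] = tuple(d["mnar_params"])
        return cls(**d)


def generate_design(
    n_knockouts: int,
    n_controls: int,
    n_replicates: int,
    timepoints: list[float],
    include_vehicle: bool = True,
    donors: list[str] | None = None,
    assay: str = "phospho",
    treatment: str = "IFN-b",
    dose: float = 100.0,
    cell_type: str = "CD4T",
    cell_input: float | None = None,
) -> pd.DataFrame:
    """Enumerate a full perturbation-screen design manifest.

    One sample per (genotype, timepoint, replicate, arm) where the arms
    are the treatment and — if ``include_vehicle`` — a time-matched
    vehicle control in the same genotype and donor.  Total sample count is
    ``(n_knockouts + n_controls) * n_replicates * len(timepoints) *
    (2 if include_vehicle else 1)``.

    Replicates are assigned to donors round-robin, so every donor carries
    matched treated/vehicle pairs at every timepoint.
    """
    if n_knockouts < 0 or n_controls < 0 or n_knockouts + n_controls < 1:
        raise InvalidDesignError("need at least one genotype (knockout or control)")
    if n_replicates < 1:
        raise InvalidDesignError("n_replicates must be >= 1")
    if not timepoints:
        raise InvalidDesignError("timepoints must be non-empty")
    if assay not in ("global", "phospho"):
        raise InvalidDesignError(f"unknown assay {assay!r}")
    if donors is None:
        donors = ["donor1", "donor2"]

    genotypes = [f"KO{i + 1:02d}" for i in range(n_knockouts)]
    genotypes += [f"scramble{i + 1}" for i in range(n_controls)]
    arms = [(treatment, dose)]
    if include_vehicle:
        arms.append((VEHICLE, 0.0))

    rows = []
    for genotype in genotypes:
        for tp in timepoints:
            for rep in range(1, n_replicates + 1):
                donor = donors[(rep - 1) % len(donors)]
                for arm_treatment, arm_dose in arms:
                    sid = f"{genotype}.{arm_treatment}.t{tp:g}.{donor}.r{rep}"
                    rows.append({
                        "sample_id": sid,
                        "genotype": genotype,
                        "donor": donor,
                        "replicate": rep,
                        "treatment": arm_treatment,
                        "dose": arm_dose,
                        "timepoint": float(tp),
                        "cell_input": np.nan if cell_input is None else cell_input,
                        "assay": assay,
                        "cell_type": cell_type,
                    })
    design = pd.DataFrame(rows)
    assert design["sample_id"].is_unique
    return design


def _feature_table(n_features, truth, ks_map, assay, rng):
    """Assign feature ids: induced-set proteins, kinase substrates, filler.

    Phospho features are site keys ``PROT_<S|T|Y><pos>``; global features
    are plain protein ids.  Substrate site keys from ``ks_map`` are used
    verbatim so the annotation matches the simulated report.
    """
    substrate_sites: list[str] = []
    site_to_kinases: dict[str, list[str]] = {}
    if ks_map:
        for kinase, sites in ks_map.items():
            for s in sorted(sites):
                if s not in site_to_kinases:
                    site_to_kinases[s] = []
                    substrate_sites.append(s)
                site_to_kinases[s].append(kinase)

    induced = sorted(truth.induced_set)
    reserved = len(induced) + len(substrate_sites)
    if n_features < reserved:
        raise AnnotationMismatchError(
            f"n_features={n_features} cannot host {len(induced)} induced "
            f"features plus {len(substrate_sites)} annotated substrates"
        )

    rows = []
    for sk in substrate_sites:
        prot, _, respos = sk.rpartition("_")
        rows.append({"feature_id": sk, "protein": prot or sk,
                     "is_phospho": True, "kinases": site_to_kinases[sk]})
    for pid in induced:
        if assay == "phospho":
            fid = f"{pid}_S1"
            rows.append({"feature_id": fid, "protein": pid,
                         "is_phospho": True, "kinases": []})
        else:
            rows.append({"feature_id": pid, "protein": pid,
                         "is_phospho": False, "kinases": []})
    n_fill = n_features - len(rows)
    for i in range(n_fill):
        pid = f"BG{i + 1:05d}"
        if assay == "phospho":
            residue = "STY"[i % 3]
            rows.append({"feature_id": f"{pid}_{residue}{10 + i % 90}",
                         "protein": pid, "is_phospho": True, "kinases": []})
        else:
            rows.append({"feature_id": pid, "protein": pid,
                         "is_phospho": False, "kinases": []})
    feats = pd.DataFrame(rows)
    if feats["feature_id"].duplicated().any():
        raise AnnotationMismatchError("duplicate feature ids after assignment")
    return feats


def simulate_dataset(
    design: pd.DataFrame,
    truth: GroundTruth,
    n_features: int,
    ks_map: dict[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format DIA report for a design manifest.

    Returns ``(report, truth)`` where the report holds one precursor row
    per (feature, sample) with linear-scale intensity and, for phospho
    features, a localization probability drawn Beta(9, 1) for confidently
    localized sites or Beta(2, 2) for the ambiguous fraction.
    Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    assay = design["assay"].iloc[0]
    feats = _feature_table(n_features, truth, ks_map or {}, assay, rng)
    fid = feats["feature_id"].to_numpy()
    n_f, n_s = len(feats), len(design)

    baseline = rng.normal(truth.baseline_mean, truth.baseline_sd, size=n_f)

    # per-feature treated effect before ablation: induced-set (gated on
    # timepoint) plus summed kinase effects on annotated substrates
    induced_effect = np.array(
        [truth.induced_set.get(p, 0.0) for p in feats["protein"]]
    )
    kinase_effect = np.array(
        [sum(truth.active_kinases.get(k, 0.0) for k in ks)
         for ks in feats["kinases"]]
    )

    donors = sorted(design["donor"].unique())
    donor_offsets = {
        d: rng.normal(0.0, truth.donor_sigma, size=n_f) for d in donors
    }

    # per-feature localization class, fixed across samples
    ambiguous = rng.random(n_f) < truth.ambiguous_fraction

    records = []
    for _, srow in design.iterrows():
        treated = srow["treatment"] != VEHICLE
        ab = truth.ablation_map.get(srow["genotype"], 1.0)
        effect = np.zeros(n_f)
        if treated:
            effect = kinase_effect * ab
            if srow["timepoint"] >= truth.induction_onset:
                effect = effect + induced_effect * ab
        x = (baseline + effect + donor_offsets[srow["donor"]]
             + rng.normal(0.0, truth.noise_sigma, size=n_f))
        loc_p = np.where(
            ambiguous,
            rng.beta(2.0, 2.0, size=n_f),
            rng.beta(9.0, 1.0, size=n_f),
        )
        rec = pd.DataFrame({
            "sample_id": srow["sample_id"],
            "protein_group": feats["protein"].to_numpy(),
            "stripped_sequence": feats["protein"].to_numpy(),
            "modified_sequence": fid,
            "site_key": np.where(feats["is_phospho"], fid, ""),
            "localization_probability": np.where(
                feats["is_phospho"], loc_p, np.nan
            ),
            "intensity": 2.0 ** x,
            "is_phospho": feats["is_phospho"].to_numpy(),
        })
        records.append(rec)
    report = pd.concat(records, ignore_index=True)
    return report, truth


def apply_missingness(
    matrix: IntensityMatrix,
    truth: GroundTruth,
    design: pd.DataFrame | None = None,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Introduce MNAR and MAR dropout into a fully observed matrix.

    MNAR emulates a detection limit and is intensity-dependent,
    entire-condition absence: per feature x condition block, dropout
    fires with probability ``expit(slope * (midpoint - mean block log2
    intensity))`` and removes the whole block (an infinite slope is a
    hard threshold at the midpoint).  Without a design manifest each
    sample is its own block, degrading to per-entry dropout.  Entries
    surviving MNAR are removed uniformly at ``mar_rate`` (MAR: scattered
    gaps within otherwise observed blocks).  Returns the gapped matrix
    and a label frame over {observed, MAR, MNAR} recording which
    mechanism removed each entry.  Observed values are unchanged.
    Deterministic given ``truth.seed``.
    """
    midpoint, slope = truth.mnar_params
    if slope < 0:
        raise ValueError("mnar logistic slope must be non-negative")
    rng = np.random.default_rng([truth.seed, 7])
    x = matrix.to_log2().values.to_numpy(dtype=float)

    if design is not None:
        d = condition_table(design, matrix.samples)
        blocks = [
            [matrix.samples.get_loc(s) for s in grp["sample_id"]]
            for _, grp in d.groupby("condition", sort=True)
        ]
    else:
        blocks = [[j] for j in range(x.shape[1])]

    mnar = np.zeros(x.shape, dtype=bool)
    for cols in blocks:
        block_mean = x[:, cols].mean(axis=1)
        if np.isinf(slope):
            p_mnar = (block_mean < midpoint).astype(float)
        else:
            from scipy.special import expit
            p_mnar = expit(slope * (midpoint - block_mean))
        fire = rng.random(x.shape[0]) < p_mnar
        mnar[np.ix_(fire, cols)] = True
    mar = (~mnar) & (rng.random(x.shape) < truth.mar_rate)

    gapped = matrix.values.to_numpy(dtype=float).copy()
    gapped[mnar | mar] = np.nan
    labels = np.full(x.shape, "observed", dtype=object)
    labels[mar] = "MAR"
    labels[mnar] = "MNAR"

    out = IntensityMatrix(
        pd.DataFrame(gapped, index=matrix.features, columns=matrix.samples),
        matrix.scale,
        None if matrix.feature_meta is None else matrix.feature_meta.copy(),
    )
    label_frame = pd.DataFrame(labels, index=matrix.features,
                               columns=matrix.samples)
    n_removed = int(mnar.sum() + mar.sum())
    logger.info("apply_missingness removed %d/%d entries (%d MNAR, %d MAR)",
                n_removed, x.size, int(mnar.sum()), int(mar.sum()))
    return out, label_frame


def default_truth(
    seed: int = 0,
    n_induced: int = 30,
    induced_effect: float = 2.0,
    n_active_kinases: int = 5,
    kinase_effect: float = 1.5,
    ablation_map: dict[str, float] | None = None,
    **overrides,
) -> GroundTruth:
    """Convenience constructor for the study-default truth structure.

    Induced proteins ``ISG00001..`` carry log2 effect ``induced_effect``;
    kinases ``KIN01..`` carry ``kinase_effect``.
    """
    induced = {f"ISG{i + 1:05d}": induced_effect for i in range(n_induced)}
    kinases = {f"KIN{i + 1:02d}": kinase_effect for i in range(n_active_kinases)}
    return GroundTruth(
        induced_set=induced,
        active_kinases=kinases,
        ablation_map=ablation_map or {},
        seed=seed,
        **overrides,
    )


def default_kinase_substrate_map(
    n_kinases: int = 50, substrates_per_kinase: int = 10
) -> dict[str, set[str]]:
    """Deterministic annotation: ``KIN01..`` each with disjoint substrate
    sites ``SUB<k>_<i>_S<pos>``."""
    ks: dict[str, set[str]] = {}
    for k in range(n_kinases):
        kin = f"KIN{k + 1:02d}"
        ks[kin] = {
            f"SUB{k + 1:02d}P{i + 1:02d}_S{10 + i}"
            for i in range(substrates_per_kinase)
        }
    return ks
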