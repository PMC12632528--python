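"""Configuration, orchestration and the end-to-end analysis run.

Stage order is fixed: read report and design -> (phospho) site collapse
and Class-I filter -> pivot to matrix -> replicate-presence filter ->
log2 + median-center normalization -> mechanism-aware imputation ->
donor centering -> time-matched differential statistics -> KSEA
(phospho) -> signature derivation from control arms and perturbation
scoring.  Every output file carries the config hash and seed in a
comment header, and a rerun with identical config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from phospipe import differential, impute, io_formats, ksea, preprocess, signatures
from phospipe.containers import ConfigError, condition_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run, with study defaults."""

    report: str = ""
    design: str = ""
    ks_map: str = ""
    out_dir: str = "out"
    mode: str = "phospho"            # global | phospho
    class1_threshold: float = 0.75
    min_present: tuple[int, int] = (3, 4)
    alpha: float = 0.05
    fc_min: float = 0.75
    min_substrates: int = 3
    knn_k: int = 10
    downshift_shift: float = 1.8
    downshift_width: float = 0.3
    engine: str = "moderated"        # student | moderated
    control_prefix: str = "scramble"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("global", "phospho"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.engine not in ("student", "moderated"):
            raise ConfigError(f"unknown engine {self.engine!r}")
        if not (0 < self.alpha <= 1):
            raise ConfigError("alpha must lie in (0, 1]")
        if not (0 <= self.class1_threshold <= 1):
            raise ConfigError("class1_threshold must lie in [0, 1]")
        self.min_present = tuple(self.min_present)  # type: ignore[assignment]

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis run from a different location keeps its identity)."""
        d = asdict(self)
        for key in ("report", "design", "ks_map", "out_dir"):
            d.pop(key)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "min_present" in d:
            d["min_present"] = tuple(d["min_present"])
        return cls(**d)


def validate_design(design: pd.DataFrame, min_present=(3, 4)) -> list[dict]:
    """Check a design manifest for analyzability; returns an issue list.

    Verifies time-matched vehicle availability per treated condition,
    replicate-count feasibility against the presence rule, and donor
    balance.  Reports rather than throws.
    """
    issues: list[dict] = []
    treated = design[design["treatment"] != differential.VEHICLE]
    vehicle = design[design["treatment"] == differential.VEHICLE]
    for (genotype, timepoint), _ in treated.groupby(["genotype", "timepoint"]):
        match = vehicle[(vehicle["genotype"] == genotype)
                        & (vehicle["timepoint"] == timepoint)]
        if match.empty:
            issues.append({
                "kind": "missing_vehicle",
                "detail": f"no time-matched vehicle for genotype={genotype}, "
                          f"timepoint={timepoint:g}",
            })
    k = min_present[0] if isinstance(min_present, tuple) else int(min_present)
    d = condition_table(design)
    for cond, grp in d.groupby("condition", sort=False):
        if len(grp) < k:
            issues.append({
                "kind": "replicate_feasibility",
                "detail": f"condition {cond} has {len(grp)} replicate(s), "
                          f"fewer than the presence rule k={k}",
            })
    donor_counts = design.groupby("donor").size()
    if len(donor_counts) > 1 and donor_counts.max() > 2 * donor_counts.min():
        issues.append({
            "kind": "donor_imbalance",
            "detail": f"donor sample counts {donor_counts.to_dict()} are "
                      "imbalanced (max > 2x min)",
        })
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts to out_dir.

    Returns a dict of the in-memory results (matrices, tables, signature,
    scores) for programmatic use.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("read")
        report = io_formats.read_long_report(config.report)
        design = io_formats.read_design(config.design)
        ks_map = (io_formats.read_kinase_substrate_map(config.ks_map)
                  if config.ks_map else {})
    except Exception as exc:
        raise type(exc)(f"[stage read] {exc}") from exc

    results = _run_stages(report, design, ks_map, config, _stage)

    _stage("write")
    _write_tidy(results["qc_purity"], out / "qc.tsv", header)
    io_formats.write_matrix(results["matrix_imputed"],
                            out / "matrix_imputed.tsv", header)
    _write_tidy(results["diff"], out / "diff.tsv", header)
    if results.get("ksea") is not None:
        _write_tidy(results["ksea"], out / "ksea.tsv", header)
    if results.get("signature") is not None:
        results["signature"].to_json(out / "signature.json")
    if results.get("scores") is not None:
        _write_tidy(results["scores"], out / "scores.tsv", header)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_features_matrix": int(len(results["matrix_imputed"].features)),
        "n_samples": int(len(results["matrix_imputed"].samples)),
        "stage_counts": results["stage_counts"],
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def run_pipeline_frames(
    report: pd.DataFrame,
    design: pd.DataFrame,
    ks_map: dict[str, set[str]] | None,
    config: PipelineConfig,
) -> dict:
    """As :func:`run_pipeline` but on in-memory frames, writing nothing."""
    return _run_stages(report, design, ks_map or {}, config, lambda n: None)


def _run_stages(report, design, ks_map, config, _stage):
    stage_counts = {}
    phospho = config.mode == "phospho"

    if phospho:
        _stage("collapse")
        report = preprocess.collapse_to_sites(report)
        stage_counts["records_after_collapse"] = int(len(report))
        _stage("class1_filter")
        report = preprocess.filter_class1(report, config.class1_threshold)
        stage_counts["records_after_class1"] = int(len(report))

    _stage("pivot")
    level = "site" if phospho else "protein"
    matrix = io_formats.pivot_to_matrix(report, design, level=level)
    stage_counts["features_pivoted"] = int(len(matrix.features))

    _stage("replicate_filter")
    matrix = preprocess.filter_by_replicates(matrix, design, config.min_present)
    stage_counts["features_after_replicate_filter"] = int(len(matrix.features))

    _stage("normalize")
    matrix = preprocess.normalize(matrix)

    _stage("qc")
    qc = preprocess.qc_metrics(report, matrix, design)

    _stage("impute")
    matrix_imp, labels = impute.impute_mixed(
        matrix, design, mode=config.mode, k=config.knn_k,
        shift=config.downshift_shift, width=config.downshift_width,
        seed=config.seed,
    )

    _stage("donor_center")
    centered = differential.center_by_donor(matrix_imp, design)

    _stage("differential")
    diff = differential.differential_table(centered, design,
                                           engine=config.engine)

    ksea_table = None
    if phospho and ks_map:
        _stage("ksea")
        ksea_table = ksea.ksea_z(diff, ks_map, config.min_substrates)

    _stage("signature")
    signature, scores = _signature_stage(diff, config)

    return {
        "qc": qc,
        "qc_purity": qc.enrichment_purity.reset_index().rename(
            columns={"index": "sample_id"}),
        "matrix_imputed": matrix_imp,
        "missingness": labels,
        "diff": diff,
        "ksea": ksea_table,
        "signature": signature,
        "scores": scores,
        "stage_counts": stage_counts,
    }


def _signature_stage(diff, config):
    """Derive a signature from control-arm comparisons and score every
    genotype against it.  Skipped (None, None) when no control arms or
    no induced features exist."""
    controls = sorted(
        g for g in diff["genotype"].unique()
        if str(g).startswith(config.control_prefix)
    )
    if not controls:
        return None, None
    per_cmp = dict(tuple(diff.groupby(differential.COMPARISON_KEYS, sort=True)))
    # use the latest timepoint of each control arm (abundance induction
    # is slow; early timepoints carry no signal)
    control_cmps = [key for key in per_cmp if key[0] in controls]
    if not control_cmps:
        return None, None
    latest_tp = max(key[3] for key in control_cmps)
    control_diffs = [per_cmp[key] for key in sorted(control_cmps)
                     if key[3] == latest_tp]
    signature = signatures.derive_signature(
        control_diffs, alpha=config.alpha, fc_min=config.fc_min,
        provenance=[str(key) for key in sorted(control_cmps)
                    if key[3] == latest_tp],
    )
    if not signature.members:
        return signature, None
    rows = []
    for key in sorted(per_cmp):
        if key[3] != latest_tp:
            continue
        score = signatures.score_perturbation(per_cmp[key], signature,
                                              genotype=key[0])
        rows.append({**asdict(score), "timepoint": key[3]})
    return signature, pd.DataFrame(rows)


def _write_tidy(frame: pd.DataFrame, path, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="")
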