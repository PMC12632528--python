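"""Empirical stimulation signatures and perturbation scoring.

A stimulation signature is the set of features consistently upregulated
(adjusted p below alpha AND log2FC above fc_min, both strict) in every
one of several independent control comparisons — the in-data analog of an
interferon-stimulated-gene list.  Perturbations (gene knockouts,
base edits) are then scored against the signature: how many members
remain significantly induced, how far the member fold-change
distribution shifts, and per-member classification into abolished /
attenuated / retained relative to the control response.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from phospipe.containers import DesignError

logger = logging.getLogger(__name__)

ALPHA = 0.05
FC_MIN = 0.75


@dataclass
class SignatureSet:
    """An empirically derived induced-feature set with its provenance."""

    members: frozenset[str]
    alpha: float = ALPHA
    fc_min: float = FC_MIN
    provenance: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["members"] = sorted(self.members)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SignatureSet":
        with open(path) as fh:
            d = json.load(fh)
        d["members"] = frozenset(d["members"])
        return cls(**d)


@dataclass
class PerturbationScore:
    """Signature readout for one perturbation."""

    genotype: str
    n_signature: int
    n_quantified: int
    n_significant_members: int
    mean_member_fc: float
    mean_nonmember_fc: float


def _significant(diff: pd.DataFrame, alpha: float, fc_min: float) -> pd.Series:
    return (diff["adj_p"] < alpha) & (diff["log2fc"] > fc_min)


def derive_signature(
    control_diffs: list[pd.DataFrame],
    alpha: float = ALPHA,
    fc_min: float = FC_MIN,
    provenance: list[str] | None = None,
) -> SignatureSet:
    """Features significantly upregulated in EVERY control comparison.

    Each element of ``control_diffs`` is a differential table restricted
    to a single comparison (one independent stimulated-control arm).  An
    empty result is returned with a warning rather than raised.
    """
    if not control_diffs:
        raise ValueError("need at least one control comparison")
    member_sets = []
    for diff in control_diffs:
        sig = diff.loc[_significant(diff, alpha, fc_min), "feature_id"]
        member_sets.append(set(sig))
    members = frozenset(set.intersection(*member_sets))
    if not members:
        logger.warning("derive_signature: empty signature at alpha=%g, "
                       "fc_min=%g", alpha, fc_min)
    return SignatureSet(
        members=members, alpha=alpha, fc_min=fc_min,
        provenance=provenance or [f"control_{i}" for i in
                                  range(len(control_diffs))],
    )


def score_perturbation(
    ko_diff: pd.DataFrame, sig: SignatureSet, genotype: str = ""
) -> PerturbationScore:
    """Score one perturbation's differential table against a signature.

    Members never quantified in the perturbation are excluded from the
    denominators (logged).  Non-member mean fold change provides the
    density-shift baseline.
    """
    quantified = ko_diff[np.isfinite(ko_diff["log2fc"])]
    is_member = quantified["feature_id"].isin(sig.members)
    members = quantified[is_member]
    nonmembers = quantified[~is_member]
    n_missing = len(sig.members) - len(members)
    if n_missing:
        logger.info("score_perturbation: %d signature member(s) not "
                    "quantified in %s", n_missing, genotype or "perturbation")
    n_sig = int(_significant(members, sig.alpha, sig.fc_min).sum())
    return PerturbationScore(
        genotype=genotype,
        n_signature=len(sig.members),
        n_quantified=len(members),
        n_significant_members=n_sig,
        mean_member_fc=float(members["log2fc"].mean()) if len(members) else np.nan,
        mean_nonmember_fc=(float(nonmembers["log2fc"].mean())
                           if len(nonmembers) else np.nan),
    )


def classify_members(
    ko_diff: pd.DataFrame,
    ctrl_diff: pd.DataFrame,
    sig: SignatureSet,
    abolish_ratio: float = 0.25,
    retain_ratio: float = 0.75,
) -> pd.Series:
    """Label each signature member's response in a perturbation.

    abolished: not significant in the perturbation AND fold change below
    ``abolish_ratio`` of the control's; retained: significant AND fold
    change at least ``retain_ratio`` of the control's; attenuated:
    everything else.  Members must be quantified in both tables.
    """
    ko = ko_diff.set_index("feature_id")
    ctrl = ctrl_diff.set_index("feature_id")
    shared = sorted(
        (sig.members & set(ko.index) & set(ctrl.index))
    )
    labels = {}
    for f in shared:
        fc_ko = ko.at[f, "log2fc"]
        fc_ctrl = ctrl.at[f, "log2fc"]
        sig_ko = (ko.at[f, "adj_p"] < sig.alpha) and (fc_ko > sig.fc_min)
        if not sig_ko and fc_ko < abolish_ratio * fc_ctrl:
            labels[f] = "abolished"
        elif sig_ko and fc_ko >= retain_ratio * fc_ctrl:
            labels[f] = "retained"
        else:
            labels[f] = "attenuated"
    return pd.Series(labels, name="classification", dtype=object)


def compare_perturbations(
    diff_a: pd.DataFrame,
    diff_b: pd.DataFrame,
    sig: SignatureSet,
) -> dict[str, float]:
    """Similarity of two perturbations' signature responses.

    Pearson r and OLS regression (A on x, B on y) over shared quantified
    member log2 fold changes, plus the Jaccard index of the two
    significant member sets at the signature's thresholds.  Requires at
    least 3 shared quantified members.
    """
    a = diff_a[diff_a["feature_id"].isin(sig.members)].set_index("feature_id")
    b = diff_b[diff_b["feature_id"].isin(sig.members)].set_index("feature_id")
    shared = sorted(set(a.index[np.isfinite(a["log2fc"])])
                    & set(b.index[np.isfinite(b["log2fc"])]))
    if len(shared) < 3:
        raise DesignError("fewer than 3 shared quantified signature members")
    x = a.loc[shared, "log2fc"].to_numpy()
    y = b.loc[shared, "log2fc"].to_numpy()
    fit = stats.linregress(x, y)
    sig_a = set(a.index[(a["adj_p"] < sig.alpha) & (a["log2fc"] > sig.fc_min)])
    sig_b = set(b.index[(b["adj_p"] < sig.alpha) & (b["log2fc"] > sig.fc_min)])
    union = sig_a | sig_b
    jaccard = len(sig_a & sig_b) / len(union) if union else np.nan
    return {
        "pearson_r": float(fit.rvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "jaccard": float(jaccard),
        "n_shared": len(shared),
    }
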