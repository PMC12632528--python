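"""Shared fixtures: small simulated screens built at test time."""

import numpy as np
import pandas as pd
import pytest

from phospipe import differential, impute, io_formats, preprocess
from phospipe import synthetic_data as sd
from phospipe.containers import IntensityMatrix


@pytest.fixture
def two_condition_design():
    """1 knockout + 1 scramble, quadruplicate, one timepoint, vehicles."""
    return sd.generate_design(1, 1, 4, [30.0], include_vehicle=True,
                              assay="global")


@pytest.fixture
def simulate_screen():
    """Factory: simulate a small global screen end of the impute stage.

    Returns (complete log2 matrix, gapped log2 matrix, true labels,
    design, truth).  Matrices are replicate-filtered and normalized with
    identical feature sets so truth and gapped values align.
    """

    def _make(seed=0, n_features=300, ablation=None, n_induced=0,
              timepoints=(30.0,), n_knockouts=1, n_controls=1,
              assay="global", **truth_kw):
        truth = sd.default_truth(seed=seed, n_induced=n_induced,
                                 n_active_kinases=0,
                                 ablation_map=ablation or {}, **truth_kw)
        design = sd.generate_design(n_knockouts, n_controls, 4,
                                    list(timepoints), include_vehicle=True,
                                    assay=assay)
        report, _ = sd.simulate_dataset(design, truth, n_features)
        level = "site" if assay == "phospho" else "protein"
        full = io_formats.pivot_to_matrix(report, design, level=level)
        gapped, labels = sd.apply_missingness(full, truth, design)
        gapped = preprocess.filter_by_replicates(gapped, design, (3, 4))
        gapped = preprocess.normalize(gapped)
        complete = preprocess.normalize(
            IntensityMatrix(full.values.loc[gapped.features], "linear")
        )
        labels = labels.loc[gapped.features, gapped.samples]
        return complete, gapped, labels, design, truth

    return _make


@pytest.fixture
def toy_matrix():
    """4 features x 4 samples log2 matrix with one gap, two conditions."""
    values = pd.DataFrame(
        {
            "s1": [10.0, 12.0, 14.0, 20.0],
            "s2": [10.5, 12.5, np.nan, 20.5],
            "s3": [11.0, 13.0, 15.0, 21.0],
            "s4": [11.5, 13.5, 15.5, 21.5],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    design = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "genotype": ["g"] * 4,
        "donor": ["d1"] * 4,
        "replicate": [1, 2, 3, 4],
        "treatment": ["IFN-b"] * 4,
        "dose": [100.0] * 4,
        "timepoint": [30.0] * 4,
        "assay": ["global"] * 4,
        "cell_type": ["CD4T"] * 4,
    })
    return IntensityMatrix(values, "log2"), design
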