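"""Shared fixtures: small deterministic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from qpcrkit import simdata
from qpcrkit.preprocess import CqMatrix, preprocess_cq


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size simulated study (240 samples, duplicates, 3 plates)."""
    design = simdata.StudyDesign(seed=0)
    truth = simdata.default_truth(design)
    records, meta, latent = simdata.simulate_cq_dataset(design, truth)
    return design, truth, records, meta, latent


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    """Preprocessed (calibrated, filtered, averaged) full-size matrix."""
    design, _, records, meta, _ = default_dataset
    matrix, report = preprocess_cq(records, meta, max_delta=1.0,
                                   genes=design.reference_genes)
    return design, matrix, report


@pytest.fixture(scope="session")
def toy_matrix():
    """Deterministic zero-noise panel whose rankings are subset-invariant.

    All variation is at the group level: gene i takes the value
    ``20 + i + profile_i[group]``, where profile_i is a fixed 4-group
    pattern of unit spread scaled by ``0.4 * 2**i``.  Because stratified
    subsampling keeps every group represented in equal proportion, every
    subset sees exactly the same group-profile distribution (up to a common
    Bessel factor), so each stability method ranks the genes identically on
    the full data and on any stratified subset — the "well-separated
    zero-noise panel" of the robustness criterion.
    """
    rng = np.random.default_rng(7)
    group_labels = [(30, "Low"), (30, "High"), (60, "Low"), (60, "High")]
    genes = list("ABCDEF")
    profiles = {}
    for i, g in enumerate(genes):
        p = rng.normal(size=len(group_labels))
        p = (p - p.mean()) / p.std(ddof=0)          # unit population spread
        profiles[g] = 0.4 * 2.0**i * p
    groups = [gl for gl in group_labels for _ in range(6)]
    values = pd.DataFrame(
        {g: [20.0 + i + profiles[g][group_labels.index(gl)] for gl in groups]
         for i, g in enumerate(genes)},
        index=[f"S{i+1:02d}" for i in range(len(groups))])
    meta = pd.DataFrame(
        {"age_dpf": [a for a, _ in groups],
         "temperature": [t for _, t in groups],
         "sex": list(np.where(rng.random(len(groups)) < 0.5, "F", "M"))},
        index=values.index)
    return CqMatrix(values, meta)
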