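"""Shared fixtures: small synthetic cohorts and references built once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cemsnorm as cn
from cemsnorm.datatypes import ReferenceDataset


def make_matrix(values, feature_ids=None, sample_ids=None, groups=None):
    """FeatureMatrix from a plain 2-D array with auto-generated ids."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    if feature_ids is None:
        feature_ids = [f"{100 + i}.000000/{1000 + i}.000" for i in range(m)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n)]
    g = pd.Series(groups, index=sample_ids) if groups is not None else None
    return cn.FeatureMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), groups=g)


@pytest.fixture(scope="session")
def qc_cohort():
    """Homogeneous cohort (no differential effect, no warp): the setting in
    which stable features are defined."""
    cfg = cn.SimulationConfig(m=150, n_control=8, n_disease=8,
                              n_differential=0, warp_family="none", seed=11)
    return cn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def reference(qc_cohort):
    """Reference dataset with a selected stable set, built once."""
    ss = cn.select_stable_features(qc_cohort.matrix, n_candidates=50)
    return ReferenceDataset(matrix=qc_cohort.matrix, stable=ss.features,
                            mt_window=(840.0, 3000.0),
                            provenance={"fixture": "qc_cohort"})


@pytest.fixture(scope="session")
def reference_median_peaklist(reference):
    """A synthetic new sample lying exactly at the reference medians."""
    med = reference.matrix.values.median(axis=1)
    tab = pd.DataFrame({
        "mz": reference.matrix.mz_array(),
        "mt": reference.matrix.mt_array(),
        "intensity": med.to_numpy(),
    })
    return cn.PeakList("ref_median", tab)
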