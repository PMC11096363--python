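"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from epmet.preprocess import Preprocessor
from epmet.simulate import (SimConfig, cohort_to_frame, generate_cohort,
                            generate_spectra)

SMALL_GROUPS = {"LNSP": 60, "MISCARRIAGE": 30, "PUL": 20, "TEP": 20}


@pytest.fixture(scope="session")
def default_sim():
    """Default-configuration cohort and spectra (full study sizes), seed 1."""
    cfg = SimConfig(seed=1)
    cohort = generate_cohort(cfg)
    matrix, annotation = generate_spectra(cohort, cfg)
    return cfg, cohort, cohort_to_frame(cohort), matrix, annotation


@pytest.fixture(scope="session")
def small_sim():
    """A reduced cohort for fast unit tests."""
    cfg = SimConfig(group_sizes=dict(SMALL_GROUPS), seed=7)
    cohort = generate_cohort(cfg)
    matrix, annotation = generate_spectra(cohort, cfg)
    return cfg, cohort, cohort_to_frame(cohort), matrix, annotation


@pytest.fixture(scope="session")
def preprocessed_default(default_sim):
    """Default simulation pushed through the full preprocessing chain."""
    _, _, df, matrix, annotation = default_sim
    prep = Preprocessor().fit(matrix, annotation, df["fwhm"], df["batch"],
                              df[["binary_label"]])
    kept = prep.matrix_.index
    return prep, prep.matrix_, df.loc[kept]
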