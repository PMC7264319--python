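"""Shared fixtures: synthetic cohorts and feature tables.

The two session-scoped cohorts pin the study conditions used by the
heavier end-to-end tests: a "strong effect" cohort (generator defaults:
the mutant class doubles the interior correlation length) and a null
cohort (identical texture in both classes). Both use the full ~61
patient / ~210 lesion cohort size.
"""

from __future__ import annotations

import numpy as np
import pytest

from bmradiomics import CohortConfig, CohortTable, extract_cohort, generate_cohort
from bmradiomics.synthetic import TextureParams

STRONG_SEED = 701
NULL_SEED = 702


def make_table(X, y, patients=None, diameters=None) -> CohortTable:
    """Wrap a plain matrix in a CohortTable for selector/evaluator tests."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, f = X.shape
    return CohortTable(
        X=X,
        y=y,
        patient_ids=np.asarray(patients)
        if patients is not None
        else np.array([f"P{i}" for i in range(n)]),
        lesion_ids=np.array([f"L{i:04d}" for i in range(n)]),
        diameters_mm=np.asarray(diameters) if diameters is not None else np.full(n, 10.0),
        feature_names=tuple(f"f{j}" for j in range(f)),
    )


@pytest.fixture(scope="session")
def strong_table() -> CohortTable:
    """Features of a full-size cohort with the default strong texture effect."""
    cfg = CohortConfig(seed=STRONG_SEED)
    records = generate_cohort(cfg)
    df = extract_cohort(records)
    return CohortTable.from_dataframe(df)


@pytest.fixture(scope="session")
def null_table() -> CohortTable:
    """Features of a cohort whose two classes share identical texture."""
    tex = TextureParams(correlation_length_mm=1.5, field_sd=0.4, rim_contrast=0.0)
    cfg = CohortConfig(seed=NULL_SEED, texture_class0=tex, texture_class1=tex)
    records = generate_cohort(cfg)
    df = extract_cohort(records)
    return CohortTable.from_dataframe(df)


@pytest.fixture(scope="session")
def weak_table() -> CohortTable:
    """Features of a cohort with a weak effect (1.33x correlation ratio)."""
    cfg = CohortConfig(
        seed=NULL_SEED,
        texture_class1=TextureParams(correlation_length_mm=2.0, field_sd=0.4,
                                     rim_contrast=0.0),
    )
    records = generate_cohort(cfg)
    df = extract_cohort(records)
    return CohortTable.from_dataframe(df)


@pytest.fixture(scope="session")
def tiny_records():
    """A small in-memory cohort for fast pipeline tests."""
    cfg = CohortConfig(
        n_patients=8,
        seed=42,
        diameter_mm=type(CohortConfig().diameter_mm)(3.0, 14.0, 8.0),
    )
    return generate_cohort(cfg)
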