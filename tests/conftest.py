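import numpy as np
import pandas as pd
import pytest

from glioprog import (CohortGeneratorConfig, CohortTable, MissingnessPlan,
                      generate_cohort, generate_training_segments,
                      train_stain_classifier)

NO_MISSING = MissingnessPlan(center_blocks={}, mcar_rate=0.0)


@pytest.fixture(scope="session")
def labeled_segments():
    """Labeled training segments from the default training tile config."""
    return generate_training_segments(n_tiles=10, seed=7)


@pytest.fixture(scope="session")
def stain_model(labeled_segments):
    return train_stain_classifier(labeled_segments, seed=7)


@pytest.fixture(scope="session")
def clean_cohort():
    """A fully observed synthetic cohort with its ground truth."""
    cfg = CohortGeneratorConfig(n=2000, seed=42, missingness=NO_MISSING)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


def make_table(columns: dict, schema: dict | None = None) -> CohortTable:
    """Small cohort table from plain columns (auto patient ids)."""
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns)
    if "patient_id" not in df:
        df.insert(0, "patient_id",
                  pd.array([f"P{i:03d}" for i in range(n)], dtype="string"))
    if schema is None:
        schema = {"patient_id": ("string", None)}
        for c in columns:
            schema[c] = ("numeric", None)
    return CohortTable(df, schema)
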