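"""Published reference tables for a multi-site glioblastoma cohort.

These are the printed summary counts and Cox screening tables from the
retrospective study the pipeline is designed around (581 patients across
four centers).  They serve as worked-example inputs: the summarizer must
reproduce the printed percentages from the counts, and the p < 0.05 screen
must reproduce the printed retained-feature counts.  No patient-level data
is included — only published aggregates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_data import CohortTable

#: patients documented per center; the totals column is their sum.
CENTER_N = {"OSU": 377, "UMMC": 57, "Barretos": 94, "FLENI": 53}

#: per-center categorical counts (collected sites only; elsewhere the
#: field was never collected).
CATEGORICAL_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "gender": {
        "OSU": {"Male": 219, "Female": 158},
        "UMMC": {"Male": 36, "Female": 21},
        "Barretos": {"Male": 54, "Female": 40},
        "FLENI": {"Male": 33, "Female": 20},
    },
    "atrx": {
        "OSU": {"intact": 341, "loss": 3},
        "Barretos": {"intact": 86, "loss": 6},
    },
    "p53_positive": {
        "OSU": {"True": 256, "False": 72},
    },
    "egfr_amplified": {
        "OSU": {"True": 173, "False": 136},
    },
    "mgmt_methylated": {
        "OSU": {"True": 155, "False": 221},
        "Barretos": {"True": 34, "False": 28},
    },
}

#: univariate Cox screen of overall survival: published beta and Wald p
#: per clinical feature.
UNIVARIATE_RESULTS = pd.DataFrame(
    [
        ("age_at_surgery", 0.01944, 4.20e-06),
        ("gender", -0.01552, 0.87),
        ("race", -0.002198, 0.54),
        ("ethnicity", 0.1583, 0.15),
        ("weight", 0.002215, 0.32),
        ("height", 0.004985, 0.31),
        ("bmi", 0.004967, 0.54),
        ("cci_score", 0.05545, 0.011),
        ("lesion_side", 0.03169, 0.72),
        ("lesion_lobe", -0.01187, 0.77),
        ("atrx", 0.1074, 0.78),
        ("p53_positive", -0.1035, 0.46),
        ("ki67", 0.00311, 0.35),
        ("egfr_amplified", -0.2294, 0.057),
        ("mgmt_methylated", -0.4272, 3.40e-05),
        ("lesion_size", 0.01855, 0.53),
        ("midline_shift", -0.1176, 0.3),
        ("wbc", 0.02951, 0.00036),
        ("platelets", 0.000202, 0.72),
        ("neutrophils", 0.04722, 0.00015),
        ("lymphocytes", 0.01214, 0.51),
        ("nlr", 0.01261, 0.0023),
        ("steroid_dose", 0.02151, 0.12),
        ("radiation_dose", -0.05025, 9.80e-22),
        ("radiation_fractions", -0.05064, 1.70e-12),
        ("radiation_time", -0.003487, 0.049),
        ("tmz_cycles", -0.1612, 3.30e-19),
        ("tmz_dose", -0.00238, 1.80e-10),
        ("center", -0.05162, 0.32),
    ],
    columns=["feature", "beta", "p"],
)

#: multivariate Cox model over the univariate-significant features.
MULTIVARIATE_RESULTS = pd.DataFrame(
    [
        ("age_at_surgery", 0.02665, 0.0011),
        ("cci_score", -0.01702, 0.62),
        ("mgmt_methylated", -0.4308, 0.0027),
        ("wbc", 0.01937, 0.18),
        ("neutrophils", 0.062, 0.013),
        ("nlr", -0.01111, 0.13),
        ("radiation_dose", -0.05578, 5.30e-06),
        ("radiation_fractions", 0.0134, 0.55),
        ("radiation_time", 0.005447, 0.55),
        ("tmz_cycles", -0.205, 1.20e-10),
        ("tmz_dose", 0.0003521, 0.53),
    ],
    columns=["feature", "beta", "p"],
)


def build_reference_cohort() -> CohortTable:
    """Reconstruct a categorical-only cohort table from the published
    per-center counts.

    Each patient row carries only the categorical fields with printed
    counts (gender, ATRX, p53, EGFR, MGMT) assigned so the per-feature
    tallies match the publication exactly; fields never collected at a
    site are missing.  Numeric and outcome fields are not reconstructed.
    """
    frames = []
    for center, n in CENTER_N.items():
        df = pd.DataFrame({
            "patient_id": [f"{center}-{i:04d}" for i in range(n)],
            "center": center,
        })
        for feat, by_center in CATEGORICAL_COUNTS.items():
            col = np.full(n, None, dtype=object)
            counts = by_center.get(center, {})
            pos = 0
            for level, k in counts.items():
                col[pos:pos + k] = level
                pos += k
            df[feat] = col
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    for feat in ("p53_positive", "egfr_amplified", "mgmt_methylated"):
        df[feat] = df[feat].map({"True": True, "False": False}
                                ).astype("boolean")
    for feat in ("patient_id", "center", "gender", "atrx"):
        df[feat] = df[feat].astype("string")
    table = CohortTable(df)
    table.validate()
    return table
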