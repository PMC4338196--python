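"""Bundled reference constants from the originating serum-miRNA study.

These are published, printed numbers carried as fixtures: the study's
cohort composition, the top-10 marker median expression levels, the
published 4-miRNA discriminant function, and its per-group classification
counts.  They let the performance and discriminant modules be exercised
against the published worked examples without access to the raw data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ClinicalGroup, DiscriminantModel

#: Cohort composition: patients per clinical group (571 total).
DEFAULT_GROUP_SIZES: dict[ClinicalGroup, int] = {
    ClinicalGroup.HEALTHY: 150,
    ClinicalGroup.PANCREATIC: 100,
    ClinicalGroup.BILIARY: 98,
    ClinicalGroup.NONMALIGNANT_PB: 21,
    ClinicalGroup.COLON: 50,
    ClinicalGroup.STOMACH: 50,
    ClinicalGroup.ESOPHAGEAL: 50,
    ClinicalGroup.LIVER: 52,
}

#: Top-10 validated marker miRNAs for pancreato-biliary cancer vs all other
#: clinical conditions, with median log2 expression on each side
#: (cancer-side median, control-side median), ordered by ascending
#: training-cohort p-value.
REFERENCE_MARKER_MEDIANS: dict[str, tuple[float, float]] = {
    "miR-6075": (9.46, 8.43),
    "miR-4294": (9.25, 10.39),
    "miR-6880-5p": (6.60, 7.63),
    "miR-6799-5p": (7.88, 8.24),
    "miR-125a-3p": (4.08, 6.02),
    "miR-4530": (8.76, 9.39),
    "miR-6836-3p": (9.25, 8.70),
    "miR-4634": (10.08, 9.85),
    "miR-7114-5p": (6.59, 6.91),
    "miR-4476": (5.79, 7.01),
}


def pb4_model() -> DiscriminantModel:
    """The published 4-miRNA diagnostic index.

    index = 1.20 x miR-6075 - 0.93 x miR-6799-5p - 0.22 x miR-125a-3p
            + 0.71 x miR-6836-3p - 8.55

    A bundled constant, not a fit product: the exact scaling convention
    behind the published coefficients is not reproducible from data.
    """
    return DiscriminantModel(
        marker_ids=["miR-6075", "miR-6799-5p", "miR-125a-3p", "miR-6836-3p"],
        weights=np.array([1.20, -0.93, -0.22, 0.71]),
        intercept=-8.55,
        training_comparison="pb_vs_all",
    )


BUILTIN_MODELS = {"pb4": pb4_model}

# Published per-group classification counts of the 4-miRNA index
# (positive = classified pancreato-biliary cancer).  One row per clinical
# subgroup and cohort; "stage" carries the stage/operability stratum.
_INDEX_COUNT_ROWS = [
    # cohort, group, stage, positive, negative
    ("train", ClinicalGroup.HEALTHY, "-", 0, 102),
    ("train", ClinicalGroup.PANCREATIC, "pStage I", 0, 0),
    ("train", ClinicalGroup.PANCREATIC, "pStage II", 12, 1),
    ("train", ClinicalGroup.PANCREATIC, "cStage III", 19, 2),
    ("train", ClinicalGroup.PANCREATIC, "cStage IV", 34, 3),
    ("train", ClinicalGroup.BILIARY, "Operable", 21, 5),
    ("train", ClinicalGroup.BILIARY, "Inoperable", 27, 8),
    ("train", ClinicalGroup.NONMALIGNANT_PB, "-", 6, 8),
    ("train", ClinicalGroup.COLON, "-", 11, 25),
    ("train", ClinicalGroup.STOMACH, "-", 2, 23),
    ("train", ClinicalGroup.ESOPHAGEAL, "-", 9, 25),
    ("train", ClinicalGroup.LIVER, "-", 5, 33),
    ("test", ClinicalGroup.HEALTHY, "-", 0, 48),
    ("test", ClinicalGroup.PANCREATIC, "pStage I", 1, 0),
    ("test", ClinicalGroup.PANCREATIC, "pStage II", 3, 2),
    ("test", ClinicalGroup.PANCREATIC, "cStage III", 5, 1),
    ("test", ClinicalGroup.PANCREATIC, "cStage IV", 15, 2),
    ("test", ClinicalGroup.BILIARY, "Operable", 17, 5),
    ("test", ClinicalGroup.BILIARY, "Inoperable", 13, 2),
    ("test", ClinicalGroup.NONMALIGNANT_PB, "-", 0, 7),
    ("test", ClinicalGroup.COLON, "-", 1, 13),
    ("test", ClinicalGroup.STOMACH, "-", 2, 23),
    ("test", ClinicalGroup.ESOPHAGEAL, "-", 1, 15),
    ("test", ClinicalGroup.LIVER, "-", 0, 14),
]


def reference_index_counts() -> pd.DataFrame:
    """Published classification counts of the 4-miRNA index, as a DataFrame
    with columns cohort, group, stage, positive, negative."""
    return pd.DataFrame(
        _INDEX_COUNT_ROWS, columns=["cohort", "group", "stage", "positive", "negative"]
    )


#: Published per-group (train, test) cohort sizes.  Not all consistent with
#: a single rounding rule; pass to ``stratified_split`` as an override to
#: replicate the published partition sizes exactly.
REFERENCE_SPLIT_COUNTS: dict[ClinicalGroup, tuple[int, int]] = {
    ClinicalGroup.HEALTHY: (102, 48),
    ClinicalGroup.PANCREATIC: (71, 29),
    ClinicalGroup.BILIARY: (61, 37),
    ClinicalGroup.NONMALIGNANT_PB: (14, 7),
    ClinicalGroup.COLON: (36, 14),
    ClinicalGroup.STOMACH: (25, 25),
    ClinicalGroup.ESOPHAGEAL: (34, 16),
    ClinicalGroup.LIVER: (38, 14),
}
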