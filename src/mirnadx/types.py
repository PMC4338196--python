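"""Shared domain types for the serum-miRNA diagnostic pipeline.

The pipeline moves data through three containers: raw linear-scale array
signals (:class:`RawArrayCollection`), a preprocessed log2 expression matrix
(:class:`ExpressionMatrix`), and per-sample clinical annotations
(:class:`SampleAnnotation`).  Fitted diagnostic indices are carried by
:class:`DiscriminantModel`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ClinicalGroup(str, enum.Enum):
    """The eight clinical groups of the study design.

    PANCREATIC and BILIARY together form the pancreato-biliary cancer
    (detection target) side; the remaining six groups serve as controls in
    the pooled comparison.
    """

    HEALTHY = "HEALTHY"
    PANCREATIC = "PANCREATIC"
    BILIARY = "BILIARY"
    NONMALIGNANT_PB = "NONMALIGNANT_PB"
    COLON = "COLON"
    STOMACH = "STOMACH"
    ESOPHAGEAL = "ESOPHAGEAL"
    LIVER = "LIVER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Pancreato-biliary cancer side of the pooled comparison.
PB_CANCER_GROUPS = frozenset({ClinicalGroup.PANCREATIC, ClinicalGroup.BILIARY})

#: All non-pancreato-biliary groups.
CONTROL_GROUPS = frozenset(set(ClinicalGroup) - PB_CANCER_GROUPS)


def parse_group(label: str) -> ClinicalGroup:
    """Parse a clinical-group label, raising with the valid labels listed."""
    try:
        return ClinicalGroup(label.strip().upper())
    except ValueError:
        valid = ", ".join(g.value for g in ClinicalGroup)
        raise ValueError(
            f"unknown clinical group {label!r}; valid groups are: {valid}"
        ) from None


@dataclass
class SampleAnnotation:
    """Clinical annotation of one serum sample.

    Optional covariates are ``None`` when unavailable, never 0 — serum
    CA19-9 / CEA scores are missing for some patients and 0 would be a
    legitimate assay value.
    """

    sample_id: str
    group: ClinicalGroup
    stage: Optional[str] = None
    operable: Optional[bool] = None
    ca19_9: Optional[float] = None  # U/mL
    cea: Optional[float] = None  # ng/mL
    d_bilirubin: Optional[float] = None  # mg/dL

    def __post_init__(self) -> None:
        if isinstance(self.group, str):
            self.group = parse_group(self.group)


def check_unique_sample_ids(annotations: Sequence[SampleAnnotation]) -> None:
    seen: set[str] = set()
    for ann in annotations:
        if ann.sample_id in seen:
            raise ValueError(f"duplicate sample_id {ann.sample_id!r}")
        seen.add(ann.sample_id)


def group_counts(annotations: Sequence[SampleAnnotation]) -> dict[ClinicalGroup, int]:
    counts: dict[ClinicalGroup, int] = {g: 0 for g in ClinicalGroup}
    for ann in annotations:
        counts[ann.group] += 1
    return counts


@dataclass
class ExpressionMatrix:
    """A probe x sample signal matrix with a detection mask.

    ``values`` is a pandas DataFrame indexed by probe (miRNA) ID with one
    column per sample.  ``scale`` records whether values are raw linear
    signals or preprocessed log2 signals; stages that require one scale
    refuse the other.  ``detected`` mirrors ``values`` with the per-cell
    present call (all True when unknown).
    """

    values: pd.DataFrame
    scale: str = "log2"  # "linear" or "log2"
    detected: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.detected is None:
            self.detected = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        elif self.detected.shape != self.values.shape:
            raise ValueError("detected mask shape must match values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            values=self.values.loc[:, list(sample_ids)].copy(),
            scale=self.scale,
            detected=self.detected.loc[:, list(sample_ids)].copy(),
        )

    def require_scale(self, scale: str, stage: str) -> None:
        if self.scale != scale:
            raise ValueError(
                f"{stage} requires a {scale}-scale matrix but got {self.scale}; "
                "check the '# scale=' tag of the input file"
            )


@dataclass
class RawArrayCollection:
    """Pre-normalization single-channel array signals for a cohort.

    ``probe_signals``: linear-scale probe x sample DataFrame.
    ``nc_signals``: linear-scale negative-control x sample DataFrame; the
    negative-control probes carry no complementary target and define the
    per-array presence threshold.
    """

    probe_signals: pd.DataFrame
    nc_signals: pd.DataFrame
    annotations: list[SampleAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.probe_signals.to_numpy(dtype=float) <= 0).any():
            raise ValueError("linear-scale probe signals must be positive")
        if (self.nc_signals.to_numpy(dtype=float) <= 0).any():
            raise ValueError("linear-scale negative-control signals must be positive")
        if list(self.probe_signals.columns) != list(self.nc_signals.columns):
            raise ValueError("probe and negative-control sample columns differ")
        if self.probe_signals.index.has_duplicates:
            raise ValueError("duplicate probe IDs in raw collection")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probe_signals.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.probe_signals.columns)


@dataclass
class NegativeControlStats:
    """Trimmed summary of one array's negative-control signals.

    ``presence_threshold`` = trimmed mean + multiplier x trimmed SD; a probe
    is called present only if its linear signal strictly exceeds it.
    """

    trimmed_mean: float
    trimmed_sd: float
    presence_threshold: float
    n_used: int


@dataclass
class DiscriminantModel:
    """A linear diagnostic index: score = w . x + b on log2 signals.

    A sample is classified to the cancer side iff its score exceeds the
    index cutoff (0 by convention); a score exactly at the cutoff falls on
    the non-cancer side.
    """

    marker_ids: list[str]
    weights: np.ndarray
    intercept: float
    training_comparison: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.marker_ids) != self.weights.size:
            raise ValueError("one weight per marker required")
        if len(self.marker_ids) < 1:
            raise ValueError("model needs at least one marker")


@dataclass
class CohortSplit:
    """A stratified train/test partition of sample IDs."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    per_group_counts: dict[ClinicalGroup, tuple[int, int]]

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
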