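"""Pipeline configuration.

Collects every tunable constant of the preprocessing and selection
procedure in one validated record, so that the whole pipeline is a pure
function of (data, config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Any, Mapping


@dataclass
class PipelineConfig:
    """Constants of the preprocessing / selection / discriminant procedure.

    Parameters
    ----------
    nc_trim_fraction
        Fraction of negative-control signals removed from EACH end (ranked
        by intensity) before computing the presence threshold.
    presence_sd_multiplier
        Presence threshold = trimmed NC mean + multiplier x trimmed NC SD.
    floor_offset_log2
        Undetected signals are replaced by the array's minimum detected
        log2 signal minus this offset.
    prevalence_signal_log2
        Robust-marker filter: a probe must show a signal of at least
        2**prevalence_signal_log2 ...
    prevalence_fraction
        ... in strictly more than this fraction of samples on at least one
        side of the comparison.
    alpha
        Family-wise significance level for the Bonferroni-corrected
        two-sided Student's t-test.
    train_fraction
        Fraction of each clinical group assigned to the training cohort.
    index_cutoff
        Diagnostic-index decision boundary; scores strictly above it are
        classified to the cancer side.
    validation_mode
        How test-cohort significance is judged for training-selected
        markers: "bonferroni" (corrected over the carried-forward
        candidates) or "raw".
    bonferroni_scope
        Multiplicity for the training-cohort correction: "prevalence"
        (probes surviving the prevalence filter, the stricter reading) or
        "all" (every probe on the array).
    lda_ridge
        Ridge term added to the pooled within-class covariance when it is
        singular, as a multiple of its mean diagonal; None disables the
        fallback and singular fits raise.
    """

    nc_trim_fraction: float = 0.05
    presence_sd_multiplier: float = 2.0
    floor_offset_log2: float = 0.1
    prevalence_signal_log2: float = 6.0
    prevalence_fraction: float = 0.5
    alpha: float = 0.01
    train_fraction: float = 2.0 / 3.0
    index_cutoff: float = 0.0
    rng_seed: int = 7
    validation_mode: str = "bonferroni"
    bonferroni_scope: str = "prevalence"
    lda_ridge: float | None = 1e-6

    def __post_init__(self) -> None:
        for name in ("nc_trim_fraction", "prevalence_fraction", "train_fraction", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.presence_sd_multiplier <= 0:
            raise ValueError("presence_sd_multiplier must be > 0")
        if self.floor_offset_log2 <= 0:
            raise ValueError("floor_offset_log2 must be > 0")
        if self.validation_mode not in ("bonferroni", "raw"):
            raise ValueError("validation_mode must be 'bonferroni' or 'raw'")
        if self.bonferroni_scope not in ("prevalence", "all"):
            raise ValueError("bonferroni_scope must be 'prevalence' or 'all'")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
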