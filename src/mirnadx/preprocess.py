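"""Single-channel microarray signal preprocessing.

Four fixed steps, in order:

1. Per array, summarize the negative-control signals after trimming the
   top and bottom 5% ranked by intensity; the presence threshold is the
   trimmed mean + 2 x trimmed SD.
2. Call each probe present iff its linear signal strictly exceeds the
   threshold, and subtract the trimmed negative-control mean from present
   signals (background subtraction).
3. log2-transform present signals; replace undetected or non-positive
   values by the array's minimum detected log2 signal minus 0.1.
4. Quantile-normalize across arrays (rank-mean, Bolstad-style tie
   handling), making every sample's signal distribution identical.

Thresholding and subtraction act on the LINEAR scale; the log2 transform
happens at the flooring step — the only ordering under which a linear
presence threshold and a log2 floor offset are both coherent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .types import ExpressionMatrix, NegativeControlStats, RawArrayCollection


def negative_control_stats(
    nc_signals: np.ndarray,
    trim_fraction: float = 0.05,
    sd_multiplier: float = 2.0,
) -> NegativeControlStats:
    """Trimmed mean/SD of one array's negative controls and the derived
    presence threshold.

    Removes floor(trim_fraction * n) values from each end of the intensity
    ranking, then takes the mean and the sample (n-1) standard deviation of
    the remainder.
    """
    nc = np.asarray(nc_signals, dtype=float)
    if (nc < 0).any():
        raise ValueError("negative-control signals must be non-negative")
    n = nc.size
    k = int(np.floor(trim_fraction * n))
    kept = np.sort(nc)[k : n - k] if k else np.sort(nc)
    if kept.size < 3:
        raise ValueError(
            f"only {kept.size} negative-control signals remain after trimming; need >= 3"
        )
    mean = float(kept.mean())
    sd = float(kept.std(ddof=1))
    return NegativeControlStats(
        trimmed_mean=mean,
        trimmed_sd=sd,
        presence_threshold=mean + sd_multiplier * sd,
        n_used=int(kept.size),
    )


def call_present_and_subtract(
    raw: RawArrayCollection,
    stats: dict[str, NegativeControlStats],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Present call and background subtraction, per sample.

    A probe is present iff its linear signal is strictly greater than the
    sample's presence threshold ("more than" is strict); present signals
    have the trimmed negative-control mean subtracted.  Returns
    ``(subtracted_linear, detected)`` DataFrames; undetected cells keep
    their subtracted value but carry no meaning downstream.
    """
    missing = [s for s in raw.sample_ids if s not in stats]
    if missing:
        raise ValueError(f"missing negative-control stats for samples: {missing[:5]}")
    thresholds = pd.Series({s: stats[s].presence_threshold for s in raw.sample_ids})
    means = pd.Series({s: stats[s].trimmed_mean for s in raw.sample_ids})
    detected = raw.probe_signals.gt(thresholds, axis=1)
    subtracted = raw.probe_signals.sub(means, axis=1)
    return subtracted, detected


def floor_undetected(
    subtracted: pd.DataFrame,
    detected: pd.DataFrame,
    floor_offset_log2: float = 0.1,
) -> pd.DataFrame:
    """log2-transform detected signals; floor everything else.

    A cell is floored when it was not called present or its subtracted
    value is non-positive; the replacement is (minimum detected log2 value
    on that array) - ``floor_offset_log2``, computed per sample.
    """
    usable = detected & (subtracted > 0)
    n_det = usable.sum(axis=0)
    empty = n_det[n_det == 0]
    if len(empty):
        raise ValueError(
            f"samples with zero detected probes: {list(empty.index)[:5]}"
        )
    log2_vals = pd.DataFrame(
        np.where(usable, np.log2(subtracted.where(usable, 1.0)), np.nan),
        index=subtracted.index,
        columns=subtracted.columns,
    )
    floors = log2_vals.min(axis=0) - floor_offset_log2
    out = log2_vals.fillna(floors)
    return out


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Rank-mean quantile normalization across sample columns.

    Each sample's sorted values are replaced by the mean sorted vector
    across samples; ties within a sample receive the mean of the reference
    values at their tied ranks, so after normalization every column holds
    the same multiset of values (exactly, absent ties).
    """
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if values.isna().any().any():
        raise ValueError("missing values present; flooring must precede normalization")
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(arr)
    n = arr.shape[0]
    ranks = np.empty(n, dtype=float)
    for j in range(arr.shape[1]):
        col_order = order[:, j]
        col_sorted = arr[col_order, j]
        # positional reference values, then average over runs of ties
        ref_assigned = reference.copy()
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col_sorted[k + 1] == col_sorted[i]:
                k += 1
            if k > i:
                ref_assigned[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        ranks[col_order] = ref_assigned
        out[:, j] = ranks
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def preprocess(
    raw: RawArrayCollection,
    config: PipelineConfig | None = None,
    groups: pd.Series | None = None,
) -> ExpressionMatrix:
    """Full preprocessing: NC stats -> present call/subtraction -> floor ->
    quantile normalization.

    ``groups`` (sample_id -> label) switches normalization from the pooled
    default to per-batch: each label's arrays are normalized among
    themselves.  Returns a log2-scale :class:`ExpressionMatrix` with the
    present-call mask attached.
    """
    config = config or PipelineConfig()
    stats = {
        s: negative_control_stats(
            raw.nc_signals[s].to_numpy(),
            trim_fraction=config.nc_trim_fraction,
            sd_multiplier=config.presence_sd_multiplier,
        )
        for s in raw.sample_ids
    }
    subtracted, detected = call_present_and_subtract(raw, stats)
    floored = floor_undetected(subtracted, detected, config.floor_offset_log2)
    if groups is None:
        normalized = quantile_normalize(floored)
    else:
        pieces = []
        for label in pd.unique(groups):
            cols = [s for s in floored.columns if groups.get(s) == label]
            pieces.append(quantile_normalize(floored[cols]))
        normalized = pd.concat(pieces, axis=1)[floored.columns]
    return ExpressionMatrix(values=normalized, scale="log2", detected=detected)
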