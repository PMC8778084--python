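"""Signal conditioning: channel exclusion, smoothing, min–max normalization.

Two normalization schemes are provided.  *Local* (fractional) normalization
scales each recording by its own per-sensor range,

    |Rnorm(x)| = |Ri - R0| / (Rmax(x) - Rmin(x)),

with R0 the baseline-phase reference of sensor x and Rmin/Rmax the extremes
within that same sample.  *Global* normalization subtracts the per-sample
baseline average and divides by the per-sensor range observed across all
samples and classes,

    |Rnorm(x)| = |Ri - Rbaseline(avg)| / (Rglobal_max(x) - Rglobal_min(x)),

which preserves absolute-amplitude differences between classes.  Both map
responses onto a unified dimensionless [0, 1] scale.  The global scale
should be fitted on training data only and reused on held-out data
(out-of-range values are clipped, with a logged count) to avoid leakage.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .recording import (
    PHASES,
    ConditionedRecording,
    NormalizationScale,
    RawRecording,
)

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED = (5, 6, 23, 31)  # humidity-sensitive channels
DEFAULT_WINDOW = 5  # rolling-mean samples


def exclude_channels(rec: RawRecording, ids: Sequence[int]) -> RawRecording:
    """Drop the named sensor channels, preserving the order of the rest."""
    unknown = [i for i in ids if i not in rec.sensor_ids]
    if unknown:
        raise ValueError(f"unknown sensor IDs: {unknown}")
    keep = [j for j, sid in enumerate(rec.sensor_ids) if sid not in set(ids)]
    return rec.with_values(
        rec.values[:, keep], sensor_ids=[rec.sensor_ids[j] for j in keep]
    )


def rolling_mean(rec: RawRecording, window: int = DEFAULT_WINDOW) -> RawRecording:
    """Trailing per-sensor rolling mean; partial windows at the start are
    truncated (mean over the samples seen so far)."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    smoothed = (
        pd.DataFrame(rec.values).rolling(window, min_periods=1).mean().to_numpy()
    )
    return rec.with_values(smoothed)


def _baseline_range(rec, baseline_window: Optional[tuple[int, int]]) -> tuple[int, int]:
    if baseline_window is None:
        start, stop = rec.phase_range("baseline")
        if stop <= start:  # no baseline phase recorded: fall back to first sample
            return 0, 1
        return start, stop
    start, stop = baseline_window
    if not (0 <= start < stop <= rec.n_timepoints):
        raise ValueError(f"baseline_window {baseline_window} outside recording")
    return start, stop


def _zero_flat_channels(norm: np.ndarray, span: np.ndarray, sensor_ids) -> np.ndarray:
    flat = span <= 0
    if np.any(flat):
        bad = [sensor_ids[i] for i in np.flatnonzero(flat)]
        logger.warning("flat channels zeroed during normalization: %s", bad)
        norm[:, flat] = 0.0
    return norm


def normalize_local(
    rec: RawRecording, baseline_window: Optional[tuple[int, int]] = None
) -> ConditionedRecording:
    """Fractional normalization by the sample's own per-sensor range.

    R0 is the mean over the baseline window (the baseline phase by default).
    Flat channels (zero range) are set to zero with a warning rather than
    raising, so degenerate channels do not abort a batch.
    """
    start, stop = _baseline_range(rec, baseline_window)
    r0 = rec.values[start:stop].mean(axis=0)
    rmin = rec.values.min(axis=0)
    rmax = rec.values.max(axis=0)
    span = rmax - rmin
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.abs(rec.values - r0) / span
    norm = _zero_flat_channels(norm, span, rec.sensor_ids)
    return ConditionedRecording(
        sensor_ids=list(rec.sensor_ids),
        values=np.clip(norm, 0.0, 1.0),
        mode="local",
        sampling_rate=rec.sampling_rate,
        phase_boundaries=rec.phase_boundaries,
        label=rec.label,
        replicate_id=rec.replicate_id,
    )


def fit_global_scale(
    dataset: Sequence[RawRecording],
    baseline_window: Optional[tuple[int, int]] = None,
) -> NormalizationScale:
    """Per-sensor min/max over every timepoint of every recording."""
    if len(dataset) == 0:
        raise ValueError("cannot fit a global scale on an empty dataset")
    sensor_ids = list(dataset[0].sensor_ids)
    for rec in dataset:
        if list(rec.sensor_ids) != sensor_ids:
            raise ValueError("recordings have inconsistent sensor sets")
    stacked = np.vstack([rec.values for rec in dataset])
    return NormalizationScale(
        mode="global",
        sensor_ids=sensor_ids,
        rmin=stacked.min(axis=0),
        rmax=stacked.max(axis=0),
    )


def normalize_global(
    rec: RawRecording,
    scale: NormalizationScale,
    baseline_window: Optional[tuple[int, int]] = None,
) -> ConditionedRecording:
    """Normalize by a fitted global per-sensor range.

    The per-sample baseline average is subtracted; values that fall outside
    the fitted range (possible on held-out data) are clipped to [0, 1] and
    the clipped count logged.
    """
    if scale.mode != "global":
        raise ValueError("scale must be fitted in global mode")
    if list(rec.sensor_ids) != list(scale.sensor_ids):
        raise ValueError("recording sensors do not match the fitted scale")
    start, stop = _baseline_range(rec, baseline_window)
    r0 = rec.values[start:stop].mean(axis=0)
    span = scale.rmax - scale.rmin
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.abs(rec.values - r0) / span
    norm = _zero_flat_channels(norm, span, rec.sensor_ids)
    n_clipped = int(np.sum(norm > 1.0))
    if n_clipped:
        logger.info("clipped %d out-of-range values during global normalization",
                    n_clipped)
    return ConditionedRecording(
        sensor_ids=list(rec.sensor_ids),
        values=np.clip(norm, 0.0, 1.0),
        mode="global",
        sampling_rate=rec.sampling_rate,
        phase_boundaries=rec.phase_boundaries,
        label=rec.label,
        replicate_id=rec.replicate_id,
    )


def slice_phase(rec, phase: str):
    """Restrict a recording to one named phase's rows."""
    start, stop = rec.phase_range(phase)
    i = PHASES.index(phase)
    new_edges = tuple([0] * (i + 1) + [stop - start] * (len(PHASES) - i))
    common = dict(
        sensor_ids=list(rec.sensor_ids),
        values=rec.values[start:stop],
        sampling_rate=rec.sampling_rate,
        phase_boundaries=new_edges,
        label=rec.label,
        replicate_id=rec.replicate_id,
    )
    if isinstance(rec, ConditionedRecording):
        return ConditionedRecording(mode=rec.mode, **common)
    return RawRecording(**common)


# ---------------------------------------------------------------------------
# sklearn-style transformers (operate on lists of recordings)


class ChannelExcluder(BaseEstimator, TransformerMixin):
    """Stateless transformer dropping humidity-sensitive channels."""

    def __init__(self, ids: Sequence[int] = DEFAULT_EXCLUDED):
        self.ids = ids

    def fit(self, X, y=None):
        self.n_fitted_ = len(X)
        return self

    def transform(self, X):
        return [exclude_channels(rec, self.ids) for rec in X]


class RollingMean(BaseEstimator, TransformerMixin):
    """Stateless trailing rolling-mean smoother."""

    def __init__(self, window: int = DEFAULT_WINDOW):
        self.window = window

    def fit(self, X, y=None):
        self.n_fitted_ = len(X)
        return self

    def transform(self, X):
        return [rolling_mean(rec, self.window) for rec in X]


class LocalNormalizer(BaseEstimator, TransformerMixin):
    """Per-recording fractional normalization (no fitted state)."""

    def __init__(self, baseline_window: Optional[tuple[int, int]] = None):
        self.baseline_window = baseline_window

    def fit(self, X, y=None):
        self.n_fitted_ = len(X)
        return self

    def transform(self, X):
        return [normalize_local(rec, self.baseline_window) for rec in X]


class GlobalNormalizer(BaseEstimator, TransformerMixin):
    """Global min–max normalization fitted on the training recordings.

    Fitting computes ``scale_`` (per-sensor global extremes); transform
    reuses it, clipping out-of-range values on unseen data.
    """

    def __init__(self, baseline_window: Optional[tuple[int, int]] = None):
        self.baseline_window = baseline_window

    def fit(self, X, y=None):
        self.scale_ = fit_global_scale(X, self.baseline_window)
        return self

    def transform(self, X):
        return [normalize_global(rec, self.scale_, self.baseline_window) for rec in X]
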