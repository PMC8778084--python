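"""AERO: address-event-representation encoding of conditioned recordings.

Each (sensor, timepoint) cell of a normalized recording is quantized to one
of ``2**n_bits`` amplitude levels and emitted as an AER event carrying
(timestamp, sensor ID, level).  Level-for-level this is a one-hot-like
layout over (sensor, timepoint, level) *activation bins*; a downstream
spiking classifier learns only from the non-zero bins, since level 0 marks
amplitudes indistinguishable from baseline.

The flattened bin layout is fixed (sensor-major, then time, then level)::

    index = ((sensor_position * T) + t) * levels + level

and versioned as ``aeronose-bins-v1`` so saved models stay portable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .recording import ConditionedRecording

BIN_LAYOUT_VERSION = "aeronose-bins-v1"


@dataclass(frozen=True)
class EncodingConfig:
    """Input-space geometry: quantization depth, recording length, sensors."""

    n_bits: int
    timepoints: int
    sensor_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_bits < 1:
            raise ValueError("n_bits must be >= 1")
        if self.timepoints < 1 or len(self.sensor_ids) < 1:
            raise ValueError("timepoints and sensor count must be >= 1")
        object.__setattr__(self, "sensor_ids", tuple(self.sensor_ids))

    @property
    def levels(self) -> int:
        return 2 ** self.n_bits

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    @property
    def n_bins(self) -> int:
        return self.n_sensors * self.timepoints * self.levels


class AerEvent(NamedTuple):
    t: int  # 0-based timepoint index
    sensor: int  # sensor ID
    level: int  # quantized amplitude in [0, levels - 1]


@dataclass(frozen=True)
class ActivationBins:
    """The non-zero activation bins of one encoded recording."""

    bins: frozenset
    config: EncodingConfig

    def __len__(self) -> int:
        return len(self.bins)


def quantize(x, n_bits: int):
    """Quantize amplitudes in [0, 1] to ``floor(x * 2**n_bits)``, with the
    top of the range clipped to level ``2**n_bits - 1``.  Monotone in x."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("amplitudes must lie in [0, 1]")
    levels = 2 ** n_bits
    q = np.minimum(np.floor(arr * levels).astype(int), levels - 1)
    return int(q) if np.isscalar(x) else q


def encoding_config_for(rec: ConditionedRecording, n_bits: int) -> EncodingConfig:
    return EncodingConfig(
        n_bits=n_bits, timepoints=rec.n_timepoints, sensor_ids=tuple(rec.sensor_ids)
    )


def encode(rec: ConditionedRecording, n_bits: int) -> list[AerEvent]:
    """Emit exactly one event per (sensor, timepoint), ordered by (t, sensor).

    Level-0 events are kept in the stream for timestamp bookkeeping; they are
    dropped only when forming :class:`ActivationBins`.
    """
    q = quantize(rec.values, n_bits)
    return [
        AerEvent(t, sid, int(q[t, s]))
        for t in range(rec.n_timepoints)
        for s, sid in enumerate(rec.sensor_ids)
    ]


def bin_index(sensor_pos: int, t: int, level: int, config: EncodingConfig) -> int:
    """Flattened activation-bin index (layout ``aeronose-bins-v1``)."""
    return ((sensor_pos * config.timepoints) + t) * config.levels + level


def to_bins(events: Sequence[AerEvent], config: EncodingConfig) -> ActivationBins:
    """Collect the non-zero bins of an event stream.

    At most one level may be active per (sensor, timepoint); duplicates
    raise.  Level-0 events are excluded — learning happens on non-zero bins.
    """
    pos = {sid: i for i, sid in enumerate(config.sensor_ids)}
    seen: set[tuple[int, int]] = set()
    active: set[int] = set()
    for ev in events:
        if ev.sensor not in pos:
            raise ValueError(f"event sensor {ev.sensor} not in encoding config")
        if not (0 <= ev.t < config.timepoints and 0 <= ev.level < config.levels):
            raise ValueError(f"event out of range: {ev}")
        key = (ev.sensor, ev.t)
        if key in seen:
            raise ValueError(f"duplicate event for sensor {ev.sensor}, t={ev.t}")
        seen.add(key)
        if ev.level > 0:
            active.add(bin_index(pos[ev.sensor], ev.t, ev.level, config))
    return ActivationBins(bins=frozenset(active), config=config)


def from_bins(bins: ActivationBins, config: EncodingConfig) -> list[AerEvent]:
    """Invert :func:`to_bins` for the non-zero events, ordered by (t, sensor)."""
    events = []
    for idx in bins.bins:
        level = idx % config.levels
        rest = idx // config.levels
        t = rest % config.timepoints
        sensor_pos = rest // config.timepoints
        events.append(AerEvent(t, config.sensor_ids[sensor_pos], level))
    return sorted(events, key=lambda e: (e.t, config.sensor_ids.index(e.sensor)))


def decode(events: Sequence[AerEvent], config: EncodingConfig) -> np.ndarray:
    """Rebuild the quantized level matrix [t, s]; every (t, sensor) pair must
    be present exactly once."""
    pos = {sid: i for i, sid in enumerate(config.sensor_ids)}
    out = np.full((config.timepoints, config.n_sensors), -1, dtype=int)
    for ev in events:
        s = pos.get(ev.sensor)
        if s is None:
            raise ValueError(f"event sensor {ev.sensor} not in encoding config")
        out[ev.t, s] = ev.level
    if np.any(out < 0):
        missing = np.argwhere(out < 0)[0]
        raise ValueError(
            f"missing event for t={missing[0]}, sensor "
            f"{config.sensor_ids[missing[1]]}"
        )
    return out


def max_weight_bound(timepoints: int, levels: int) -> int:
    """Upper bound on synaptic weights per neuron: ``2 * T * levels``."""
    if timepoints < 1 or levels < 1:
        raise ValueError("timepoints and levels must be >= 1")
    return 2 * timepoints * levels


# ---------------------------------------------------------------------------
# Event-stream CSV I/O


def write_events_csv(events: Sequence[AerEvent], config: EncodingConfig, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# aeronose-events v1\n")
        fh.write(f"# layout={BIN_LAYOUT_VERSION}\n")
        fh.write(f"# n_bits={config.n_bits}\n")
        fh.write(f"# timepoints={config.timepoints}\n")
        fh.write("# sensors=" + ",".join(map(str, config.sensor_ids)) + "\n")
        w = csv.writer(fh)
        w.writerow(["t", "sensor", "level"])
        for ev in events:
            w.writerow([ev.t, ev.sensor, ev.level])


def read_events_csv(path) -> tuple[list[AerEvent], EncodingConfig]:
    meta: dict[str, str] = {}
    events: list[AerEvent] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            cells = next(csv.reader([line]))
            if cells[0] == "t":
                continue
            events.append(AerEvent(int(cells[0]), int(cells[1]), int(cells[2])))
    try:
        config = EncodingConfig(
            n_bits=int(meta["n_bits"]),
            timepoints=int(meta["timepoints"]),
            sensor_ids=tuple(int(s) for s in meta["sensors"].split(",")),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing header key {exc}") from None
    return events, config


class AeroEncoder(BaseEstimator, TransformerMixin):
    """Transformer: conditioned recordings -> activation-bin sets."""

    def __init__(self, n_bits: int = 4):
        self.n_bits = n_bits

    def fit(self, X, y=None):
        self.n_fitted_ = len(X)
        return self

    def transform(self, X) -> list[ActivationBins]:
        out = []
        for rec in X:
            cfg = encoding_config_for(rec, self.n_bits)
            out.append(to_bins(encode(rec, self.n_bits), cfg))
        return out
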