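"""Sensor-array recording containers and their plain-text serialisation.

A recording is one sampling cycle of a chemiresistive array: ``T`` timepoints
by ``S`` sensors of resistance values (ohms), sampled at a fixed rate, with
the cycle partitioned into four phases — reference-air baseline, sample
draw-in (the "sniffing" phase), snout removal, and purge.  Conditioned
recordings hold the dimensionless normalized responses in ``[0, 1]``.

The CSV dialect is ``# key=value`` comment headers followed by a
``time_s,S01,...`` table, so files remain inspectable with any text tool.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

#: Phase names in cycle order.
PHASES = ("baseline", "sample_draw", "snout_removal", "purge")

#: Alias used throughout the field for the exposure phase.
SNIFFING_PHASE = "sample_draw"


class RecordingParseError(ValueError):
    """Raised when a recording CSV is malformed; names the offending line."""


def _check_phase_boundaries(boundaries: Sequence[int], n_rows: int) -> tuple[int, ...]:
    b = tuple(int(x) for x in boundaries)
    if len(b) != len(PHASES) + 1:
        raise ValueError(
            f"phase_boundaries must have {len(PHASES) + 1} entries, got {len(b)}"
        )
    if b[0] != 0 or b[-1] != n_rows:
        raise ValueError(
            f"phase_boundaries must start at 0 and end at T={n_rows}, got {b}"
        )
    if any(b[i] > b[i + 1] for i in range(len(b) - 1)):
        raise ValueError(f"phase_boundaries must be non-decreasing, got {b}")
    return b


@dataclass
class RawRecording:
    """One raw sampling cycle: resistance[t, s] in ohms.

    ``phase_boundaries`` holds the five cumulative row indices
    ``(0, t1, t2, t3, T)`` delimiting the four phases.
    """

    sensor_ids: list[int]
    values: np.ndarray
    sampling_rate: float = 1.0
    phase_boundaries: tuple[int, ...] = ()
    label: Optional[str] = None
    replicate_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x S matrix")
        if self.values.shape[1] != len(self.sensor_ids):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.sensor_ids)} sensor IDs"
            )
        if not np.all(self.values > 0):
            raise ValueError("raw resistance values must be strictly positive")
        if not self.phase_boundaries:
            self.phase_boundaries = (0, 0, 0, 0, self.values.shape[0])
        self.phase_boundaries = _check_phase_boundaries(
            self.phase_boundaries, self.values.shape[0]
        )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.values.shape[1]

    def phase_range(self, phase: str) -> tuple[int, int]:
        """Row range [start, stop) of a named phase."""
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
        i = PHASES.index(phase)
        return self.phase_boundaries[i], self.phase_boundaries[i + 1]

    def with_values(self, values: np.ndarray, sensor_ids=None) -> "RawRecording":
        return replace(
            self,
            values=values,
            sensor_ids=list(self.sensor_ids if sensor_ids is None else sensor_ids),
        )


@dataclass
class ConditionedRecording:
    """A normalized recording: dimensionless responses |Rnorm| in [0, 1]."""

    sensor_ids: list[int]
    values: np.ndarray
    mode: str  # "local" or "global"
    sampling_rate: float = 1.0
    phase_boundaries: tuple[int, ...] = ()
    label: Optional[str] = None
    replicate_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x S matrix")
        if self.values.shape[1] != len(self.sensor_ids):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.sensor_ids)} sensor IDs"
            )
        if self.mode not in ("local", "global"):
            raise ValueError(f"mode must be 'local' or 'global', got {self.mode!r}")
        lo, hi = self.values.min(initial=0.0), self.values.max(initial=0.0)
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValueError(f"conditioned values must lie in [0, 1]; range [{lo}, {hi}]")
        if not self.phase_boundaries:
            self.phase_boundaries = (0, 0, 0, 0, self.values.shape[0])
        self.phase_boundaries = _check_phase_boundaries(
            self.phase_boundaries, self.values.shape[0]
        )

    n_timepoints = RawRecording.n_timepoints
    n_sensors = RawRecording.n_sensors
    phase_range = RawRecording.phase_range


@dataclass
class NormalizationScale:
    """Per-sensor reference values used by min–max normalization.

    In *local* mode, ``rmin``/``rmax`` are a single sample's per-sensor
    extremes and ``r0`` the baseline reference of that sample.  In *global*
    mode they are the extremes across every timepoint of every recording the
    scale was fitted on; ``r0`` is ``None`` because the baseline average is
    taken per recording at transform time.
    """

    mode: str
    sensor_ids: list[int]
    rmin: np.ndarray
    rmax: np.ndarray
    r0: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rmin = np.asarray(self.rmin, dtype=float)
        self.rmax = np.asarray(self.rmax, dtype=float)
        if self.r0 is not None:
            self.r0 = np.asarray(self.r0, dtype=float)
        arrays = [self.rmin, self.rmax] + ([self.r0] if self.r0 is not None else [])
        for a in arrays:
            if a.shape != (len(self.sensor_ids),):
                raise ValueError("scale arrays must be one value per sensor")
            if not np.all(np.isfinite(a)):
                raise ValueError("scale entries must be finite")
        if np.any(self.rmax < self.rmin):
            raise ValueError("rmax must be >= rmin elementwise")


# ---------------------------------------------------------------------------
# CSV I/O

_FORMAT_TAG = "aeronose-recording v1"


def _sensor_col(sid: int) -> str:
    return f"S{sid:02d}"


def _format_header(rec) -> list[str]:
    lines = [f"# {_FORMAT_TAG}"]
    if isinstance(rec, ConditionedRecording):
        lines.append(f"# mode={rec.mode}")
    if rec.label is not None:
        lines.append(f"# label={rec.label}")
    if rec.replicate_id is not None:
        lines.append(f"# replicate_id={rec.replicate_id}")
    lines.append(f"# sampling_rate={rec.sampling_rate!r}")
    lines.append("# phase_boundaries=" + ",".join(map(str, rec.phase_boundaries)))
    return lines


def write_recording_csv(rec, path) -> None:
    """Write a raw or conditioned recording in the commented-header dialect."""
    cols = ["time_s"] + [_sensor_col(s) for s in rec.sensor_ids]
    times = np.arange(rec.n_timepoints) / rec.sampling_rate
    with open(path, "w", newline="") as fh:
        for line in _format_header(rec):
            fh.write(line + "\n")
        w = csv.writer(fh)
        w.writerow(cols)
        for t, row in zip(times, rec.values):
            w.writerow([repr(float(t))] + [repr(float(v)) for v in row])


def read_recording_csv(path):
    """Read a recording written by :func:`write_recording_csv`.

    Returns a :class:`RawRecording` or, when the header carries a ``mode``
    key, a :class:`ConditionedRecording`.  Malformed headers or ragged rows
    raise :class:`RecordingParseError` naming the line number.
    """
    meta: dict[str, str] = {}
    header_cols: Optional[list[str]] = None
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            cells = next(csv.reader([line]))
            if header_cols is None:
                header_cols = cells
                if not header_cols or header_cols[0] != "time_s":
                    raise RecordingParseError(
                        f"{path}, line {lineno}: expected 'time_s' as first column"
                    )
                continue
            if len(cells) != len(header_cols):
                raise RecordingParseError(
                    f"{path}, line {lineno}: expected {len(header_cols)} fields, "
                    f"got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells[1:]])
            except ValueError as exc:
                raise RecordingParseError(
                    f"{path}, line {lineno}: non-numeric value ({exc})"
                ) from None
    if header_cols is None or not rows:
        raise RecordingParseError(f"{path}: no data rows found")
    try:
        sensor_ids = [int(c.lstrip("S")) for c in header_cols[1:]]
    except ValueError:
        raise RecordingParseError(f"{path}: malformed sensor column names") from None
    values = np.asarray(rows, dtype=float)
    common = dict(
        sensor_ids=sensor_ids,
        values=values,
        sampling_rate=float(meta.get("sampling_rate", 1.0)),
        phase_boundaries=tuple(
            int(x) for x in meta["phase_boundaries"].split(",")
        )
        if "phase_boundaries" in meta
        else (),
        label=meta.get("label"),
        replicate_id=int(meta["replicate_id"]) if "replicate_id" in meta else None,
    )
    if "mode" in meta:
        return ConditionedRecording(mode=meta["mode"], **common)
    return RawRecording(**common)


def write_scale_csv(scale: NormalizationScale, path) -> None:
    """Serialize a normalization scale as ``sensor,r0,rmin,rmax``."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# {_FORMAT_TAG.replace('recording', 'scale')}\n")
        fh.write(f"# mode={scale.mode}\n")
        w = csv.writer(fh)
        w.writerow(["sensor", "r0", "rmin", "rmax"])
        for i, sid in enumerate(scale.sensor_ids):
            r0 = "" if scale.r0 is None else repr(float(scale.r0[i]))
            w.writerow([sid, r0, repr(float(scale.rmin[i])), repr(float(scale.rmax[i]))])


def read_scale_csv(path) -> NormalizationScale:
    mode = "local"
    sensors: list[int] = []
    r0: list[float] = []
    rmin: list[float] = []
    rmax: list[float] = []
    has_r0 = True
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("mode="):
                    mode = body.split("=", 1)[1]
                continue
            cells = next(csv.reader([line]))
            if cells[0] == "sensor":
                continue
            sensors.append(int(cells[0]))
            if cells[1] == "":
                has_r0 = False
            else:
                r0.append(float(cells[1]))
            rmin.append(float(cells[2]))
            rmax.append(float(cells[3]))
    return NormalizationScale(
        mode=mode,
        sensor_ids=sensors,
        rmin=np.array(rmin),
        rmax=np.array(rmax),
        r0=np.array(r0) if has_r0 else None,
    )
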