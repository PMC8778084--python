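"""Synthetic chemiresistive sensor-array recordings.

Emulates headspace sampling cycles of a 32-sensor polymer-composite array:
each odor class is a *smell-print* — a per-sensor vector of maximal
fractional resistance changes — and each replicate is a noisy realisation of
the class's first-order response envelope (flat baseline, exponential rise
to a plateau during sample draw-in, exponential recovery), plus additive
Gaussian noise and a slow linear drift.

Humidity-sensitive channels carry a class-independent response so that
excluding them downstream is meaningful.  Everything is deterministic given
the master seed; per-replicate seeds are derived with
``numpy.random.SeedSequence([master, class_index, replicate])`` so any single
file can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .recording import PHASES, RawRecording, read_recording_csv, write_recording_csv

__all__ = [
    "SimulationConfig",
    "ClassProfile",
    "make_class_profiles",
    "response_envelope",
    "simulate_recording",
    "generate_dataset",
    "write_recording_csv",
    "read_recording_csv",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow the acquisition protocol of a portable e-nose sampling
    cycle: 15 s baseline, 50 s sample draw-in, 5 s snout removal, 20 s purge
    at 1 Hz (90 rows), 32 sensors of which four humidity-sensitive channels
    {5, 6, 23, 31} (1-based IDs) are candidates for exclusion, and 8 odor
    classes with 9 replicates each.
    """

    n_classes: int = 8
    n_sensors: int = 32
    replicates_per_class: int = 9
    sampling_rate: float = 1.0
    phase_durations: tuple[float, float, float, float] = (15.0, 50.0, 5.0, 20.0)
    baseline_level: float = 10_000.0
    noise_sd: float = 0.0075
    drift_slope: float = 1e-5
    class_separation: float = 1.0
    overlap_pairs: tuple[tuple[int, int], ...] = ((6, 7),)
    overlap_fraction: float = 0.15
    delta_scale: float = 0.15
    delta_max: float = 0.5
    excluded_sensor_ids: tuple[int, ...] = (5, 6, 23, 31)
    class_labels: Optional[list[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_sensors < 1 or self.replicates_per_class < 1:
            raise ValueError("n_classes, n_sensors and replicates_per_class must be >= 1")
        if any(d < 0 for d in self.phase_durations):
            raise ValueError("phase durations must be >= 0")
        if self.noise_sd < 0 or self.class_separation < 0:
            raise ValueError("noise_sd and class_separation must be >= 0")
        total = sum(self.phase_durations) * self.sampling_rate
        if total <= 0 or abs(total - round(total)) > 1e-9:
            raise ValueError(
                "total duration x sampling_rate must be a positive integer"
            )
        if self.class_labels is not None and len(self.class_labels) != self.n_classes:
            raise ValueError("class_labels must have n_classes entries")

    @property
    def n_timepoints(self) -> int:
        return int(round(sum(self.phase_durations) * self.sampling_rate))

    @property
    def phase_boundaries(self) -> tuple[int, ...]:
        edges = np.cumsum((0.0,) + self.phase_durations) * self.sampling_rate
        return tuple(int(round(e)) for e in edges)

    @property
    def sensor_ids(self) -> list[int]:
        return list(range(1, self.n_sensors + 1))

    def labels(self) -> list[str]:
        if self.class_labels is not None:
            return list(self.class_labels)
        return [f"class_{i}" for i in range(self.n_classes)]


@dataclass
class ClassProfile:
    """Per-class response signature: maximal fractional resistance change per
    sensor (may be negative) and first-order rise/decay time constants."""

    class_id: str
    delta: np.ndarray
    rise_tau: float
    decay_tau: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")


def make_class_profiles(config: SimulationConfig) -> list[ClassProfile]:
    """Draw one response signature per class.

    Class signatures share a common base pattern and diverge by
    ``class_separation`` times a per-class random direction, so the expected
    pairwise distance between signatures scales linearly with
    ``class_separation`` (zero separation makes all classes identical).
    Pairs listed in ``overlap_pairs`` are drawn at ``overlap_fraction`` of
    that divergence from each other, emulating aroma profiles that overlap
    instrumentally.  Humidity-sensitive channels get a class-independent
    signature.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    s = config.n_sensors
    base = rng.uniform(-0.15, 0.25, size=s)
    humidity = rng.uniform(0.05, 0.2, size=s)  # shared across classes
    humidity_pos = [sid - 1 for sid in config.excluded_sensor_ids if sid <= s]

    offsets = rng.normal(size=(config.n_classes, s))
    offsets /= np.linalg.norm(offsets, axis=1, keepdims=True)
    taus = rng.uniform(5.0, 10.0, size=config.n_classes)
    decays = rng.uniform(8.0, 15.0, size=config.n_classes)

    # offsets are unit-norm, so inter-class delta distances scale as
    # sqrt(2) * class_separation * delta_scale
    scale = config.class_separation * config.delta_scale
    deltas = base + scale * offsets
    # overlapping pairs: second member re-centred near the first
    for a, b in config.overlap_pairs:
        if a < config.n_classes and b < config.n_classes:
            deltas[b] = base + scale * (
                offsets[a] + config.overlap_fraction * offsets[b]
            )
    deltas = np.clip(deltas, -config.delta_max, config.delta_max)
    deltas[:, humidity_pos] = humidity[humidity_pos]

    labels = config.labels()
    return [
        ClassProfile(labels[c], deltas[c], float(taus[c]), float(decays[c]))
        for c in range(config.n_classes)
    ]


def response_envelope(
    times: np.ndarray,
    phase_edges_s: Sequence[float],
    baseline: float,
    delta: np.ndarray,
    rise_tau: float,
    decay_tau: float,
) -> np.ndarray:
    """Noise-free resistance envelope R[t, s].

    Flat at ``baseline`` during the reference phase; first-order exponential
    approach (time constant ``rise_tau``) toward ``baseline * (1 + delta)``
    during sample draw-in; first-order return toward baseline (``decay_tau``)
    from snout removal onward.
    """
    t = np.asarray(times, dtype=float)[:, None]
    delta = np.asarray(delta, dtype=float)[None, :]
    t1, t2 = float(phase_edges_s[1]), float(phase_edges_s[2])
    frac = np.zeros((t.shape[0], delta.shape[1]))
    rising = (t >= t1) & (t < t2)
    frac = np.where(rising, delta * (1.0 - np.exp(-(t - t1) / rise_tau)), frac)
    frac_end = delta * (1.0 - np.exp(-(t2 - t1) / rise_tau))
    frac = np.where(t >= t2, frac_end * np.exp(-(t - t2) / decay_tau), frac)
    return baseline * (1.0 + frac)


def simulate_recording(
    profile: ClassProfile,
    config: SimulationConfig,
    replicate_seed: int,
    replicate_id: int = 0,
) -> RawRecording:
    """One noisy realisation of a class profile.

    Additive Gaussian noise has standard deviation ``noise_sd * baseline``;
    drift adds ``baseline * drift_slope * t`` to every channel.
    """
    rng = np.random.default_rng(replicate_seed)
    T = config.n_timepoints
    times = np.arange(T) / config.sampling_rate
    edges_s = np.cumsum((0.0,) + config.phase_durations)
    clean = response_envelope(
        times, edges_s, config.baseline_level, profile.delta,
        profile.rise_tau, profile.decay_tau,
    )
    drift = config.baseline_level * config.drift_slope * times[:, None]
    noise = rng.normal(0.0, config.noise_sd * config.baseline_level, size=clean.shape)
    values = np.maximum(clean + drift + noise, 1e-6)  # resistances stay positive
    return RawRecording(
        sensor_ids=config.sensor_ids,
        values=values,
        sampling_rate=config.sampling_rate,
        phase_boundaries=config.phase_boundaries,
        label=profile.class_id,
        replicate_id=replicate_id,
    )


def replicate_seed(master_seed: int, class_index: int, rep: int) -> int:
    """Documented per-file seed derivation (stable across runs/platforms)."""
    ss = np.random.SeedSequence([master_seed, class_index, rep])
    return int(ss.generate_state(1)[0] & 0x7FFF_FFFF)


def generate_dataset(
    config: SimulationConfig,
    profiles: Optional[list[ClassProfile]] = None,
) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate ``replicates_per_class`` recordings per class plus a manifest.

    The manifest has columns ``file, label, replicate, seed``; file names are
    what :func:`write_dataset` would use, so the manifest doubles as an index
    for on-disk datasets.
    """
    if profiles is None:
        profiles = make_class_profiles(config)
    recordings: list[RawRecording] = []
    rows = []
    for ci, prof in enumerate(profiles):
        for rep in range(config.replicates_per_class):
            seed = replicate_seed(config.seed, ci, rep)
            rec = simulate_recording(prof, config, seed, replicate_id=rep)
            recordings.append(rec)
            rows.append(
                {
                    "file": f"{prof.class_id}_r{rep:02d}.csv",
                    "label": prof.class_id,
                    "replicate": rep,
                    "seed": seed,
                }
            )
    return recordings, pd.DataFrame(rows)


def write_dataset(recordings, manifest: pd.DataFrame, out_dir) -> None:
    """Write every recording plus ``manifest.csv`` into a directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for rec, fname in zip(recordings, manifest["file"]):
        write_recording_csv(rec, os.path.join(out_dir, fname))
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)


def read_dataset(in_dir) -> tuple[list[RawRecording], pd.DataFrame]:
    """Read a directory written by :func:`write_dataset`."""
    import os

    manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"))
    recs = [read_recording_csv(os.path.join(in_dir, f)) for f in manifest["file"]]
    return recs, manifest
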