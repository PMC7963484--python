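"""Stochastic generation of spontaneous L- and H-event trains.

Two renewal processes drive the model: local L-events activate a contiguous
block of thalamic cells at a fixed binary amplitude, while global H-events
set the intrinsic rate of most cortical cells.  Event sizes are drawn as a
uniform fraction of the layer, durations are Gaussian, and inter-event
intervals follow an exponential (L) or Gamma (H) distribution.  All defaults
are the model-time values (10x shorter than in vivo) used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventTrainConfig",
    "SpontEvent",
    "EventSchedule",
    "sample_onsets",
    "sample_event",
    "build_schedule",
]

#: minimum duration, as a fraction of the mean, at which Gaussian draws are cut
_DUR_TRUNC_FRAC = 0.1


@dataclass(frozen=True)
class EventTrainConfig:
    """Parameters of the L- and H-event trains and layer sizes."""

    n_thal: int = 50
    n_ctx: int = 50
    horizon: float = 50_000.0
    # L-events (thalamic layer)
    l_amp: float = 1.0
    l_pct_range: tuple[float, float] = (0.2, 0.8)
    l_dur_mean: float = 0.15
    l_dur_sd: float = 0.015
    l_int_mean: float = 1.5
    # H-events (cortical layer)
    h_amp_mean: float = 6.0
    h_pct_range: tuple[float, float] = (0.8, 1.0)
    h_dur_mean: float = 0.15
    h_dur_sd: float = 0.015
    h_int_shape: float = 3.5
    h_int_scale: float = 1.0
    h_geometry: Literal["block", "random"] = "block"
    #: replace sampled inter-event intervals by their means (regular trains)
    fixed_intervals: bool = False
    #: disable one of the trains entirely
    l_enabled: bool = True
    h_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_thal <= 0 or self.n_ctx <= 0:
            raise ValueError("layer sizes must be positive")
        if self.horizon < 0:
            raise ValueError("horizon must be non-negative")
        for name in ("l_dur_mean", "l_int_mean", "h_dur_mean",
                     "h_int_shape", "h_int_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.h_amp_mean <= 0:
            raise ValueError("h_amp_mean must be positive")
        for name in ("l_pct_range", "h_pct_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= 1")

    @property
    def h_int_mean(self) -> float:
        return self.h_int_shape * self.h_int_scale

    def with_h_int_mean(self, mean: float) -> "EventTrainConfig":
        """Return a copy with the Gamma scale set so E[Hint] = ``mean``."""
        if mean <= 0:
            raise ValueError("mean must be positive")
        return replace(self, h_int_scale=mean / self.h_int_shape)


@dataclass(frozen=True)
class SpontEvent:
    """A single spontaneous event.

    ``start_index``/``size`` describe the contiguous participating block with
    periodic wrap; ``members`` overrides the block when a scattered H-event
    geometry is requested.
    """

    kind: Literal["L", "H"]
    onset: float
    duration: float
    amplitude: float
    start_index: int
    size: int
    members: tuple[int, ...] | None = None

    @property
    def end(self) -> float:
        return self.onset + self.duration

    def indices(self, layer_size: int) -> np.ndarray:
        """Participating unit indices on the periodic layer."""
        if self.members is not None:
            return np.asarray(self.members, dtype=np.intp)
        return (self.start_index + np.arange(self.size)) % layer_size


@dataclass(frozen=True)
class EventSchedule:
    """Time-sorted union of the L- and H-event trains."""

    events: tuple[SpontEvent, ...]
    horizon: float

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, kind: str) -> tuple[SpontEvent, ...]:
        return tuple(e for e in self.events if e.kind == kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [e.kind for e in self.events],
                "onset_s": [e.onset for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "amplitude": [e.amplitude for e in self.events],
                "start_index": [e.start_index for e in self.events],
                "size": [e.size for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, horizon: float) -> "EventSchedule":
        events = tuple(
            SpontEvent(
                kind=str(row.kind),
                onset=float(row.onset_s),
                duration=float(row.duration_s),
                amplitude=float(row.amplitude),
                start_index=int(row.start_index),
                size=int(row.size),
            )
            for row in df.itertuples()
        )
        return cls(events=events, horizon=horizon)

    @classmethod
    def from_csv(cls, path, horizon: float) -> "EventSchedule":
        return cls.from_frame(pd.read_csv(path), horizon)


def sample_onsets(
    dist: Sequence, horizon: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample onset times of a renewal process on ``[0, horizon)``.

    ``dist`` is ``("exponential", mean)``, ``("gamma", shape, scale)`` or
    ``("fixed", interval)``.  Successive onsets are separated by i.i.d.
    inter-event intervals; the first onset is one interval after time 0.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    name = dist[0]
    if name == "exponential":
        (mean,) = dist[1:]
        draw = lambda n: rng.exponential(mean, n)  # noqa: E731
        exp_iei = mean
    elif name == "gamma":
        shape, scale = dist[1:]
        draw = lambda n: rng.gamma(shape, scale, n)  # noqa: E731
        exp_iei = shape * scale
    elif name == "fixed":
        (interval,) = dist[1:]
        draw = lambda n: np.full(n, float(interval))  # noqa: E731
        exp_iei = interval
    else:
        raise ValueError(f"unknown interval distribution {name!r}")
    if horizon == 0:
        return np.empty(0)
    onsets: list[np.ndarray] = []
    t = 0.0
    # draw in chunks sized from the expected count
    chunk = max(16, int(1.2 * horizon / exp_iei) + 16)
    while t < horizon:
        ieis = draw(chunk)
        ts = t + np.cumsum(ieis)
        onsets.append(ts[ts < horizon])
        t = ts[-1]
    return np.concatenate(onsets) if onsets else np.empty(0)


def sample_event(
    cfg: EventTrainConfig,
    kind: Literal["L", "H"],
    onset: float,
    rng: np.random.Generator,
) -> SpontEvent:
    """Draw size, position, duration and amplitude of one event."""
    if kind == "L":
        layer, pct = cfg.n_thal, cfg.l_pct_range
        dur_mean, dur_sd = cfg.l_dur_mean, cfg.l_dur_sd
    elif kind == "H":
        layer, pct = cfg.n_ctx, cfg.h_pct_range
        dur_mean, dur_sd = cfg.h_dur_mean, cfg.h_dur_sd
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    if onset < 0:
        raise ValueError("onset must be non-negative")

    p = rng.uniform(*pct)
    size = int(round(p * layer))
    if size < 1:
        raise ValueError(
            f"participation range {pct} yields zero participating units"
        )
    start = int(rng.integers(layer))
    members: tuple[int, ...] | None = None
    if kind == "H" and cfg.h_geometry == "random":
        members = tuple(
            int(i) for i in rng.choice(layer, size=size, replace=False)
        )
    duration = max(
        float(rng.normal(dur_mean, dur_sd)), _DUR_TRUNC_FRAC * dur_mean
    )
    if kind == "L":
        amplitude = cfg.l_amp
    else:
        amplitude = max(
            float(rng.normal(cfg.h_amp_mean, cfg.h_amp_mean / 3.0)), 0.0
        )
    return SpontEvent(
        kind=kind,
        onset=float(onset),
        duration=duration,
        amplitude=amplitude,
        start_index=start,
        size=size,
        members=members,
    )


@dataclass
class TrainArrays:
    """Columnar representation of one event train (simulator fast path)."""

    kind: str
    onset: np.ndarray
    duration: np.ndarray
    amplitude: np.ndarray
    start: np.ndarray
    size: np.ndarray
    members: list | None = None  # per-event index arrays (scattered H only)

    @property
    def end(self) -> np.ndarray:
        return self.onset + self.duration

    def flat_indices(self, layer: int) -> tuple[np.ndarray, np.ndarray]:
        """(offsets, flat) participating-index arrays for all events."""
        n = self.onset.size
        offsets = np.zeros(n + 1, dtype=np.int64)
        if n == 0:
            return offsets, np.empty(0, dtype=np.int64)
        if self.members is not None:
            offsets[1:] = np.cumsum([len(m) for m in self.members])
            flat = np.concatenate(self.members).astype(np.int64)
            return offsets, flat
        sizes = self.size.astype(np.int64)
        offsets[1:] = np.cumsum(sizes)
        within = np.arange(offsets[-1]) - np.repeat(offsets[:-1], sizes)
        flat = (np.repeat(self.start.astype(np.int64), sizes) + within) % layer
        return offsets, flat


def _sample_train_arrays(
    cfg: EventTrainConfig,
    kind: Literal["L", "H"],
    dist: Sequence,
    rng: np.random.Generator,
) -> TrainArrays:
    """Vectorized sampling of one train, with within-train collisions
    resolved by delaying an onset to the previous event's end."""
    if kind == "L":
        layer, pct = cfg.n_thal, cfg.l_pct_range
        dur_mean, dur_sd = cfg.l_dur_mean, cfg.l_dur_sd
    else:
        layer, pct = cfg.n_ctx, cfg.h_pct_range
        dur_mean, dur_sd = cfg.h_dur_mean, cfg.h_dur_sd

    onsets = sample_onsets(dist, cfg.horizon, rng)
    n = onsets.size
    p = rng.uniform(pct[0], pct[1], n)
    sizes = np.round(p * layer).astype(np.int64)
    if n and sizes.min() < 1:
        raise ValueError(
            f"participation range {pct} yields zero participating units"
        )
    starts = rng.integers(layer, size=n)
    durations = np.maximum(
        rng.normal(dur_mean, dur_sd, n), _DUR_TRUNC_FRAC * dur_mean
    )
    if kind == "L":
        amps = np.full(n, cfg.l_amp)
    else:
        amps = np.maximum(
            rng.normal(cfg.h_amp_mean, cfg.h_amp_mean / 3.0, n), 0.0
        )
    members = None
    if kind == "H" and cfg.h_geometry == "random":
        members = [
            rng.choice(layer, size=int(s), replace=False) for s in sizes
        ]
    # sequential collision fix: events of one train never coexist
    keep = np.ones(n, dtype=bool)
    prev_end = -np.inf
    on = onsets.copy()
    for k in range(n):
        o = on[k] if on[k] >= prev_end else prev_end
        if o >= cfg.horizon:
            keep[k] = False
            continue
        on[k] = o
        prev_end = o + durations[k]
    if not keep.all():
        on, durations, amps = on[keep], durations[keep], amps[keep]
        starts, sizes = starts[keep], sizes[keep]
        if members is not None:
            members = [m for m, k in zip(members, keep) if k]
    return TrainArrays(
        kind=kind, onset=on, duration=durations, amplitude=amps,
        start=starts, size=sizes, members=members,
    )


def build_schedule_arrays(
    cfg: EventTrainConfig, rng: np.random.Generator
) -> tuple[TrainArrays, TrainArrays]:
    """Sample both trains in columnar form (L first, then H)."""
    if cfg.l_enabled:
        dist = (
            ("fixed", cfg.l_int_mean)
            if cfg.fixed_intervals
            else ("exponential", cfg.l_int_mean)
        )
        l_train = _sample_train_arrays(cfg, "L", dist, rng)
    else:
        empty = np.empty(0)
        l_train = TrainArrays("L", empty, empty, empty,
                              empty.astype(int), empty.astype(int))
    if cfg.h_enabled:
        dist = (
            ("fixed", cfg.h_int_mean)
            if cfg.fixed_intervals
            else ("gamma", cfg.h_int_shape, cfg.h_int_scale)
        )
        h_train = _sample_train_arrays(cfg, "H", dist, rng)
    else:
        empty = np.empty(0)
        h_train = TrainArrays("H", empty, empty, empty,
                              empty.astype(int), empty.astype(int))
    return l_train, h_train


def _train_events(train: TrainArrays) -> list[SpontEvent]:
    return [
        SpontEvent(
            kind=train.kind,
            onset=float(train.onset[k]),
            duration=float(train.duration[k]),
            amplitude=float(train.amplitude[k]),
            start_index=int(train.start[k]),
            size=int(train.size[k]),
            members=(
                tuple(int(i) for i in train.members[k])
                if train.members is not None
                else None
            ),
        )
        for k in range(train.onset.size)
    ]


def build_schedule(
    cfg: EventTrainConfig, rng: np.random.Generator
) -> EventSchedule:
    """Sample both trains and merge them into a time-sorted schedule.

    The L- and H-trains are independent renewal processes; events from
    different trains may overlap and their drives superpose downstream.
    """
    l_train, h_train = build_schedule_arrays(cfg, rng)
    events = _train_events(l_train) + _train_events(h_train)
    events.sort(key=lambda e: e.onset)
    return EventSchedule(events=tuple(events), horizon=cfg.horizon)
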