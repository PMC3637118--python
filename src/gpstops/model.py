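"""Core trajectory data model.

A *track* is an ordered sequence of timestamped GPS fixes belonging to one
device/person.  All detection math in this package operates on planar
coordinates in meters; geographic (lon/lat) tracks are projected at the I/O
boundary (:mod:`gpstops.io`).  Timestamps are POSIX epoch seconds (UTC)
internally; files use ISO-8601.

Synthetic tracks carry a :class:`TrackTruth` describing the ground-truth
stops (center, arrival, departure) and the per-track GPS noise magnitude,
which is what the benchmark scores detectors against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GpsFix",
    "TrueStop",
    "TrackTruth",
    "Track",
    "Visit",
    "DetectedStop",
]


@dataclass(frozen=True)
class GpsFix:
    """A single timestamped position record.

    ``x``/``y`` are planar easting/northing in meters; ``lon``/``lat`` are
    present only for tracks read from or destined for geographic formats.
    """

    t: float
    x: Optional[float] = None
    y: Optional[float] = None
    lon: Optional[float] = None
    lat: Optional[float] = None


@dataclass(frozen=True)
class TrueStop:
    """Ground-truth stop: center (m) and exact arrival/departure times (s)."""

    cx: float
    cy: float
    t_arrive: float
    t_depart: float

    def __post_init__(self) -> None:
        if not self.t_depart > self.t_arrive:
            raise ValueError(
                f"stop departure ({self.t_depart}) must be after arrival "
                f"({self.t_arrive})"
            )

    @property
    def duration(self) -> float:
        """True duration of stay in seconds."""
        return self.t_depart - self.t_arrive


@dataclass
class TrackTruth:
    """Ground truth attached to a synthetic track.

    ``noise_m`` is the per-axis standard deviation of the Gaussian positional
    noise applied to the track's fixes, drawn once per track.  ``seed`` is the
    index used to derive the track's RNG substream (None for truths read back
    from files, where it is not persisted).
    """

    stops: tuple[TrueStop, ...]
    noise_m: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.stops = tuple(self.stops)
        if not self.stops:
            raise ValueError("truth must contain at least one stop")
        if self.noise_m < 0:
            raise ValueError("noise magnitude must be non-negative")
        for a, b in zip(self.stops, self.stops[1:]):
            if b.t_arrive < a.t_depart:
                raise ValueError("true stop time windows must be ordered and disjoint")

    @property
    def centers(self) -> np.ndarray:
        """(n_stops, 2) array of stop centers."""
        return np.array([(s.cx, s.cy) for s in self.stops], dtype=float)

    def min_pairwise_distance(self) -> float:
        """Smallest distance between any two true stop centers (inf if single)."""
        c = self.centers
        if len(c) < 2:
            return float("inf")
        d = np.hypot(c[:, None, 0] - c[None, :, 0], c[:, None, 1] - c[None, :, 1])
        iu = np.triu_indices(len(c), k=1)
        return float(d[iu].min())


@dataclass
class Track:
    """An ordered sequence of fixes, stored as parallel NumPy arrays.

    Invariants: at least two fixes, strictly increasing finite timestamps,
    and at least one complete coordinate set (planar x/y or geographic
    lon/lat) with all-finite values.
    """

    id: str
    t: np.ndarray
    x: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    lon: Optional[np.ndarray] = None
    lat: Optional[np.ndarray] = None
    truth: Optional[TrackTruth] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("x", "y", "lon", "lat"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if v.shape != self.t.shape:
                    raise ValueError(f"track {self.id!r}: {name} shape mismatch")
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"track {self.id!r}: non-finite {name}")
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError(f"track {self.id!r}: need at least 2 fixes")
        if not np.all(np.isfinite(self.t)):
            raise ValueError(f"track {self.id!r}: non-finite timestamps")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError(f"track {self.id!r}: timestamps not strictly increasing")
        if not (self.has_planar or self.has_geographic):
            raise ValueError(f"track {self.id!r}: no complete coordinate set")

    @property
    def has_planar(self) -> bool:
        return self.x is not None and self.y is not None

    @property
    def has_geographic(self) -> bool:
        return self.lon is not None and self.lat is not None

    def __len__(self) -> int:
        return len(self.t)

    def fix(self, i: int) -> GpsFix:
        """Materialize fix ``i`` as a :class:`GpsFix`."""
        return GpsFix(
            t=float(self.t[i]),
            x=None if self.x is None else float(self.x[i]),
            y=None if self.y is None else float(self.y[i]),
            lon=None if self.lon is None else float(self.lon[i]),
            lat=None if self.lat is None else float(self.lat[i]),
        )


@dataclass(frozen=True)
class Visit:
    """One continuous period of stay attributed to a detected stop."""

    t_start: float
    t_end: float
    n_fixes: int

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("visit must have t_end >= t_start")
        if self.n_fixes < 1:
            raise ValueError("visit must contain at least one fix")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class DetectedStop:
    """Algorithm output: a stop location plus its timetable of visits.

    ``total_duration`` (the detector's duration estimate, Δ_found) is defined
    as the sum of visit durations and exposed as a property so the invariant
    cannot drift.
    """

    x: float
    y: float
    visits: tuple[Visit, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.visits = tuple(self.visits)
        if not self.visits:
            raise ValueError("detected stop must have at least one visit")

    @property
    def total_duration(self) -> float:
        return float(sum(v.duration for v in self.visits))

    @property
    def n_fixes(self) -> int:
        return int(sum(v.n_fixes for v in self.visits))

    @property
    def t_first(self) -> float:
        return min(v.t_start for v in self.visits)


def as_tracks(tracks: Sequence[Track] | Track) -> list[Track]:
    """Normalize a single track or a sequence of tracks to a list."""
    if isinstance(tracks, Track):
        return [tracks]
    return list(tracks)
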