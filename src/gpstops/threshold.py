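"""Classical fixed-threshold stop detector (sequential time-distance clustering).

The detector scans fixes in time order and groups consecutive fixes that
remain within a *roaming radius* of a reference point; a group whose time
span (first to last fix) reaches the minimal stay duration is emitted as a
stop at the group centroid.

Three classical disciplines are provided.  The default, ``"first"``, grows
one cluster at a time, testing each fix against the cluster's first fix,
and restarts at the breaking fix.  ``"centroid"`` does the same against
the running centroid.  ``"window"`` is the sliding stay-point window: when
a candidate window fails the duration test the scan advances by a single
fix, so overlapping windows are tried from every start point.

All variants are deliberately minimal baselines: no outlier buffer (a
single excursion splits a stay in two — the documented
duration-underestimation failure mode) and no merging of successive stops
with nearby centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import hypot

from .model import DetectedStop, Track, Visit

__all__ = ["FtParams", "detect_stops_ft"]


@dataclass(frozen=True)
class FtParams:
    """Parameters of the fixed-threshold detector.

    Attributes
    ----------
    roaming_radius : distance threshold d (m) a fix may roam from the
        cluster reference point.
    min_stop_duration : minimal time (s) between a cluster's first and last
        fix to qualify as a stop (default 5 min).
    membership : clustering discipline —
        ``"first"`` (default): grow-and-reset; fixes join while within the
        radius of the *cluster's first fix*; a breaking fix closes the
        cluster (emitted if its span is long enough) and starts a new one;
        ``"centroid"``: grow-and-reset against the running centroid;
        ``"window"``: sliding stay-point window testing against the
        window's first fix, advancing the start by a single fix whenever a
        window fails the duration test.
    """

    roaming_radius: float
    min_stop_duration: float = 300.0
    membership: str = "first"

    def __post_init__(self) -> None:
        if self.roaming_radius <= 0:
            raise ValueError("roaming_radius must be positive")
        if self.min_stop_duration <= 0:
            raise ValueError("min_stop_duration must be positive")
        if self.membership not in ("window", "centroid", "first"):
            raise ValueError("membership must be 'window', 'centroid' or 'first'")


def detect_stops_ft(track: Track, params: FtParams) -> list[DetectedStop]:
    """Run sequential time-distance clustering on one planar track.

    Emitted stops are located at the cluster centroid and carry a single
    visit spanning the cluster's first to last fix.
    """
    if not track.has_planar:
        raise ValueError(f"track {track.id!r}: planar coordinates required")
    if params.membership == "window":
        return _detect_window(track, params)
    return _detect_grow_reset(track, params)


def _detect_window(track: Track, params: FtParams) -> list[DetectedStop]:
    """Sliding stay-point window: advance the start fix by one on failure."""
    x, y, t = track.x, track.y, track.t
    d = params.roaming_radius
    min_dur = params.min_stop_duration
    n = len(track)
    stops: list[DetectedStop] = []
    i = 0
    while i < n:
        xi, yi = float(x[i]), float(y[i])
        j = i
        while j + 1 < n and hypot(float(x[j + 1]) - xi, float(y[j + 1]) - yi) <= d:
            j += 1
        if t[j] - t[i] >= min_dur:
            sl = slice(i, j + 1)
            stops.append(
                DetectedStop(
                    x=float(x[sl].mean()),
                    y=float(y[sl].mean()),
                    visits=(
                        Visit(t_start=float(t[i]), t_end=float(t[j]),
                              n_fixes=j - i + 1),
                    ),
                )
            )
            i = j + 1
        else:
            i += 1
    return stops


def _detect_grow_reset(track: Track, params: FtParams) -> list[DetectedStop]:
    """Grow a cluster until a fix breaks the radius, then flush and restart."""
    x, y, t = track.x, track.y, track.t
    d = params.roaming_radius
    min_dur = params.min_stop_duration
    by_centroid = params.membership == "centroid"

    stops: list[DetectedStop] = []
    start = 0
    sx, sy, n = float(x[0]), float(y[0]), 1

    def flush(last: int) -> None:
        if t[last] - t[start] >= min_dur:
            stops.append(
                DetectedStop(
                    x=sx / n,
                    y=sy / n,
                    visits=(
                        Visit(t_start=float(t[start]), t_end=float(t[last]),
                              n_fixes=last - start + 1),
                    ),
                )
            )

    for k in range(1, len(track)):
        if by_centroid:
            rx, ry = sx / n, sy / n
        else:
            rx, ry = float(x[start]), float(y[start])
        if hypot(float(x[k]) - rx, float(y[k]) - ry) <= d:
            sx += float(x[k])
            sy += float(y[k])
            n += 1
        else:
            flush(k - 1)
            start = k
            sx, sy, n = float(x[k]), float(y[k]), 1
    flush(len(track) - 1)
    return stops
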