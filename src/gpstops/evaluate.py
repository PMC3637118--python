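"""Performance indicators for stop-detection benchmarks.

Per-track classification
------------------------
A processed track is *on target* when exactly the true number of stops was
detected, a *false negative* when fewer were detected, a *false positive*
when more.  Tracks with the right count but a detected stop farther than
1,000 m from every true stop are *outliers* (a right count arising from a
false positive canceling a false negative) and are discarded from the
on-target group.

Accuracy metrics
----------------
*Spatial accuracy* is the Euclidean distance from a detected stop to the
closest true stop; *temporal accuracy* is the signed relative duration
error (Δ_found − Δ_true) / Δ_true against that same closest true stop.
Both are aggregated over on-target tracks only, where the detected↔true
correspondence is unambiguous.

Stratification
--------------
Indicators are compiled per noise range ([0,50), [50,100), [100,150),
[150,200] m — half-open, last bin closed), per true stay-duration category,
and per bandwidth.  Two further indicators probe robustness: the capacity
to discriminate true stops closer than 800 m, and the per-track range of
bandwidths that achieve an on-target classification (sensitivity to
parameter choice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DetectedStop, TrackTruth

__all__ = [
    "CLASSIFICATIONS",
    "NOISE_BINS",
    "DURATION_BINS_MIN",
    "noise_bin",
    "noise_bin_label",
    "duration_bin",
    "classify_track",
    "StopMatch",
    "match_stops",
    "summarize",
    "close_stop_discrimination",
    "bandwidth_sensitivity",
]

CLASSIFICATIONS = ("on_target", "false_negative", "false_positive", "outlier_discarded")

#: Noise strata in meters: half-open [lo, hi), except the last which is closed.
NOISE_BINS: tuple[tuple[float, float], ...] = ((0, 50), (50, 100), (100, 150), (150, 200))

#: True stay-duration strata in minutes: [0,20), [20,120), [120,inf).
DURATION_BINS_MIN: tuple[tuple[float, float], ...] = ((0, 20), (20, 120), (120, float("inf")))

#: A detected stop farther than this from every true stop marks the track as outlier.
OUTLIER_DISTANCE_M = 1000.0


def noise_bin(noise_m: float) -> int:
    """Index of the noise stratum for a per-track noise magnitude."""
    if not 0 <= noise_m <= NOISE_BINS[-1][1]:
        raise ValueError(f"noise magnitude {noise_m} outside [0, {NOISE_BINS[-1][1]}]")
    for k, (lo, hi) in enumerate(NOISE_BINS):
        if noise_m < hi:
            return k
    return len(NOISE_BINS) - 1  # exactly the closed upper bound


def noise_bin_label(k: int) -> str:
    lo, hi = NOISE_BINS[k]
    close = "]" if k == len(NOISE_BINS) - 1 else ")"
    return f"[{lo:g},{hi:g}{close}"


def duration_bin(duration_s: float) -> int:
    """Index of the stay-duration stratum for a true duration in seconds."""
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    minutes = duration_s / 60.0
    for k, (lo, hi) in enumerate(DURATION_BINS_MIN):
        if minutes < hi:
            return k
    return len(DURATION_BINS_MIN) - 1


def classify_track(
    detected: Sequence[DetectedStop],
    truth: TrackTruth,
    outlier_distance: float = OUTLIER_DISTANCE_M,
) -> str:
    """Classify one processed track against its truth."""
    n_true = len(truth.stops)
    n_det = len(detected)
    if n_det < n_true:
        return "false_negative"
    if n_det > n_true:
        return "false_positive"
    centers = truth.centers
    for s in detected:
        d = np.hypot(centers[:, 0] - s.x, centers[:, 1] - s.y).min()
        if d > outlier_distance:
            return "outlier_discarded"
    return "on_target"


@dataclass(frozen=True)
class StopMatch:
    """A detected stop matched to its closest true stop."""

    detected_index: int
    true_index: int
    distance: float
    duration_error: float  # signed: (found - true) / true


def match_stops(
    detected: Sequence[DetectedStop],
    truth: TrackTruth,
    one_to_one: bool = False,
) -> list[StopMatch]:
    """Match each detected stop to a true stop and compute accuracy metrics.

    Default matching is detected→closest-true (the aggregate metrics are
    only used on on-target tracks, where collisions are rare); set
    ``one_to_one=True`` for an optimal one-to-one assignment minimizing the
    total distance (Hungarian algorithm).
    """
    if not detected:
        return []
    centers = truth.centers
    dx = np.array([s.x for s in detected])
    dy = np.array([s.y for s in detected])
    dist = np.hypot(dx[:, None] - centers[None, :, 0], dy[:, None] - centers[None, :, 1])
    if one_to_one:
        from scipy.optimize import linear_sum_assignment

        ri, ci = linear_sum_assignment(dist)
        pairs = list(zip(ri.tolist(), ci.tolist()))
    else:
        pairs = [(i, int(np.argmin(dist[i]))) for i in range(len(detected))]
    out = []
    for i, j in pairs:
        true = truth.stops[j]
        err = (detected[i].total_duration - true.duration) / true.duration
        out.append(
            StopMatch(
                detected_index=i, true_index=j,
                distance=float(dist[i, j]), duration_error=float(err),
            )
        )
    return out


# ---------------------------------------------------------------------------
# aggregation over result tables
# ---------------------------------------------------------------------------
#
# The functions below operate on a tidy "runs" DataFrame with one row per
# (algo, bandwidth_m, track_id) containing at least:
#   algo, bandwidth_m, track_id, noise_m, noise_bin, classification,
#   n_detected, mean_distance_m, mean_duration_err, mean_abs_duration_err,
#   has_close_stops
# as produced by gpstops.experiment.run_experiment.


def summarize(runs: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Aggregate per-track results into per-stratum performance rows.

    Classification percentages are over all tracks of the stratum and sum
    to 100; distance and duration-error statistics are over the stratum's
    on-target tracks only.
    """
    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        ont = g[g["classification"] == "on_target"]
        out = {"n_tracks": n}
        for cls in CLASSIFICATIONS:
            out[f"pct_{cls}"] = 100.0 * (g["classification"] == cls).sum() / n
        out["mean_stops"] = g["n_detected"].mean()
        out["sd_stops"] = g["n_detected"].std(ddof=1)
        for col, name in [
            ("mean_distance_m", "distance_m"),
            ("mean_duration_err", "duration_err"),
            ("mean_abs_duration_err", "abs_duration_err"),
        ]:
            out[f"mean_{name}"] = ont[col].mean() if len(ont) else np.nan
            out[f"sd_{name}"] = ont[col].std(ddof=1) if len(ont) > 1 else np.nan
        return pd.Series(out)

    res = runs.groupby(list(by), sort=True).apply(_agg, include_groups=False).reset_index()
    res["n_tracks"] = res["n_tracks"].astype(int)
    return res


def close_stop_discrimination(
    runs: pd.DataFrame, radius_m: float = 800.0
) -> pd.DataFrame:
    """Count correctly classified tracks among those with close true stops.

    Restricts to tracks whose truth contains two or more stops within
    ``radius_m`` of each other (the ``has_close_stops`` flag is computed at
    that radius by the experiment runner) and counts on-target tracks per
    algorithm and bandwidth.
    """
    sub = runs[runs["has_close_stops"]]
    out = (
        sub.assign(on_target=sub["classification"] == "on_target")
        .groupby(["algo", "bandwidth_m"])["on_target"]
        .agg(n_correct="sum", n_close="count")
        .reset_index()
    )
    out["n_correct"] = out["n_correct"].astype(int)
    return out


def bandwidth_sensitivity(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-track range of bandwidths achieving on-target, averaged per noise bin.

    For each track and algorithm, records the smallest and largest bandwidth
    with an on-target classification; tracks that never succeed are excluded.
    Returns per algo × noise-bin averages of both limits.
    """
    ont = runs[runs["classification"] == "on_target"]
    per_track = (
        ont.groupby(["algo", "track_id"])
        .agg(
            min_bw=("bandwidth_m", "min"),
            max_bw=("bandwidth_m", "max"),
            noise_bin=("noise_bin", "first"),
        )
        .reset_index()
    )
    out = (
        per_track.groupby(["algo", "noise_bin"])
        .agg(
            mean_min_bw=("min_bw", "mean"),
            mean_max_bw=("max_bw", "mean"),
            n_tracks=("track_id", "count"),
        )
        .reset_index()
    )
    return out
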