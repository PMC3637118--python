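"""Full factorial benchmark: track set × bandwidths × both detectors.

``run_experiment`` generates (or accepts) a synthetic track set, runs every
requested detector at every bandwidth over every track, and returns tidy
result tables; ``make_tables`` aggregates them into the benchmark's summary
tables:

* ``table1`` — global classification percentages per algorithm × bandwidth;
* ``table2`` — on-target percentage per algorithm × bandwidth × noise bin;
* ``table3`` — close-stop discrimination counts per algorithm × bandwidth;
* ``table4`` — headline summary criteria per algorithm;
* ``sensitivity`` — average min/max successful bandwidth per noise bin;
* ``strata`` — mean/sd of stop count, distance and duration error per
  algorithm × bandwidth × noise bin (the material of the profile figures);
* ``duration_strata`` — on-target percentages per true stay-duration
  category (computed at stop level).

Everything is deterministic under a fixed master seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluate as ev
from .generate import GeneratorConfig, generate_track_set
from .kde import KdParams, detect_stops_kd
from .model import DetectedStop, Track
from .threshold import FtParams, detect_stops_ft

__all__ = ["ExperimentConfig", "ExperimentResults", "run_experiment", "make_tables", "write_tables"]

log = logging.getLogger(__name__)

DEFAULT_BANDWIDTHS = (10.0, 50.0, 100.0, 200.0, 500.0, 1000.0)

#: Radius defining the "close true stops" subset (half a mile).
CLOSE_STOP_RADIUS_M = 800.0


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a full benchmark run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    bandwidths: tuple[float, ...] = DEFAULT_BANDWIDTHS
    algorithms: tuple[str, ...] = ("kd", "ft")
    min_stop_duration: float = 300.0
    kd_refine: str = "kernel_centroid"
    ft_membership: str = "first"

    def __post_init__(self) -> None:
        bws = tuple(float(b) for b in self.bandwidths)
        if not bws or any(b <= 0 for b in bws) or any(
            a >= b for a, b in zip(bws, bws[1:])
        ):
            raise ValueError("bandwidths must be positive and strictly increasing")
        object.__setattr__(self, "bandwidths", bws)
        unknown = set(self.algorithms) - {"kd", "ft"}
        if unknown:
            raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")


def detect_stops(
    track: Track, algo: str, bandwidth: float, config: ExperimentConfig
) -> list[DetectedStop]:
    """Dispatch one detection run."""
    if algo == "kd":
        return detect_stops_kd(
            track,
            KdParams(
                bandwidth=bandwidth,
                min_stop_duration=config.min_stop_duration,
                refine=config.kd_refine,
            ),
        )
    if algo == "ft":
        return detect_stops_ft(
            track,
            FtParams(
                roaming_radius=bandwidth,
                min_stop_duration=config.min_stop_duration,
                membership=config.ft_membership,
            ),
        )
    raise ValueError(f"unknown algorithm {algo!r}")


@dataclass
class ExperimentResults:
    """Tidy result tables of one benchmark run.

    ``runs`` has one row per (algo, bandwidth, track); ``stops`` one row per
    detected stop (with its closest-true match); ``tracks`` one row per
    track with its ground-truth characteristics.
    """

    config: ExperimentConfig
    tracks: pd.DataFrame
    runs: pd.DataFrame
    stops: pd.DataFrame


def run_experiment(
    config: ExperimentConfig,
    tracks: Optional[Sequence[Track]] = None,
) -> ExperimentResults:
    """Run the full factorial benchmark.

    Generates the track set from ``config.generator`` unless ``tracks`` is
    given (tracks must then carry truths).  Per-track detector failures are
    logged and recorded as zero detections rather than aborting the batch.
    """
    t0 = time.monotonic()
    if tracks is None:
        log.info("generating %d tracks (seed %d)", config.generator.n_tracks,
                 config.generator.master_seed)
        tracks = generate_track_set(config.generator)
    log.info("generated %d tracks in %.1f s", len(tracks), time.monotonic() - t0)

    track_rows = []
    for tr in tracks:
        if tr.truth is None:
            raise ValueError(f"track {tr.id!r} has no truth; cannot evaluate")
        track_rows.append(
            {
                "track_id": tr.id,
                "n_fixes": len(tr),
                "noise_m": tr.truth.noise_m,
                "noise_bin": ev.noise_bin(tr.truth.noise_m),
                "n_true_stops": len(tr.truth.stops),
                "min_stop_gap_m": tr.truth.min_pairwise_distance(),
                "has_close_stops": tr.truth.min_pairwise_distance() <= CLOSE_STOP_RADIUS_M,
            }
        )
    tracks_df = pd.DataFrame(track_rows)

    run_rows, stop_rows = [], []
    for algo in config.algorithms:
        t1 = time.monotonic()
        for bw in config.bandwidths:
            for tr in tracks:
                try:
                    detected = detect_stops(tr, algo, bw, config)
                except Exception:  # pragma: no cover - robustness only
                    log.warning("detection failed: algo=%s bw=%g track=%s",
                                algo, bw, tr.id, exc_info=True)
                    detected = []
                cls = ev.classify_track(detected, tr.truth)
                matches = ev.match_stops(detected, tr.truth)
                dists = [m.distance for m in matches]
                errs = [m.duration_error for m in matches]
                run_rows.append(
                    {
                        "algo": algo,
                        "bandwidth_m": bw,
                        "track_id": tr.id,
                        "noise_m": tr.truth.noise_m,
                        "noise_bin": ev.noise_bin(tr.truth.noise_m),
                        "has_close_stops": tr.truth.min_pairwise_distance()
                        <= CLOSE_STOP_RADIUS_M,
                        "n_detected": len(detected),
                        "classification": cls,
                        "mean_distance_m": float(np.mean(dists)) if dists else np.nan,
                        "mean_duration_err": float(np.mean(errs)) if errs else np.nan,
                        "mean_abs_duration_err": float(np.mean(np.abs(errs)))
                        if errs else np.nan,
                    }
                )
                for k, (s, m) in enumerate(zip(detected, matches)):
                    true = tr.truth.stops[m.true_index]
                    stop_rows.append(
                        {
                            "algo": algo,
                            "bandwidth_m": bw,
                            "track_id": tr.id,
                            "stop_id": k,
                            "x": s.x,
                            "y": s.y,
                            "total_duration_s": s.total_duration,
                            "n_visits": len(s.visits),
                            "true_index": m.true_index,
                            "distance_m": m.distance,
                            "duration_err": m.duration_error,
                            "true_duration_s": true.duration,
                            "duration_bin": ev.duration_bin(true.duration),
                            "classification": cls,
                        }
                    )
        log.info("algorithm %s: %d runs in %.1f s", algo,
                 len(config.bandwidths) * len(tracks), time.monotonic() - t1)

    runs_df = pd.DataFrame(run_rows)
    stops_df = pd.DataFrame(
        stop_rows,
        columns=["algo", "bandwidth_m", "track_id", "stop_id", "x", "y",
                 "total_duration_s", "n_visits", "true_index", "distance_m",
                 "duration_err", "true_duration_s", "duration_bin", "classification"],
    )
    log.info("experiment complete in %.1f s", time.monotonic() - t0)
    return ExperimentResults(config=config, tracks=tracks_df, runs=runs_df, stops=stops_df)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _check_complete(results: ExperimentResults) -> None:
    expected = {(a, b) for a in results.config.algorithms for b in results.config.bandwidths}
    present = set(map(tuple, results.runs[["algo", "bandwidth_m"]].drop_duplicates().values))
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"incomplete results; missing strata: {missing}")


def make_tables(results: ExperimentResults) -> dict[str, pd.DataFrame]:
    """Aggregate run results into the benchmark summary tables."""
    _check_complete(results)
    runs = results.runs

    table1 = ev.summarize(runs, by=["algo", "bandwidth_m"])[
        ["algo", "bandwidth_m", "n_tracks", "pct_false_negative", "pct_on_target",
         "pct_false_positive", "pct_outlier_discarded"]
    ]

    t2 = ev.summarize(runs, by=["algo", "bandwidth_m", "noise_bin"])
    table2 = (
        t2.pivot_table(index=["algo", "bandwidth_m"], columns="noise_bin",
                       values="pct_on_target")
        .rename(columns=lambda k: f"pct_on_target_{ev.noise_bin_label(int(k))}")
        .reset_index()
    )

    table3 = ev.close_stop_discrimination(runs, radius_m=CLOSE_STOP_RADIUS_M)

    sensitivity = ev.bandwidth_sensitivity(runs)
    sensitivity["noise_bin_label"] = sensitivity["noise_bin"].map(ev.noise_bin_label)

    strata = ev.summarize(runs, by=["algo", "bandwidth_m", "noise_bin"])
    strata["noise_bin_label"] = strata["noise_bin"].map(ev.noise_bin_label)

    # stop-level view per true stay-duration category (on-target tracks)
    ont_stops = results.stops[results.stops["classification"] == "on_target"]
    if len(ont_stops):
        duration_strata = (
            ont_stops.groupby(["algo", "bandwidth_m", "duration_bin"])
            .agg(
                n_stops=("stop_id", "count"),
                mean_distance_m=("distance_m", "mean"),
                mean_duration_err=("duration_err", "mean"),
            )
            .reset_index()
        )
    else:
        duration_strata = pd.DataFrame(
            columns=["algo", "bandwidth_m", "duration_bin", "n_stops",
                     "mean_distance_m", "mean_duration_err"]
        )

    table4 = _summary_criteria(results, table1, table3, strata)
    return {
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "table4": table4,
        "sensitivity": sensitivity,
        "strata": strata,
        "duration_strata": duration_strata,
    }


def _summary_criteria(
    results: ExperimentResults,
    table1: pd.DataFrame,
    table3: pd.DataFrame,
    strata: pd.DataFrame,
) -> pd.DataFrame:
    """Headline criteria per algorithm, over bandwidth × noise-bin combinations."""
    rows = []
    for algo in results.config.algorithms:
        g1 = table1[table1["algo"] == algo]
        best = g1.loc[g1["pct_on_target"].idxmax()]
        st = strata[strata["algo"] == algo]
        n_combos = len(st)
        rows.append(
            {
                "algo": algo,
                "best_pct_on_target": best["pct_on_target"],
                "best_bandwidth_m": best["bandwidth_m"],
                "n_combos": n_combos,
                "n_combos_on_target_ge_70pct": int((st["pct_on_target"] >= 70).sum()),
                "n_combos_on_target_ge_90pct": int((st["pct_on_target"] >= 90).sum()),
                "close_stop_correct_total": int(
                    table3[table3["algo"] == algo]["n_correct"].sum()
                ),
                "n_combos_mean_stops_near_3": int(
                    st["mean_stops"].between(2.8, 3.2, inclusive="neither").sum()
                ),
                "n_combos_mean_distance_lt_15m": int((st["mean_distance_m"] < 15).sum()),
                "n_combos_abs_duration_err_lt_10pct": int(
                    (st["mean_duration_err"].abs() < 0.10).sum()
                ),
            }
        )
    return pd.DataFrame(rows)


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    """Write each table as ``<name>.csv`` under ``outdir`` (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
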