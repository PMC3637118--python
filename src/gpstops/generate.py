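"""Synthetic GPS track generator with known stops, trips and Gaussian noise.

Each track visits ``n_stops`` locations drawn uniformly in a square area,
dwelling at each for a duration drawn from one of three categories (short /
medium / long stays), and travels between consecutive stops in a straight
line at constant speed.  Fixes are sampled on a regular time grid.  Finally,
every fix is displaced by independent zero-mean Gaussian noise whose per-axis
standard deviation ν is drawn once per track, uniformly on ``[0, noise_max]``
— emulating GPS positional error of varying severity across devices and
environments.

The defaults reproduce the benchmark design this package ships: 750 tracks,
3 stops each, a 6 km square, 36 km/h travel, 10 s fix interval, noise up to
200 m, and stay-duration categories [6, 20], [20, 120] and [120, 360]
minutes (the short-stay lower bound sits above the 5-minute detection
threshold so every simulated stop is in principle detectable, and the
open-ended long category is capped so it can be sampled).

Reproducibility: track ``i`` uses an RNG substream derived from
``(master_seed, i)``, so individual tracks can be regenerated independently
and the whole set is deterministic for a given master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Track, TrackTruth, TrueStop

__all__ = [
    "GeneratorConfig",
    "sample_stop_plan",
    "build_noiseless_path",
    "apply_noise",
    "generate_track",
    "generate_track_set",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-track design.

    Attributes
    ----------
    n_tracks : number of tracks in the set.
    n_stops : stops per track.
    area_side : side of the square the stop centers are drawn in (m).
    speed : constant travel speed between stops (m/s); 10 m/s = 36 km/h.
    fix_interval : time between consecutive fixes (s).
    master_seed : seed of the whole set.
    duration_bounds : (lo, hi) per stay category, in **minutes**.
    noise_max : upper bound of the per-track noise magnitude ν (m).
    noise_scope : ``"all"`` applies noise to every fix; ``"stops"`` only to
        fixes inside true stop windows (trip fixes left exact).
    """

    n_tracks: int = 750
    n_stops: int = 3
    area_side: float = 6000.0
    speed: float = 10.0
    fix_interval: float = 10.0
    master_seed: int = 0
    duration_bounds: tuple[tuple[float, float], ...] = ((6, 20), (20, 120), (120, 360))
    noise_max: float = 200.0
    noise_scope: str = "all"

    def __post_init__(self) -> None:
        if min(self.n_tracks, self.n_stops) < 1:
            raise ValueError("n_tracks and n_stops must be positive")
        if min(self.area_side, self.speed, self.fix_interval) <= 0:
            raise ValueError("area_side, speed and fix_interval must be positive")
        if self.noise_max < 0:
            raise ValueError("noise_max must be non-negative")
        if self.noise_scope not in ("all", "stops"):
            raise ValueError("noise_scope must be 'all' or 'stops'")
        for lo, hi in self.duration_bounds:
            if not 0 < lo < hi:
                raise ValueError("duration bounds must satisfy 0 < lo < hi")
            if lo * 60.0 < 300.0:
                raise ValueError(
                    "stay-duration lower bounds must be at least the 5-minute "
                    "minimal stop duration, or stops become undetectable by design"
                )


def track_rng(master_seed: int, index: int) -> np.random.Generator:
    """RNG substream for track ``index`` of a set seeded by ``master_seed``."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def sample_stop_plan(rng: np.random.Generator, config: GeneratorConfig) -> TrackTruth:
    """Draw one track's ground truth: stop centers, schedule and noise level.

    Stop centers are uniform in the area square (visiting order = draw
    order, no minimum separation — close stops are a deliberate, scored
    difficulty).  Each stay duration first draws its category uniformly
    among the three, then a duration uniform within the category bounds.
    The realized schedule starts at t = 0 at the first stop and interleaves
    straight-line trips at constant speed.
    """
    noise = float(rng.uniform(0.0, config.noise_max))
    centers = rng.uniform(0.0, config.area_side, size=(config.n_stops, 2))
    cats = rng.integers(0, len(config.duration_bounds), size=config.n_stops)
    durations = np.array(
        [rng.uniform(*config.duration_bounds[c]) * 60.0 for c in cats]
    )
    stops = []
    t = 0.0
    for k in range(config.n_stops):
        t_arrive = t
        t_depart = t_arrive + durations[k]
        stops.append(
            TrueStop(cx=float(centers[k, 0]), cy=float(centers[k, 1]),
                     t_arrive=t_arrive, t_depart=t_depart)
        )
        t = t_depart
        if k + 1 < config.n_stops:
            leg = float(np.hypot(*(centers[k + 1] - centers[k])))
            t += leg / config.speed
    return TrackTruth(stops=tuple(stops), noise_m=noise)


def build_noiseless_path(
    truth: TrackTruth, config: GeneratorConfig, track_id: str = "synthetic"
) -> Track:
    """Render a truth's exact trajectory as fixes on a regular time grid.

    The position is piecewise linear in time (constant at stop centers,
    linear along trip legs), so fixes are obtained by interpolation at
    ``fix_interval`` steps from the first arrival to the last departure.
    """
    knots_t, knots_x, knots_y = [], [], []
    for s in truth.stops:
        knots_t += [s.t_arrive, s.t_depart]
        knots_x += [s.cx, s.cx]
        knots_y += [s.cy, s.cy]
    t0, t1 = knots_t[0], knots_t[-1]
    t = t0 + config.fix_interval * np.arange(int(np.floor((t1 - t0) / config.fix_interval)) + 1)
    x = np.interp(t, knots_t, knots_x)
    y = np.interp(t, knots_t, knots_y)
    return Track(id=track_id, t=t, x=x, y=y, truth=truth)


def apply_noise(
    track: Track,
    noise_m: float,
    rng: np.random.Generator,
    scope: str = "all",
) -> Track:
    """Displace fixes by independent bivariate Gaussian offsets.

    ``noise_m`` is the per-axis standard deviation; timestamps are left
    untouched.  With ``scope="stops"`` only fixes inside true stop windows
    are displaced (requires a truth on the track).
    """
    if noise_m < 0:
        raise ValueError("noise magnitude must be non-negative")
    x, y = track.x.copy(), track.y.copy()
    if noise_m > 0:
        n = len(track)
        dx = rng.normal(0.0, noise_m, size=n)
        dy = rng.normal(0.0, noise_m, size=n)
        if scope == "all":
            mask = np.ones(n, dtype=bool)
        elif scope == "stops":
            if track.truth is None:
                raise ValueError("scope='stops' requires a truth on the track")
            mask = np.zeros(n, dtype=bool)
            for s in track.truth.stops:
                mask |= (track.t >= s.t_arrive) & (track.t <= s.t_depart)
        else:
            raise ValueError("scope must be 'all' or 'stops'")
        x[mask] += dx[mask]
        y[mask] += dy[mask]
    return Track(id=track.id, t=track.t.copy(), x=x, y=y, truth=track.truth)


def generate_track(config: GeneratorConfig, index: int) -> Track:
    """Generate track ``index`` of the set (independent of all others)."""
    rng = track_rng(config.master_seed, index)
    truth = sample_stop_plan(rng, config)
    truth.seed = index
    clean = build_noiseless_path(truth, config, track_id=f"t{index:04d}")
    return apply_noise(clean, truth.noise_m, rng, scope=config.noise_scope)


def generate_track_set(config: GeneratorConfig) -> list[Track]:
    """Generate the full benchmark set (``n_tracks`` tracks with truths)."""
    return [generate_track(config, i) for i in range(config.n_tracks)]
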