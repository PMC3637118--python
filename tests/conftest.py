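"""Shared fixtures: small synthetic tracks with exactly known geometry."""

import numpy as np
import pytest

from gpstops.generate import GeneratorConfig
from gpstops.model import Track, TrackTruth, TrueStop


@pytest.fixture
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_tracks=5, master_seed=7)


def make_three_stop_truth(
    centers=((0.0, 0.0), (3000.0, 0.0), (3000.0, 4000.0)),
    durations=(600.0, 900.0, 1200.0),
    speed=10.0,
    noise=0.0,
) -> TrackTruth:
    """Hand-built truth with explicit centers/durations and realized schedule."""
    stops = []
    t = 0.0
    prev = None
    for (cx, cy), dur in zip(centers, durations):
        if prev is not None:
            t += float(np.hypot(cx - prev[0], cy - prev[1])) / speed
        stops.append(TrueStop(cx=cx, cy=cy, t_arrive=t, t_depart=t + dur))
        t += dur
        prev = (cx, cy)
    return TrackTruth(stops=tuple(stops), noise_m=noise)


@pytest.fixture
def three_stop_truth() -> TrackTruth:
    return make_three_stop_truth()


@pytest.fixture
def stationary_track() -> Track:
    """37 fixes at one point over 360 s, then straight movement away."""
    t = 10.0 * np.arange(60)
    x = np.where(t <= 360, 100.0, 100.0 + 10.0 * (t - 360))
    y = np.full_like(t, 50.0)
    return Track(id="stationary", t=t, x=x, y=np.array(y))
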