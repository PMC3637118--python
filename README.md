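# gpstops

Activity-place (stop) detection from raw GPS tracks, for exposure assessment
in health-and-place and mobility research.

GPS loggers produce long streams of noisy fixes. Before a track can be linked
to environmental exposures, it must be reduced to a sequence of *activity
locations* — places where the wearer stayed at least a minimum duration — and
the trips between them. This package implements two detectors over a common
track model, plus a controlled synthetic-track benchmark for scoring them:

- **Kernel-density detector (`kd`).** Operates globally: a quartic
  (biweight) kernel K(d) = 3/(πh²)·(1 − d²/h²)² for d ≤ h is summed over all
  fixes into a density surface on a grid; local maxima of the surface become
  candidate places; each fix is allocated to its nearest peak (within an
  allocation radius proportional to the bandwidth h) or to a trip segment;
  runs of allocated fixes form a timetable of visits, and peaks with a visit
  of at least the minimal stay duration (5 min by default) are reported as
  stops, located off-grid by a kernel-weighted centroid.
- **Fixed-threshold detector (`ft`).** The classical sequential comparator:
  consecutive fixes are clustered while they remain within a roaming radius
  d of a reference fix; a cluster whose time span reaches the minimal stay
  duration is emitted as a stop at its centroid.

The synthetic generator builds tracks with a known ground truth — n stops
uniform in a square area, stay durations drawn from short/medium/long
categories, straight constant-speed trips (36 km/h), and per-track Gaussian
positional noise with standard deviation drawn uniformly up to 200 m — so
that detection, spatial and temporal accuracy can be scored exactly.
The evaluation module classifies each processed track (on target / false
negative / false positive / outlier), measures detected-to-true stop
distances and relative duration errors (Δ_found − Δ_true)/Δ_true, and
compiles them per noise range, stay-duration category and bandwidth,
including close-stop discrimination (< 800 m) and sensitivity of each
detector to its bandwidth choice.

## Worked example

```python
from gpstops import GeneratorConfig, KdParams, FtParams
from gpstops.generate import generate_track
from gpstops.kde import detect_stops_kd
from gpstops.threshold import detect_stops_ft

track = generate_track(GeneratorConfig(master_seed=42), index=0)
print(f"track {track.id}: {len(track)} fixes, noise SD {track.truth.noise_m:.1f} m")
for s in track.truth.stops:
    print(f"  true stop at ({s.cx:7.1f}, {s.cy:7.1f}), stay {s.duration/60:6.1f} min")

stops = detect_stops_kd(track, KdParams(bandwidth=200.0))
print(f"kernel detector (h = 200 m): {len(stops)} stops")
for s in stops:
    print(f"  detected ({s.x:7.1f}, {s.y:7.1f}), stay {s.total_duration/60:6.1f} min, "
          f"{len(s.visits)} visit(s)")

stops_ft = detect_stops_ft(track, FtParams(roaming_radius=200.0))
print(f"fixed-threshold detector (d = 200 m): {len(stops_ft)} stops")
```

prints

```
track t0000: 2922 fixes, noise SD 183.3 m
  true stop at ( 5465.9,  5259.6), stay   58.3 min
  true stop at ( 1855.9,  5727.9), stay  259.0 min
  true stop at ( 1050.6,  5979.8), stay  162.1 min
kernel detector (h = 200 m): 3 stops
  detected ( 5435.1,  5293.6), stay   58.7 min, 1 visit(s)
  detected ( 1855.8,  5713.8), stay  259.7 min, 2 visit(s)
  detected ( 1056.6,  5971.9), stay  161.0 min, 3 visit(s)
fixed-threshold detector (d = 200 m): 0 stops
```

This track carries heavy noise (183 m SD, comparable to the 200 m bandwidth).
The kernel detector still recovers all three stops within ~45 m and estimates
every stay duration within about 1%, while the sequential comparator at the
same 200 m radius finds nothing: noise keeps breaking its clusters before
they reach the 5-minute threshold. That resilience difference is the central
result the benchmark quantifies.

## Command line

```
gpstops generate  --n 750 --seed 1 --out data/           # tracks.csv + truth.csv (+ GPX)
gpstops detect    --algo kd --bandwidth 200 --in data/tracks.csv --out stops.csv
gpstops evaluate  --stops stops.csv --truth data/truth.csv --out metrics.csv
gpstops replicate --seed 1 --out results/                # the full factorial benchmark
```

`replicate` writes tidy per-run results plus summary tables: global
classification shares per bandwidth, on-target shares per bandwidth × noise
bin, close-stop discrimination counts, bandwidth-sensitivity averages, and a
headline summary per detector.

GPX 1.1 input is supported; geographic tracks are projected onto a local
azimuthal-equidistant plane (meters) before detection.

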