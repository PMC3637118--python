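"""Kernel-density stop detector.

The detector operates globally on a track: it builds a kernel density
surface over all fixes, extracts the surface's local maxima ("peaks") as
candidate activity locations, allocates every fix either to its nearest peak
(within the allocation radius) or to a trip segment, derives a timetable of
visits per peak from the allocation runs, and finally keeps as stops the
peaks with a visit at least as long as the minimal stay duration.

The kernel is the quartic (biweight) kernel standard in GIS kernel-density
tools,

    K(d) = 3 / (π h²) · (1 − d²/h²)²   for d ≤ h, else 0,

which integrates to 1 over the plane, so the surface integrates to the
number of fixes.  The surface is evaluated on a square grid whose cell size
defaults to h/10 (floored at 2 m); because the kernel has compact support,
each fix only "stamps" the ~(2h/c)² cells within one bandwidth of it, which
keeps the construction linear in the number of fixes.

Stop locations are refined off-grid.  The default estimator is the
quartic-weighted centroid of the peak's allocated fixes (one smoothing step
from the peak cell), which frees the reported location from grid resolution,
discounts passing trip fixes, and avoids the sampling-bump chasing of a
fully converged mode seeker; converged mean-shift and the plain centroid
remain available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import DetectedStop, Track, Visit

__all__ = [
    "KdParams",
    "DensitySurface",
    "Peak",
    "TRIP",
    "compute_density_surface",
    "extract_peaks",
    "assign_fixes",
    "build_visits",
    "detect_stops_kd",
]

#: Label of fixes allocated to a trip segment rather than a peak.
TRIP = -1

_MAX_GRID_CELLS = 400_000_000  # hard sanity cap on grid size


@dataclass(frozen=True)
class KdParams:
    """Tunable parameters of the kernel-density detector.

    Attributes
    ----------
    bandwidth : kernel bandwidth h (m) — the spatial scale of smoothing.
    min_stop_duration : minimal total stay (s) for a peak to qualify as a
        stop; 300 s (5 min) by default.
    cell_size : density grid resolution (m); defaults to max(h/10, 2).
    merge_gap : visits to the same peak separated by at most this gap (s)
        are merged, bridging single noisy excursions.
    min_peak_support : minimal number of allocated fixes for a peak to be
        eligible (suppresses single-fix artifacts).
    allocation_radius_factor : a fix joins its nearest peak when closer than
        this multiple of the bandwidth (beyond, it is a trip fix).
    qualify : ``"visit"`` (default) requires a single visit of at least
        ``min_stop_duration`` — the same per-stay reading the sequential
        detector applies per cluster; ``"total"`` requires the *sum* of
        visit durations to reach it.
    refine : off-grid stop-location estimator —
        ``"kernel_centroid"`` (default): quartic-weighted centroid of the
        peak's allocated fixes, weights centered on the peak cell (one
        smoothing step; low-variance and insensitive to grid resolution);
        ``"mode"``: mean-shift iterated to the continuous density mode
        (chases sampling bumps when noise exceeds the bandwidth);
        ``"centroid"``: plain centroid of allocated fixes.
    """

    bandwidth: float
    min_stop_duration: float = 300.0
    cell_size: Optional[float] = None
    merge_gap: float = 60.0
    min_peak_support: int = 2
    allocation_radius_factor: float = 1.5
    qualify: str = "visit"
    refine: str = "kernel_centroid"

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.min_stop_duration <= 0:
            raise ValueError("min_stop_duration must be positive")
        c = self.resolved_cell_size
        if c <= 0 or c > self.bandwidth:
            raise ValueError("cell size must be positive and at most the bandwidth")
        if self.allocation_radius_factor <= 0:
            raise ValueError("allocation_radius_factor must be positive")
        if self.qualify not in ("visit", "total"):
            raise ValueError("qualify must be 'visit' or 'total'")
        if self.refine not in ("kernel_centroid", "mode", "centroid"):
            raise ValueError("refine must be 'kernel_centroid', 'mode' or 'centroid'")

    @property
    def allocation_radius(self) -> float:
        return self.allocation_radius_factor * self.bandwidth

    @property
    def resolved_cell_size(self) -> float:
        if self.cell_size is not None:
            return float(self.cell_size)
        return max(self.bandwidth / 10.0, 2.0)


@dataclass
class DensitySurface:
    """A kernel density grid: values (per m²) at cell centers.

    Cell (i, j) covers ``[x0 + j·c, x0 + (j+1)·c] × [y0 + i·c, y0 + (i+1)·c]``
    and its center is ``(x0 + (j+0.5)·c, y0 + (i+0.5)·c)``.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray  # (n_rows, n_cols)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, i: float, j: float) -> tuple[float, float]:
        return (
            self.x0 + (float(j) + 0.5) * self.cell_size,
            self.y0 + (float(i) + 0.5) * self.cell_size,
        )


@dataclass
class Peak:
    """A local maximum of the density surface (candidate activity location).

    ``grid_cell`` is the representative cell (plateaus collapse to the cell
    nearest their centroid); ``cell_center`` the corresponding point;
    ``refined_location`` the off-grid location set during detection.
    """

    id: int
    grid_cell: tuple[int, int]
    cell_center: tuple[float, float]
    density: float
    refined_location: Optional[tuple[float, float]] = None

    @property
    def location(self) -> tuple[float, float]:
        return self.refined_location if self.refined_location is not None else self.cell_center


# ---------------------------------------------------------------------------
# density surface
# ---------------------------------------------------------------------------

def quartic_kernel(d2: np.ndarray, h: float) -> np.ndarray:
    """Quartic kernel evaluated at squared distances ``d2``."""
    u = 1.0 - d2 / (h * h)
    np.clip(u, 0.0, None, out=u)
    return (3.0 / (np.pi * h * h)) * u * u


def compute_density_surface(
    x: np.ndarray, y: np.ndarray, params: KdParams
) -> DensitySurface:
    """Sum a quartic kernel over all fixes on a regular grid.

    The grid is padded by at least one bandwidth beyond the fixes' bounding
    box so the full kernel mass of every fix lies inside it.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot compute a density surface from an empty fix set")
    h = params.bandwidth
    c = params.resolved_cell_size
    r = int(np.ceil(h / c))  # stamp half-width in cells

    # origin chosen so the bounding-box minimum falls on a cell center
    x0 = float(x.min()) - (r + 1.5) * c
    y0 = float(y.min()) - (r + 1.5) * c
    n_cols = int(np.floor((float(x.max()) - x0) / c)) + r + 2
    n_rows = int(np.floor((float(y.max()) - y0) / c)) + r + 2
    if n_rows * n_cols > _MAX_GRID_CELLS:
        raise ValueError(
            f"density grid would need {n_rows}x{n_cols} cells; "
            "increase cell_size or reduce the track extent"
        )

    j0 = np.floor((x - x0) / c).astype(np.int64)
    i0 = np.floor((y - y0) / c).astype(np.int64)
    off = np.arange(-r, r + 1)
    w = off.size

    acc = np.zeros(n_rows * n_cols, dtype=float)
    # chunk so the (n, w, w) stamp tensor stays modest
    chunk = max(1, int(4_000_000 / (w * w)))
    norm = 3.0 / (np.pi * h * h)
    h2 = h * h
    for s in range(0, x.size, chunk):
        e = min(s + chunk, x.size)
        jj = j0[s:e, None] + off  # (n, w)
        ii = i0[s:e, None] + off
        cxs = x0 + (jj + 0.5) * c
        cys = y0 + (ii + 0.5) * c
        dx2 = (cxs - x[s:e, None]) ** 2
        dy2 = (cys - y[s:e, None]) ** 2
        d2 = dy2[:, :, None] + dx2[:, None, :]  # (n, w, w): rows=y, cols=x
        u = 1.0 - d2 / h2
        np.clip(u, 0.0, None, out=u)
        k = norm * u * u
        flat = (ii[:, :, None] * n_cols + jj[:, None, :]).ravel()
        acc += np.bincount(flat, weights=k.ravel(), minlength=n_rows * n_cols)
    return DensitySurface(x0=x0, y0=y0, cell_size=c, values=acc.reshape(n_rows, n_cols))


def compute_density_surface_bruteforce(
    x: np.ndarray, y: np.ndarray, params: KdParams
) -> DensitySurface:
    """Reference implementation: evaluate every cell against every fix.

    O(cells × fixes); used as the independent oracle for the stamped
    surface on small instances.
    """
    fast = compute_density_surface(x, y, params)  # reuse the grid geometry
    h = params.bandwidth
    c = fast.cell_size
    jj = np.arange(fast.n_cols)
    ii = np.arange(fast.n_rows)
    cxs = fast.x0 + (jj + 0.5) * c
    cys = fast.y0 + (ii + 0.5) * c
    vals = np.zeros((fast.n_rows, fast.n_cols))
    for fx, fy in zip(np.ravel(x), np.ravel(y)):
        d2 = (cys[:, None] - fy) ** 2 + (cxs[None, :] - fx) ** 2
        vals += quartic_kernel(d2, h)
    return DensitySurface(x0=fast.x0, y0=fast.y0, cell_size=c, values=vals)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def extract_peaks(surface: DensitySurface) -> list[Peak]:
    """Extract local maxima of the density surface.

    A cell qualifies when its density is positive, no 8-neighbor exceeds it,
    and at least one neighbor is strictly smaller (the padded border of
    zeros guarantees the latter for any bounded bump).  Connected plateaus
    of equal density collapse to a single peak at the plateau's cell
    centroid.  Peaks are ordered by descending density (ties: row-major
    cell order) and numbered in that order.
    """
    v = surface.values
    n_rows, n_cols = v.shape
    # separable 3x3 max (self included) without full-grid ndimage passes:
    # horizontal 3-max, then vertical 3-max of that.
    hpad = np.zeros((n_rows, n_cols + 2), dtype=v.dtype)
    hpad[:, 1:-1] = v
    hmax = np.maximum(np.maximum(hpad[:, :-2], hpad[:, 1:-1]), hpad[:, 2:])
    vpad = np.zeros((n_rows + 2, n_cols), dtype=v.dtype)
    vpad[1:-1] = hmax
    mf = np.maximum(np.maximum(vpad[:-2], vpad[1:-1]), vpad[2:])
    cand_mask = (v > 0) & (v >= mf)  # v == 3x3 max
    flat_idx = np.flatnonzero(cand_mask.ravel())
    if flat_idx.size == 0:
        return []

    rows, cols = np.divmod(flat_idx, n_cols)
    vals = v.ravel()[flat_idx]
    # candidates sit at least (r+1) cells away from the border (grid padding),
    # so all 8 neighbors exist
    neigh_off = np.array([-n_cols - 1, -n_cols, -n_cols + 1, -1, 1,
                          n_cols - 1, n_cols, n_cols + 1])
    neigh_vals = v.ravel()[flat_idx[:, None] + neigh_off]  # (n_cand, 8)
    has_lower = (neigh_vals < vals[:, None]).any(axis=1)

    # group 8-connected equal-density plateaus (adjacent candidates always
    # share their value: a smaller neighbor could not itself be a local max)
    cand_pos = {int(f): k for k, f in enumerate(flat_idx)}
    parent = list(range(flat_idx.size))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    neigh_is_cand = np.isin(flat_idx[:, None] + neigh_off, flat_idx)
    for k in np.flatnonzero(neigh_is_cand.any(axis=1)):
        for off in neigh_off[neigh_is_cand[k]]:
            other = cand_pos[int(flat_idx[k] + off)]
            ra, rb = find(k), find(other)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    roots = np.array([find(k) for k in range(flat_idx.size)])
    comps: dict[int, list[int]] = {}
    for k, r in enumerate(roots):
        comps.setdefault(int(r), []).append(k)

    entries = []
    for members in comps.values():
        if not has_lower[members].any():
            continue  # interior of a flat positive region: not a maximum
        ri = float(np.mean(rows[members]))
        ci = float(np.mean(cols[members]))
        entries.append((float(vals[members[0]]), int(flat_idx[members].min()), ri, ci))
    entries.sort(key=lambda e: (-e[0], e[1]))
    return [
        Peak(
            id=pid,
            grid_cell=(int(round(ri)), int(round(ci))),
            cell_center=surface.cell_center(ri, ci),
            density=dens,
        )
        for pid, (dens, _, ri, ci) in enumerate(entries)
    ]


# ---------------------------------------------------------------------------
# allocation, visits, detection
# ---------------------------------------------------------------------------

def assign_fixes(
    x: np.ndarray, y: np.ndarray, peaks: Sequence[Peak], params: KdParams
) -> np.ndarray:
    """Allocate each fix to its nearest peak within the allocation radius,
    else TRIP.

    Distances are to the peak's refined location when set, else its cell
    center.  Ties (within 1e-9 m) break to the lowest peak id.
    """
    n = np.size(x)
    labels = np.full(n, TRIP, dtype=np.int64)
    if not peaks or n == 0:
        return labels
    px = np.array([p.location[0] for p in peaks])
    py = np.array([p.location[1] for p in peaks])
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    h = params.allocation_radius
    chunk = max(1, int(8_000_000 / max(len(peaks), 1)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        d = np.hypot(x[s:e, None] - px[None, :], y[s:e, None] - py[None, :])
        dmin = d.min(axis=1)
        # first peak within tie tolerance of the minimum -> lowest id
        best = np.argmax(d <= dmin[:, None] + 1e-9, axis=1)
        lab = np.where(dmin <= h, best, TRIP)
        labels[s:e] = lab
    return labels


def build_visits(
    labels: np.ndarray, t: np.ndarray, params: KdParams
) -> dict[int, list[Visit]]:
    """Derive each peak's timetable from the allocation sequence.

    Maximal runs of consecutive fixes sharing a peak label become visits;
    consecutive visits to the same peak separated by at most ``merge_gap``
    seconds merge into one visit spanning the gap.
    """
    labels = np.asarray(labels)
    t = np.asarray(t, dtype=float)
    visits: dict[int, list[Visit]] = {}
    if labels.size == 0:
        return visits
    # run-length decomposition
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [labels.size - 1]])
    for s, e in zip(starts, ends):
        pid = int(labels[s])
        if pid == TRIP:
            continue
        v = Visit(t_start=float(t[s]), t_end=float(t[e]), n_fixes=int(e - s + 1))
        lst = visits.setdefault(pid, [])
        if lst and v.t_start - lst[-1].t_end <= params.merge_gap:
            prev = lst.pop()
            v = Visit(t_start=prev.t_start, t_end=v.t_end,
                      n_fixes=prev.n_fixes + v.n_fixes)
        lst.append(v)
    return visits


def _mean_shift(
    x: np.ndarray, y: np.ndarray, start: tuple[float, float], h: float,
    tol: float = 1e-3, max_iter: int = 200,
) -> tuple[float, float]:
    """Quartic-kernel mean-shift to the nearest mode of the fix density."""
    cx, cy = start
    for _ in range(max_iter):
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        w = 1.0 - d2 / (h * h)
        np.clip(w, 0.0, None, out=w)
        w *= w
        sw = w.sum()
        if sw <= 0:
            break
        nx = float(np.dot(w, x) / sw)
        ny = float(np.dot(w, y) / sw)
        if np.hypot(nx - cx, ny - cy) < tol:
            cx, cy = nx, ny
            break
        cx, cy = nx, ny
    return cx, cy


def _kernel_centroid(
    x: np.ndarray, y: np.ndarray, center: tuple[float, float], h: float
) -> tuple[float, float]:
    """Quartic-weighted centroid of fixes, weights centered at ``center``.

    A single smoothing step off the grid: unbiased for symmetric positional
    noise and it discounts distant (e.g. passing-trip) fixes.  Falls back to
    the plain centroid if no fix carries weight.
    """
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    w = 1.0 - d2 / (h * h)
    np.clip(w, 0.0, None, out=w)
    w *= w
    sw = w.sum()
    if sw <= 0:
        return float(x.mean()), float(y.mean())
    return float(np.dot(w, x) / sw), float(np.dot(w, y) / sw)


def detect_stops_kd(track: Track, params: KdParams) -> list[DetectedStop]:
    """Run the full kernel-density detection chain on one planar track.

    Returns stops in chronological order of first visit.  A peak becomes a
    stop when its stay reaches ``min_stop_duration`` (per visit or in total,
    per ``params.qualify``) and at least ``min_peak_support`` fixes were
    allocated to it.
    """
    if not track.has_planar:
        raise ValueError(f"track {track.id!r}: planar coordinates required")
    surface = compute_density_surface(track.x, track.y, params)
    peaks = extract_peaks(surface)
    labels = assign_fixes(track.x, track.y, peaks, params)
    visits = build_visits(labels, track.t, params)

    support = np.bincount(labels[labels >= 0], minlength=len(peaks))
    stops: list[DetectedStop] = []
    for peak in peaks:
        vs = visits.get(peak.id)
        if not vs:
            continue
        if params.qualify == "visit":
            qual = max(v.duration for v in vs)
        else:
            qual = sum(v.duration for v in vs)
        if qual < params.min_stop_duration or support[peak.id] < params.min_peak_support:
            continue
        sel = labels == peak.id
        if params.refine == "centroid":
            loc = (float(track.x[sel].mean()), float(track.y[sel].mean()))
        elif params.refine == "mode":
            loc = _mean_shift(track.x, track.y, peak.cell_center, params.bandwidth)
        else:
            loc = _kernel_centroid(
                track.x[sel], track.y[sel], peak.cell_center, params.bandwidth
            )
        peak.refined_location = loc
        stops.append(DetectedStop(x=loc[0], y=loc[1], visits=tuple(vs)))
    stops.sort(key=lambda s: s.t_first)
    return stops
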