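"""Trajectory analysis: turnover, radial extension, SC growth rate and
doubling time, compression statistics, crypt clusters and fission.

These estimators operate on recorded observations (one per 1.2 h) and
mirror how full-scale runs of the simulator are analysed:

* turnover is the count of epithelial cells removed at the cylinder ends
  (cells lost by BM detachment are deliberately excluded), smoothed over
  a 20-observation sliding window;
* the radial extension of the membrane is the mean knot distance to the
  cylinder axis, resolved in 5 um axial slices with the two boundary
  slices ignored;
* the SC growth rate q (decades/day) is the slope of a least-squares fit
  of log10(SC count) against time, started at the first time point from
  which the fit over *all* following points reaches a Pearson correlation
  R > 0.95; the SC doubling time is t_d = ln(2) / (ln(10) q);
* SC compression statistics pool the per-SC relative compression
  (V_T - V_A)/V_0 over the last 40 observations (2 days);
* crypts are detected as single-linkage clusters of Paneth-cell
  positions; a fission event is a tracked cluster splitting into two
  clusters that both persist.

The extrapolated compression at which 1/t_d reaches zero estimates the
tolerated compression below which stem-cell expansion (and hence crypt
growth) vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.cluster.hierarchy import fcluster, linkage

from .mesh import BMNetwork

__all__ = [
    "window_mean", "smoothed_census_series", "expansion_doubling_time",
    "turnover_series", "radial_extension", "sc_growth_rate",
    "compression_stats", "crypt_clusters_and_fission",
    "td_vs_compression_fit", "GrowthRateResult", "FissionEvent",
]


class NoOnsetError(RuntimeError):
    """No candidate start index satisfies the R > 0.95 onset rule."""


# ----------------------------------------------------------------------

def window_mean(values, window: int = 20) -> np.ndarray:
    """Sliding mean over ``window`` consecutive observations.

    Characterization of turnover and SC numbers averages 20 observations
    (one day of 1.2 h steps); this helper implements that smoothing for
    any per-observation series.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < window:
        raise ValueError(f"need at least {window} observations, got {len(v)}")
    kernel = np.ones(window) / window
    return np.convolve(v, kernel, mode="valid")


def smoothed_census_series(observations, lineage: str = "SC",
                           window: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """(window-centre times, smoothed counts) for one lineage."""
    t = np.asarray([o.time for o in observations], dtype=float)
    c = np.asarray([o.census[lineage] for o in observations], dtype=float)
    tc = np.convolve(t, np.ones(window) / window, mode="valid")
    return tc, window_mean(c, window)


def expansion_doubling_time(observations, window: int = 20):
    """SC doubling time of the expansion phase of one trajectory.

    Applies the onset rule (:func:`sc_growth_rate`) to the 20-observation
    smoothed SC census truncated at its maximum: in a finite desk-scale
    tissue the stem-cell pool saturates once the crypts fill the tube,
    and the exponential-growth analysis refers to the expansion phase
    before that ceiling.  Returns the :class:`GrowthRateResult` or None
    when the onset rule finds no exponential stretch.
    """
    tc, cs = smoothed_census_series(observations, "SC", window)
    stop = int(np.argmax(cs)) + 1
    if stop < 5:
        return None
    try:
        return sc_growth_rate(tc[:stop] / 24.0, cs[:stop])
    except NoOnsetError:
        return None


def turnover_series(increments, window: int = 20) -> np.ndarray:
    """Sliding-window mean of the per-observation turnover counts.

    ``increments`` may be a sequence of integers or of ObservationRecord
    objects (whose ``turnover_increment`` already excludes removals of
    BM-detached cells).  Returns one smoothed rate (cells per observation
    interval) per window position; raises ValueError for series shorter
    than the window.
    """
    inc = np.asarray([
        getattr(o, "turnover_increment", o) for o in increments
    ], dtype=float)
    return window_mean(inc, window)


def radial_extension(net: BMNetwork, slice_width: float = 5.0
                     ) -> tuple[np.ndarray, float]:
    """Per-slice mean knot radius and overall mean radial extension.

    Knots are binned by their axial (z) coordinate into slices of
    ``slice_width``; the first and last non-empty slices contain the open
    boundaries and are ignored.  Raises ValueError if an interior slice
    is empty (torn membrane).
    """
    z = net.knots[:, 2]
    rad = np.linalg.norm(net.knots[:, :2], axis=1)
    lo = math.floor(z.min() / slice_width)
    hi = math.floor(z.max() / slice_width)
    idx = np.floor(z / slice_width).astype(int) - lo
    n_slices = hi - lo + 1
    sums = np.bincount(idx, weights=rad, minlength=n_slices)
    counts = np.bincount(idx, minlength=n_slices)
    if n_slices <= 2:
        raise ValueError("membrane too short for interior slices")
    interior = slice(1, n_slices - 1)
    if np.any(counts[interior] == 0):
        raise ValueError("empty interior slice (membrane torn?)")
    profile = sums[interior] / counts[interior]
    keep = (idx >= 1) & (idx <= n_slices - 2)
    return profile, float(rad[keep].mean())


# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthRateResult:
    q: float          # decades per day
    t_start: float    # onset time (same unit as input times)
    t_d: float        # doubling time in days (inf when q <= 0)
    start_index: int
    r_value: float


def _pearson_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope/intercept and Pearson R of y against t."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(tc @ tc)
    syy = float(yc @ yc)
    sty = float(tc @ yc)
    if stt == 0.0:
        raise ValueError("degenerate time axis")
    slope = sty / stt
    if syy == 0.0:
        return slope, float(y.mean()), 0.0  # flat series: undefined R -> 0
    r = sty / math.sqrt(stt * syy)
    return slope, float(y.mean() - slope * t.mean()), r


def sc_growth_rate(times, counts, r_threshold: float = 0.95,
                   min_points: int = 3) -> GrowthRateResult:
    """Exponential-growth onset detection and rate estimation.

    Scans candidate start indices in order; the onset is the first index
    for which the linear fit of log10(count) over *all* following time
    points reaches Pearson R > ``r_threshold``.  ``times`` are in days.
    Counts must be positive from the onset onward; flat series have
    undefined correlation and raise NoOnsetError.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(counts, dtype=float)
    if len(t) != len(c):
        raise ValueError("times and counts length mismatch")
    n = len(t)
    for start in range(0, n - min_points + 1):
        tail_c = c[start:]
        if np.any(tail_c <= 0):
            continue
        y = np.log10(tail_c)
        slope, _, r = _pearson_fit(t[start:], y)
        if r > r_threshold:
            q = slope
            t_d = math.log(2) / (math.log(10) * q) if q > 0 else math.inf
            return GrowthRateResult(q=q, t_start=float(t[start]), t_d=t_d,
                                    start_index=start, r_value=r)
    raise NoOnsetError(
        f"no start index reaches Pearson R > {r_threshold}")


def compression_stats(observations, n_last: int = 40
                      ) -> tuple[float, int]:
    """Pooled median relative SC compression over the last observations.

    Pools the per-SC samples (V_T - V_A)/V_0 of the last ``n_last``
    observations (40 observations = 2 days) and returns (median, count).
    Raises ValueError without any SC sample in the window.
    """
    if len(observations) < n_last:
        raise ValueError(
            f"need at least {n_last} observations, got {len(observations)}")
    samples = [np.asarray(getattr(o, "sc_compression", o), dtype=float)
               for o in observations[-n_last:]]
    pooled = np.concatenate(samples) if samples else np.empty(0)
    if pooled.size == 0:
        raise ValueError("no SC compression samples in the window")
    return float(np.median(pooled)), int(pooled.size)


# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FissionEvent:
    observation_index: int
    parent_members: frozenset
    child_members: tuple


def _cluster_members(ids: np.ndarray, pos: np.ndarray,
                     link_dist: float) -> list[frozenset]:
    """Single-linkage clusters of PC positions at cutoff ``link_dist``."""
    if len(ids) == 0:
        return []
    if len(ids) == 1:
        return [frozenset([int(ids[0])])]
    Z = linkage(pdist(pos), method="single")
    labels = fcluster(Z, t=link_dist, criterion="distance")
    out: dict[int, set] = {}
    for lab, i in zip(labels, ids):
        out.setdefault(int(lab), set()).add(int(i))
    return [frozenset(s) for s in out.values()]


def crypt_clusters_and_fission(observations, link_dist: float = 10.5,
                               persistence: int = 10):
    """Crypt detection and fission events from PC-cluster tracking.

    Per observation, Paneth cells are grouped by single-linkage
    clustering at ``link_dist`` (crypt count = cluster count).  Clusters
    are tracked over time by member overlap; a fission event is recorded
    when one tracked cluster splits into two or more clusters that each
    persist for at least ``persistence`` further observations.

    Returns ``(cluster_series, fission_events)`` where cluster_series is
    a list (per observation) of member-id frozensets.
    """
    series = [
        _cluster_members(np.asarray(getattr(o, "pc_ids")),
                         np.asarray(getattr(o, "pc_pos")), link_dist)
        for o in observations
    ]
    events: list[FissionEvent] = []
    for k in range(1, len(series)):
        prev, cur = series[k - 1], series[k]
        for parent in prev:
            children = [c for c in cur if c & parent]
            if len(children) < 2:
                continue
            # both fragments must persist as separate clusters
            if k + persistence > len(series) - 1:
                continue
            persistent = []
            for child in children:
                seed = child
                alive = True
                for kk in range(k + 1, k + persistence + 1):
                    nxt = [c for c in series[kk] if c & seed]
                    if len(nxt) != 1:
                        alive = False
                        break
                    seed = nxt[0]
                if alive:
                    persistent.append(child)
            # the fragments must not have re-merged
            if len(persistent) >= 2 and all(
                not (a & b) for ia, a in enumerate(persistent)
                for b in persistent[ia + 1:]
            ):
                events.append(FissionEvent(
                    observation_index=k,
                    parent_members=parent,
                    child_members=tuple(sorted(map(tuple, map(sorted,
                                                              persistent))))))
    # deduplicate events triggered by the same parent on consecutive steps
    unique: list[FissionEvent] = []
    seen: set = set()
    for ev in events:
        key = ev.child_members
        if key not in seen:
            seen.add(key)
            unique.append(ev)
    return series, unique


def td_vs_compression_fit(points) -> tuple[float, float]:
    """Fit 1/t_d against the median compression; extrapolate to zero.

    ``points`` are (median_compression, t_d) pairs.  A least-squares line
    ``1/t_d = a * (x - x_0)`` is fitted; returns ``(a, x_0)`` where x_0
    is the compression at which stem-cell expansion vanishes (t_d -> inf).
    Requires >= 3 points with finite t_d and non-degenerate x.
    """
    pts = [(float(x), float(td)) for x, td in points if np.isfinite(td)]
    if len(pts) < 3:
        raise ValueError("need at least 3 points with finite t_d")
    x = np.array([p[0] for p in pts])
    y = 1.0 / np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: constant compression values")
    slope, intercept, _ = _pearson_fit(x, y)
    if slope == 0:
        raise ValueError("zero slope: no compression dependence")
    return float(slope), float(-intercept / slope)
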