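"""Trajectory analysis: motility, morphology, flow/traction and composites.

Implements the simulation-analysis procedures used to locate stiffness
optima: the overlap-method mean squared displacement and random motility
coefficient (2-D, ``<r^2> = 4 mu t``), the geometric cell-shape
reconstruction and its moment-ellipse aspect ratio, per-run flow/traction
summaries, the min-max-scaled composite metric with its log-Gaussian peak,
and the bootstrap test for a shift between two fitted stiffness optima.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import curve_fit
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from skimage.measure import regionprops

from .trajectory import Trajectory

__all__ = [
    "AnalysisError", "MsdCurve", "CompositeResult", "BootstrapResult",
    "msd_overlap", "random_motility_coefficient", "cell_shape",
    "aspect_ratio", "mean_aspect_ratio", "summarize_flow_traction",
    "composite_metric", "bootstrap_optimum_shift",
]

BODY_RADIUS_UM = 10.0


class AnalysisError(ValueError):
    """Raised when an analysis is undefined for the given data."""


# ---------------------------------------------------------------------------
# mean squared displacement and motility
# ---------------------------------------------------------------------------

@dataclass
class MsdCurve:
    """MSD versus time lag with per-lag uncertainty."""
    lags: np.ndarray      # s, strictly increasing
    msd: np.ndarray       # um^2
    sem: np.ndarray       # um^2, standard error per lag
    n: np.ndarray         # displacement samples per lag


def msd_overlap(positions: np.ndarray, interval: float,
                max_lag: Optional[float] = None,
                valid_steps: Optional[np.ndarray] = None) -> MsdCurve:
    """Overlap-method MSD: average squared displacement over all start times.

    Parameters
    ----------
    positions : (n, 2) array
        Sampled positions (um) at fixed spacing ``interval`` (s).
    max_lag : float, optional
        Largest lag to evaluate (default: (n-1) * interval).
    valid_steps : (n-1,) bool array, optional
        Steps flagged False (e.g. solver-jump exclusions) invalidate every
        displacement pair spanning them.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2 or len(positions) < 2:
        raise AnalysisError("need at least two 2-D positions")
    if interval <= 0:
        raise AnalysisError("sampling interval must be > 0")
    n = len(positions)
    k_max = n - 1
    if max_lag is not None:
        k_max = min(k_max, int(math.floor(max_lag / interval + 1e-9)))
    if k_max < 1:
        raise AnalysisError("max_lag shorter than the sampling interval")
    if valid_steps is None:
        bad = np.zeros(n - 1)
    else:
        valid_steps = np.asarray(valid_steps, dtype=bool)
        if valid_steps.shape != (n - 1,):
            raise AnalysisError("valid_steps must have length n-1")
        bad = (~valid_steps).astype(float)
    cum_bad = np.concatenate([[0.0], np.cumsum(bad)])
    lags, msd, sem, counts = [], [], [], []
    for k in range(1, k_max + 1):
        ok = (cum_bad[k:] - cum_bad[:-k]) == 0
        if not ok.any():
            continue
        d = positions[k:] - positions[:-k]
        sq = (d[:, 0] ** 2 + d[:, 1] ** 2)[ok]
        lags.append(k * interval)
        msd.append(sq.mean())
        counts.append(sq.size)
        sem.append(sq.std(ddof=1) / math.sqrt(sq.size) if sq.size > 1 else 0.0)
    if not lags:
        raise AnalysisError("all displacement pairs excluded")
    return MsdCurve(np.array(lags), np.array(msd), np.array(sem),
                    np.array(counts))


def random_motility_coefficient(traj: Trajectory,
                                sample_interval: float = 900.0,
                                exclude_time: float = 3600.0,
                                speed_cutoff_um_s: float = 1.0,
                                max_lag: float = 18000.0) -> float:
    """Random motility coefficient mu (um^2/min) from one trajectory.

    Positions are resampled to ``sample_interval`` (15 min by default), the
    first ``exclude_time`` seconds are discarded, interval displacements
    implying speeds >= ``speed_cutoff_um_s`` are removed, and a line through
    the origin, inversely weighted by the per-lag standard error, is fit to
    the first half of the overlap-method MSD curve (lags up to ``max_lag``,
    5 h by default as in the migration-movie protocol); mu is slope/4.
    """
    stride = max(1, int(round(sample_interval / traj.record_interval)))
    dt = stride * traj.record_interval
    keep = traj.cell["t_s"].to_numpy() >= exclude_time - 1e-9
    pos = traj.positions_um()[keep][::stride]
    if len(pos) < 3:
        raise AnalysisError("not enough records after exclusion to fit mu")
    step = np.diff(pos, axis=0)
    speed = np.hypot(step[:, 0], step[:, 1]) / dt
    valid = speed < speed_cutoff_um_s
    curve = msd_overlap(pos, dt, max_lag=max_lag, valid_steps=valid)
    return fit_motility(curve)


def fit_motility(curve: MsdCurve) -> float:
    """Origin-constrained weighted fit of the first half of an MSD curve."""
    n_half = max(1, len(curve.lags) // 2)
    t = curve.lags[:n_half]
    y = curve.msd[:n_half]
    s = curve.sem[:n_half].copy()
    positive = s[s > 0]
    s[s == 0] = positive.min() if positive.size else 1.0
    w = 1.0 / s ** 2
    denom = float(np.sum(w * t * t))
    if denom == 0.0:
        raise AnalysisError("degenerate MSD curve: zero lag support")
    slope = float(np.sum(w * t * y)) / denom        # um^2/s
    return slope / 4.0 * 60.0                        # um^2/min


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def cell_shape(thetas: Sequence[float], lengths_um: Sequence[float],
               center: Tuple[float, float] = (0.0, 0.0),
               body_radius: float = BODY_RADIUS_UM) -> Polygon:
    """Geometric cell outline: a body disc plus one tangent wedge per module.

    A disc of ``body_radius`` (10 um) is centred on the cell body; each
    module's tip is placed ``length + body_radius`` from the centre (the
    module starts at the edge of the body, not its centre) and joined to the
    disc by its two tangent lines.
    """
    cx, cy = center
    disc = Point(cx, cy).buffer(body_radius, quad_segs=64)
    parts = [disc]
    for theta, l_um in zip(thetas, lengths_um):
        L = l_um + body_radius
        if L <= body_radius * (1 + 1e-12):
            continue
        tip = (cx + L * math.cos(theta), cy + L * math.sin(theta))
        gamma = math.acos(body_radius / L)
        t1 = (cx + body_radius * math.cos(theta + gamma),
              cy + body_radius * math.sin(theta + gamma))
        t2 = (cx + body_radius * math.cos(theta - gamma),
              cy + body_radius * math.sin(theta - gamma))
        parts.append(Polygon([tip, t1, t2]))
    return unary_union(parts)


def aspect_ratio(region: Polygon, pixel: float = 0.1) -> float:
    """Major/minor axis ratio of the moment-matched ellipse (>= 1).

    The region is rasterized on a ``pixel``-sized grid (0.1 um default) and
    the region-properties ellipse convention is applied to the mask.
    """
    if region.is_empty or region.area == 0:
        raise AnalysisError("zero-area region")
    minx, miny, maxx, maxy = region.bounds
    xs = np.arange(minx + pixel / 2, maxx, pixel)
    ys = np.arange(miny + pixel / 2, maxy, pixel)
    gx, gy = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(region, gx.ravel(), gy.ravel())
    img = mask.reshape(gy.shape).astype(np.uint8)
    if img.sum() == 0:
        raise AnalysisError("region rasterized to an empty mask")
    props = regionprops(img)[0]
    minor = props.axis_minor_length
    if minor == 0:
        raise AnalysisError("degenerate (zero-width) region")
    return props.axis_major_length / minor


def mean_aspect_ratio(traj: Trajectory, sample_interval: float = 900.0,
                      exclude_time: float = 3600.0) -> float:
    """Time-averaged aspect ratio of the reconstructed cell shape."""
    stride = max(1, int(round(sample_interval / traj.record_interval)))
    times = traj.cell["t_s"].to_numpy()
    times = times[times >= exclude_time - 1e-9][::stride]
    if times.size == 0:
        raise AnalysisError("no records after exclusion")
    by_t = traj.modules.groupby("t_s")
    ratios = []
    for t in times:
        try:
            grp = by_t.get_group(t)
        except KeyError:          # no live modules at this record
            ratios.append(1.0)
            continue
        region = cell_shape(grp["theta_rad"].to_numpy(),
                            grp["length_nm"].to_numpy() / 1000.0)
        ratios.append(aspect_ratio(region))
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# flow / traction summaries
# ---------------------------------------------------------------------------

def summarize_flow_traction(traj: Trajectory,
                            exclude_time: float = 3600.0) -> Tuple[float, float]:
    """(mean flow nm/s, mean traction pN), first ``exclude_time`` discarded.

    Flow is the time average of the per-record mean module flow; traction is
    the time average of the per-record sum of module force magnitudes plus
    the cell-body force magnitude.
    """
    cell = traj.cell[traj.cell["t_s"] >= exclude_time - 1e-9]
    if cell.empty:
        raise AnalysisError("no records after exclusion")
    flow = float(np.nanmean(cell["mean_flow_nm_s"].to_numpy())) \
        if not np.all(np.isnan(cell["mean_flow_nm_s"])) else math.nan
    traction = float(cell["total_traction_pN"].mean())
    return flow, traction


# ---------------------------------------------------------------------------
# composite metric
# ---------------------------------------------------------------------------

@dataclass
class CompositeResult:
    """Scaled composite metric on a stiffness grid with its fitted optimum."""
    stiffness: np.ndarray
    scaled: Dict[str, np.ndarray]
    composite: np.ndarray          # in [0, 1], spans both endpoints
    log10_peak: float              # fitted peak location, log10(stiffness)
    log_width: float               # fitted Gaussian sigma in decades
    amplitude: float
    optimum: float = field(init=False)

    def __post_init__(self) -> None:
        self.optimum = 10.0 ** self.log10_peak


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise AnalysisError("constant metric series cannot be min-max scaled")
    return (values - lo) / (hi - lo)


def _log_gaussian(log_k: np.ndarray, amp: float, mu: float,
                  sigma: float) -> np.ndarray:
    return amp * np.exp(-(log_k - mu) ** 2 / (2.0 * sigma ** 2))


def fit_log_gaussian(stiffness: np.ndarray,
                     values: np.ndarray) -> Tuple[float, float, float]:
    """Fit ``A exp(-(log10 k - mu)^2 / 2 sigma^2)``; variance unconstrained.

    Initialization: peak at the grid argmax, width one decade.
    Returns (amplitude, mu, sigma).
    """
    log_k = np.log10(stiffness)
    p0 = (float(values.max()), float(log_k[np.argmax(values)]), 1.0)
    try:
        popt, _ = curve_fit(_log_gaussian, log_k, values, p0=p0, maxfev=10000)
    except RuntimeError as err:
        raise AnalysisError(f"log-Gaussian fit failed: {err}") from err
    amp, mu, sigma = popt
    return float(amp), float(mu), abs(float(sigma))


def composite_metric(metrics: Mapping[str, Sequence[float]],
                     stiffness: Sequence[float],
                     invert: Iterable[str] = frozenset({"flow"})
                     ) -> CompositeResult:
    """Min-max scale each metric (inverting those named in ``invert``),
    average per stiffness, rescale the average to [0, 1], and fit the
    log-Gaussian peak.
    """
    stiffness = np.asarray(stiffness, dtype=float)
    if stiffness.ndim != 1 or len(stiffness) < 2:
        raise AnalysisError("need at least two stiffness grid points")
    if np.any(np.diff(stiffness) <= 0):
        raise AnalysisError("stiffness grid must be strictly increasing")
    invert = set(invert)
    scaled = {}
    for name, vals in metrics.items():
        v = np.asarray(vals, dtype=float)
        if v.shape != stiffness.shape:
            raise AnalysisError(f"metric {name!r} does not match the grid")
        if np.any(~np.isfinite(v)):
            raise AnalysisError(f"metric {name!r} contains non-finite values")
        scaled[name] = _minmax(-v if name in invert else v)
    if not scaled:
        raise AnalysisError("no metrics supplied")
    avg = np.mean(np.stack(list(scaled.values())), axis=0)
    composite = _minmax(avg)
    amp, mu, sigma = fit_log_gaussian(stiffness, composite)
    return CompositeResult(stiffness=stiffness, scaled=scaled,
                           composite=composite, log10_peak=mu,
                           log_width=sigma, amplitude=amp)


# ---------------------------------------------------------------------------
# bootstrap optimum-shift test
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    p_value: float
    observed_log_distance: float   # |log10 k_A - log10 k_B|
    null_distances: np.ndarray
    n_failed: int


GroupData = Mapping[str, Mapping[float, Sequence[float]]]


def _composite_peak(groups: Dict[str, Dict[float, np.ndarray]],
                    stiffness: np.ndarray,
                    invert: Iterable[str]) -> float:
    means = {m: np.array([np.mean(groups[m][k]) for k in stiffness])
             for m in groups}
    return composite_metric(means, stiffness, invert=invert).log10_peak


def bootstrap_optimum_shift(group_a: GroupData, group_b: GroupData,
                            n_boot: int = 10000, seed: int = 0,
                            invert: Iterable[str] = frozenset({"flow"})
                            ) -> BootstrapResult:
    """Shuffle test for a shift between two composite stiffness optima.

    At every (metric, stiffness) the two groups' measurements are pooled and
    randomly re-assigned to pseudo-groups whose sizes are the original
    sizes, randomly swapped in each shuffle.  Both composite metrics and
    log-Gaussian fits are recomputed and the log-distance between fitted
    peaks recorded; the p-value is the fraction of null distances at least
    as large as the observed one.
    """
    if n_boot < 100:
        raise AnalysisError("n_boot must be >= 100")
    metrics = sorted(group_a)
    if sorted(group_b) != metrics:
        raise AnalysisError("groups must share the same metrics")
    grids = {tuple(sorted(group_a[m])) for m in metrics} \
        | {tuple(sorted(group_b[m])) for m in metrics}
    if len(grids) != 1:
        raise AnalysisError("groups must share the stiffness grid")
    stiffness = np.array(grids.pop(), dtype=float)
    ga = {m: {k: np.asarray(group_a[m][k], dtype=float) for k in stiffness}
          for m in metrics}
    gb = {m: {k: np.asarray(group_b[m][k], dtype=float) for k in stiffness}
          for m in metrics}
    for m in metrics:
        for k in stiffness:
            if ga[m][k].size + gb[m][k].size < 2:
                raise AnalysisError(
                    f"fewer than 2 pooled measurements at metric {m!r}, "
                    f"stiffness {k}")
    peak_a = _composite_peak(ga, stiffness, invert)
    peak_b = _composite_peak(gb, stiffness, invert)
    observed = abs(peak_a - peak_b)

    rng = np.random.default_rng(seed)
    null = []
    failed = 0
    for _ in range(n_boot):
        pa: Dict[str, Dict[float, np.ndarray]] = {}
        pb: Dict[str, Dict[float, np.ndarray]] = {}
        for m in metrics:
            pa[m] = {}
            pb[m] = {}
            for k in stiffness:
                pool = np.concatenate([ga[m][k], gb[m][k]])
                n_a = ga[m][k].size
                if rng.random() < 0.5:   # randomly switch the group sizes
                    n_a = pool.size - n_a
                perm = rng.permutation(pool.size)
                pa[m][k] = pool[perm[:n_a]]
                pb[m][k] = pool[perm[n_a:]]
        try:
            d = abs(_composite_peak(pa, stiffness, invert)
                    - _composite_peak(pb, stiffness, invert))
        except AnalysisError:
            failed += 1
            continue
        null.append(d)
    if failed > n_boot // 10:
        raise AnalysisError(f"{failed}/{n_boot} bootstrap fits failed")
    null_arr = np.array(null)
    p = float(np.mean(null_arr >= observed - 1e-12)) if null_arr.size else math.nan
    return BootstrapResult(p_value=p, observed_log_distance=observed,
                           null_distances=null_arr, n_failed=failed)


def groups_from_long(df: pd.DataFrame, group: str) -> GroupData:
    """Extract ``{metric: {stiffness: values}}`` for one group label from a
    long-format table with columns stiffness, metric, group, value."""
    sub = df[df["group"] == group]
    out: Dict[str, Dict[float, np.ndarray]] = {}
    for (metric, k), g in sub.groupby(["metric", "stiffness"]):
        out.setdefault(metric, {})[float(k)] = g["value"].to_numpy(float)
    return out
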