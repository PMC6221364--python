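"""Embryo-scale expression-pattern statistics.

From per-nucleus activity, computes the instantaneous spot probability
``P_SPOT(t, x)`` (fraction of nuclei with a visible spot, per AP bin and
time), the cumulative per-cycle activity probability ``P_ON(x)``, aligns
embryos at the ``P_ON = 0.5`` boundary, fits a sigmoid to profile data to
read off the boundary position ``X_0`` and steepness ``H`` (a Hill
coefficient in concentration under the exponential gradient), measures
boundary formation times, and partitions the expression domain into the
anterior saturating zone and the boundary zone with a sliding-window
Kolmogorov-Smirnov test.

The fitted sigmoid is ``f(x) = f_max / (1 + exp(H (x - x0) / lambda_el))``;
with an exponential gradient of decay length ``lambda_el`` this is exactly
a Hill function of exponent ``H`` in concentration, so ``H`` is reported on
the Hill scale and the ``lambda_el`` convention is recorded in every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "PatternGrid",
    "PonProfile",
    "SigmoidFit",
    "FormationTime",
    "ZonePartition",
    "compute_pspot",
    "compute_pon",
    "align_embryos",
    "fit_sigmoid",
    "formation_time",
    "boundary_from_density",
    "partition_zones",
    "steepness_over_time",
    "plot_kymograph",
]

#: Default AP bin width (% EL), about one internuclear spacing at nc12.
DEFAULT_BIN_WIDTH = 2.0


@dataclass
class PatternGrid:
    """``P_SPOT`` on a (time x AP-bin) grid with per-bin nucleus counts."""

    x_centers: np.ndarray
    times: np.ndarray
    pspot: np.ndarray   # shape (T, X); NaN where a bin is empty
    counts: np.ndarray  # per-bin nucleus counts, shape (X,)


@dataclass
class PonProfile:
    """Cumulative activity probability per AP bin."""

    x_centers: np.ndarray
    pon: np.ndarray
    counts: np.ndarray


@dataclass
class SigmoidFit:
    """Logistic boundary fit: position, steepness and uncertainty."""

    x0: float
    hill: float
    f_max: float
    x0_ci: tuple[float, float]
    hill_ci: tuple[float, float]
    lambda_el: float
    rss: float
    ok: bool


@dataclass
class FormationTime:
    t_first: float
    t_steady: float
    delta_t: float


@dataclass
class ZonePartition:
    """Anterior/boundary zone split from the sliding KS test."""

    edge_x: float | None
    window_centers: np.ndarray
    p_values: np.ndarray
    alpha: float


def _bin_edges(values: np.ndarray, bins) -> np.ndarray:
    if np.isscalar(bins):
        lo, hi = float(np.min(values)), float(np.max(values))
        n = max(1, int(np.ceil((hi - lo) / float(bins))))
        return lo + float(bins) * np.arange(n + 1)
    return np.asarray(bins, dtype=float)


def compute_pspot(positions: np.ndarray, activity: np.ndarray, times: np.ndarray,
                  bins=DEFAULT_BIN_WIDTH) -> PatternGrid:
    """Fraction of nuclei with a visible spot, per AP bin and time point.

    ``activity`` is boolean, shape (n_nuclei, n_times).  Empty bins yield
    NaN, never a fabricated zero.
    """
    positions = np.asarray(positions, dtype=float)
    activity = np.asarray(activity, dtype=bool)
    times = np.asarray(times, dtype=float)
    if activity.shape != (positions.size, times.size):
        raise ValueError("activity must be (n_nuclei, n_times)")
    edges = _bin_edges(positions, bins)
    which = np.digitize(positions, edges) - 1
    nbin = edges.size - 1
    counts = np.zeros(nbin, dtype=int)
    psp = np.full((times.size, nbin), np.nan)
    for b in range(nbin):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            psp[:, b] = activity[sel].mean(axis=0)
    return PatternGrid(0.5 * (edges[:-1] + edges[1:]), times, psp, counts)


def compute_pon(positions: np.ndarray, ever_active: np.ndarray,
                bins=DEFAULT_BIN_WIDTH) -> PonProfile:
    """Probability that a nucleus transcribes at any time during the cycle.

    ``ever_active`` may be a boolean vector (one flag per nucleus) or the
    per-frame activity matrix, in which case a nucleus counts as ON if it
    was ever active.  By construction ``P_ON(x) >= P_SPOT(t, x)`` for every
    time.
    """
    positions = np.asarray(positions, dtype=float)
    ever = np.asarray(ever_active, dtype=bool)
    if ever.ndim == 2:
        ever = ever.any(axis=1)
    if ever.shape != positions.shape:
        raise ValueError("one flag per nucleus required")
    edges = _bin_edges(positions, bins)
    which = np.digitize(positions, edges) - 1
    nbin = edges.size - 1
    counts = np.zeros(nbin, dtype=int)
    pon = np.full(nbin, np.nan)
    for b in range(nbin):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            pon[b] = ever[sel].mean()
    return PonProfile(0.5 * (edges[:-1] + edges[1:]), pon, counts)


def _crossing(x: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First anterior-to-posterior downward crossing, linearly interpolated."""
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    for i in range(x.size - 1):
        if (y[i] - level) * (y[i + 1] - level) <= 0 and y[i] != y[i + 1]:
            return float(x[i] + (level - y[i]) * (x[i + 1] - x[i]) / (y[i + 1] - y[i]))
    return None


def align_embryos(profiles: list[PonProfile], level: float = 0.5,
                  ) -> tuple[np.ndarray, list[PonProfile]]:
    """Shift each embryo so its ``P_ON = 0.5`` crossing sits at 0% EL.

    Compensates inter-embryo variability of the activator gradient (a few
    % EL) so embryos can be pooled.  Returns the applied shifts and the
    shifted profiles; embryos whose profile never crosses the level are
    excluded with a warning (their shift is NaN).
    """
    shifts = np.full(len(profiles), np.nan)
    aligned: list[PonProfile] = []
    for i, prof in enumerate(profiles):
        xc = _crossing(prof.x_centers, prof.pon, level)
        if xc is None:
            warnings.warn(f"embryo {i}: P_ON never crosses {level}; excluded",
                          stacklevel=2)
            continue
        shifts[i] = -xc
        aligned.append(PonProfile(prof.x_centers - xc, prof.pon, prof.counts))
    return shifts, aligned


def _logistic(x, f_max, hill, x0, lambda_el):
    return f_max / (1.0 + np.exp(hill * (x - x0) / lambda_el))


def fit_sigmoid(x: np.ndarray, y: np.ndarray, lambda_el: float = 20.0,
                p0: tuple | None = None, counts: np.ndarray | None = None) -> SigmoidFit:
    """Least-squares logistic fit of a boundary profile.

    ``f_max`` is estimated jointly (the anterior plateau may sit below 1 at
    early times).  When ``counts`` (nuclei per bin) are given, the fit is
    iteratively reweighted by the binomial variance ``f (1 - f) / n`` — the
    efficient weighting for activity fractions.  Confidence intervals are
    +/-1.96 sigma from the covariance of the fit.  Data that do not bracket
    the half-maximum are flagged ``ok=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if counts is not None:
        counts = np.asarray(counts, dtype=float)[keep]
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 finite points")
    if p0 is None:
        f0 = max(float(np.nanmax(y)), 1e-6)
        xh = _crossing(x[np.argsort(x)], y[np.argsort(x)], f0 / 2)
        p0 = (f0, 2.0, xh if xh is not None else float(np.median(x)))
    model = lambda xx, f, h, x0: _logistic(xx, f, h, x0, lambda_el)
    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
        if counts is not None:
            for _ in range(3):
                f = model(x, *popt)
                var = np.clip(f * (popt[0] - f) / max(popt[0], 1e-9), 1e-3, None) / counts
                popt, pcov = curve_fit(model, x, y, p0=popt, sigma=np.sqrt(var),
                                       absolute_sigma=True, maxfev=20000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    except RuntimeError:
        return SigmoidFit(np.nan, np.nan, np.nan, (np.nan, np.nan),
                          (np.nan, np.nan), lambda_el, np.nan, False)
    f_max, hill, x0 = popt
    rss = float(np.sum((y - _logistic(x, *popt, lambda_el)) ** 2))
    brackets = (y.min() < f_max / 2 < y.max())
    ok = bool(brackets and np.isfinite(perr).all() and hill >= 0)
    return SigmoidFit(float(x0), float(hill), float(f_max),
                      (float(x0 - 1.96 * perr[2]), float(x0 + 1.96 * perr[2])),
                      (float(hill - 1.96 * perr[1]), float(hill + 1.96 * perr[1])),
                      lambda_el, rss, ok)


def formation_time(times: np.ndarray, values: np.ndarray,
                   plateau_tol: float = 0.05,
                   noise_floor: float | None = None) -> FormationTime:
    """Onset and settling of a ``P_SPOT`` time series at one position.

    ``t_first`` is the first time above the noise floor (default: twice the
    SD of the pre-onset baseline, zero for a clean series), ``t_steady`` the
    first time within ``plateau_tol`` of the plateau (the mean of the last
    tenth of the series), and ``delta_t`` their difference — the boundary
    formation time when evaluated at the boundary position.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 3:
        raise ValueError("series too short")
    plateau = float(np.nanmean(values[-max(3, values.size // 10):]))
    if not np.isfinite(plateau) or plateau <= 0:
        raise ValueError("series has no positive plateau")
    if noise_floor is None:
        base = values[values < 0.1 * plateau]
        noise_floor = 2.0 * float(np.std(base)) if base.size else 0.0
    lo = np.nonzero(values > noise_floor)[0]
    hi = np.nonzero(np.abs(values - plateau) <= plateau_tol * plateau)[0]
    if lo.size == 0 or hi.size == 0:
        raise ValueError("series never rises above the floor or reaches its plateau")
    t_first = float(times[lo[0]])
    t_steady = float(times[hi[hi >= lo[0]][0]]) if np.any(hi >= lo[0]) else float(times[hi[0]])
    return FormationTime(t_first, t_steady, t_steady - t_first)


def boundary_from_density(positions: np.ndarray, bins=DEFAULT_BIN_WIDTH,
                          smooth_window: int = 3) -> float:
    """Boundary as the position of steepest drop of the active-nucleus density."""
    positions = np.asarray(positions, dtype=float)
    edges = _bin_edges(positions, bins)
    if edges.size < 3:
        raise ValueError("need at least 2 bins")
    dens, _ = np.histogram(positions, edges)
    dens = dens.astype(float)
    if smooth_window > 1:
        dens = np.convolve(dens, np.ones(smooth_window) / smooth_window, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    deriv = np.gradient(dens, centers)
    if np.allclose(deriv, 0):
        warnings.warn("flat density: boundary undefined", stacklevel=2)
        return np.nan
    # the expression domain is anterior-high: its boundary is the steepest
    # decrease of the density toward the posterior
    j = int(np.argmin(deriv))
    return float(centers[j])


def partition_zones(x: np.ndarray, values: np.ndarray, window: float = 5.0,
                    alpha: float = 0.05, min_samples: int = 5) -> ZonePartition:
    """Split the expression domain into saturating and boundary zones.

    Slides a window of width ``window`` (% EL) along the axis and compares
    the feature values inside it against the most-anterior window by a
    two-sample Kolmogorov-Smirnov test; the zone edge is the first (most
    anterior) window whose distribution differs at level ``alpha``.  Windows
    with fewer than ``min_samples`` values are widened with a warning.
    """
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(values)
    x, values = x[keep], values[keep]
    if x.size < 2 * min_samples:
        raise ValueError("not enough samples to partition")
    lo, hi = x.min(), x.max()
    ref = values[x < lo + window]
    step = window / 2.0
    centers, pvals = [], []
    c = lo + 1.5 * window
    while c <= hi - window / 2 + 1e-9:
        sel = (x >= c - window / 2) & (x < c + window / 2)
        w = window
        while sel.sum() < min_samples and w < (hi - lo):
            w *= 1.5
            sel = (x >= c - w / 2) & (x < c + w / 2)
            warnings.warn(f"window at {c:.1f}% EL widened to {w:.1f}% EL",
                          stacklevel=2)
        if sel.sum() >= 2:
            pvals.append(stats.ks_2samp(ref, values[sel]).pvalue)
            centers.append(c)
        c += step
    centers = np.asarray(centers)
    pvals = np.asarray(pvals)
    below = np.nonzero(pvals < alpha)[0]
    edge = float(centers[below[0]]) if below.size else None
    return ZonePartition(edge, centers, pvals, alpha)


def steepness_over_time(grid: PatternGrid, lambda_el: float = 20.0,
                        ) -> pd.DataFrame:
    """Sigmoid steepness ``H(t)`` fitted independently on every time slice.

    Slices that cannot be fitted (no boundary in view yet, degenerate data)
    are masked with NaN.
    """
    rows = []
    for j, t in enumerate(grid.times):
        y = grid.pspot[j]
        try:
            fit = fit_sigmoid(grid.x_centers, y, lambda_el=lambda_el)
            ok = fit.ok
        except (ValueError, FloatingPointError):
            fit, ok = None, False
        rows.append({
            "time_s": float(t),
            "hill": fit.hill if ok else np.nan,
            "x0": fit.x0 if ok else np.nan,
            "f_max": fit.f_max if ok else np.nan,
            "hill_lo": fit.hill_ci[0] if ok else np.nan,
            "hill_hi": fit.hill_ci[1] if ok else np.nan,
            "ok": ok,
        })
    return pd.DataFrame(rows)


def plot_kymograph(grid: PatternGrid, path=None, title: str = "P_SPOT(t, x)"):
    """Heat-map kymograph (AP position horizontal, time increasing downward)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(grid.pspot, aspect="auto", origin="upper", cmap="inferno",
                   vmin=0, vmax=1,
                   extent=[grid.x_centers[0], grid.x_centers[-1],
                           grid.times[-1], grid.times[0]])
    ax.set_xlabel("AP position (% EL)")
    ax.set_ylabel("time in cycle (s)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="P_SPOT")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
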