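"""Higuchi's fractal dimension (HFD) of a one-dimensional time series.

Higuchi's estimator quantifies the fractal dimension of the *graph* of a
time series — a number between 1 (a smooth differentiable curve) and 2 (a
curve so irregular it tends to fill the plane).  The algorithm builds, for
every time step ``k``, the ``k`` decimated subseries

    y_k^m : y(m), y(m+k), y(m+2k), ..., y(m + int((N-m)/k) * k),   m = 1..k

(1-based indices), measures the normalised length ``L_m(k)`` of each, and
averages them into a mean curve length ``L(k)``.  If the series is fractal
with dimension FD then ``L(k) ~ k**(-FD)``, so FD is recovered as the
negative slope of an ordinary least-squares fit of ``log L(k)`` against
``log k``.  The single free parameter is ``k_max``, the largest time step
entering the regression.

Amplitude plays no role: ``L(k)`` is homogeneous of degree one in the
signal, so an affine transform ``a*y + b`` shifts every ``log L(k)`` by the
same constant and leaves the slope — hence the estimate — unchanged.

All public functions accept plain sequences or numpy arrays; this module
performs no file I/O.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterError",
    "DegenerateWindowError",
    "HFDFit",
    "WindowedHFD",
    "KmaxSweep",
    "build_subseries",
    "curve_length",
    "mean_curve_length",
    "curve_length_profile",
    "higuchi_fd",
    "windowed_hfd",
    "kmax_sweep",
    "select_kmax",
]

DEFAULT_K_MAX = 65
DEFAULT_WINDOW_SECONDS = 2.0
DEFAULT_K_MAX_GRID = range(2, 129)


class ParameterError(ValueError):
    """An argument violates the bounds of Higuchi's construction."""


class DegenerateWindowError(ValueError):
    """The window is constant: every curve length is zero, FD undefined."""


@dataclass(frozen=True)
class HFDFit:
    """Result of one Higuchi log-log regression.

    Attributes
    ----------
    fd
        Estimated fractal dimension, ``-slope``; reported unclipped.
    slope
        Slope of the OLS regression of ``log L(k)`` on ``log k``.
    fit_points
        ``(log k, log L(k))`` pairs entering the regression.
    fit_r2
        Coefficient of determination of the regression.
    k_max
        Largest time step used.
    fit_k_min
        Smallest time step used (1 by default).
    """

    fd: float
    slope: float
    fit_points: np.ndarray
    fit_r2: float
    k_max: int
    fit_k_min: int = 1


@dataclass(frozen=True)
class WindowedHFD:
    """Windowed HFD of a longer series: the time average and its parts."""

    fd: float
    window_fits: list[HFDFit]
    n_windows: int
    n_dropped: int
    window_samples: int


@dataclass
class KmaxSweep:
    """Grand-average HFD as a function of ``k_max``.

    ``grand_avg_hfd[i]`` is the whole-sample mean (over subjects) of the
    whole-brain windowed HFD computed with ``k_max = k_max_grid[i]``.
    Per-group curves and standard errors are retained for plotting.
    """

    k_max_grid: np.ndarray
    grand_avg_hfd: np.ndarray
    per_subject: np.ndarray  # subjects x grid
    subject_ids: list[str]
    groups: list[str] | None = None
    selected_k_max: int | None = None

    def group_curves(self) -> dict[str, np.ndarray]:
        if self.groups is None:
            return {}
        out: dict[str, np.ndarray] = {}
        g = np.asarray(self.groups)
        for label in dict.fromkeys(self.groups):
            out[label] = self.per_subject[g == label].mean(axis=0)
        return out


def _as_window(y: Sequence[float] | np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ParameterError(f"expected a 1-D series, got shape {y.shape}")
    if y.size < 4:
        raise ParameterError(f"series too short: N={y.size} < 4")
    if not np.all(np.isfinite(y)):
        raise ParameterError("series contains non-finite values")
    return y


def _check_km(n: int, k: int, m: int) -> None:
    if k < 1:
        raise ParameterError(f"k={k} must be >= 1")
    if k >= n:
        raise ParameterError(f"k={k} must be < N={n}")
    if not 1 <= m <= k:
        raise ParameterError(f"m={m} must satisfy 1 <= m <= k={k}")


def build_subseries(y: Sequence[float], k: int, m: int) -> np.ndarray:
    """Decimated subseries ``y(m), y(m+k), ..., y(m + int((N-m)/k)*k)``.

    ``m`` and the formula are 1-based, as in Higuchi's construction; the
    returned array has ``int((N-m)/k) + 1`` samples.
    """
    y = _as_window(y)
    n = y.size
    _check_km(n, k, m)
    return y[m - 1 :: k].copy()


def curve_length(y: Sequence[float], k: int, m: int) -> float:
    """Normalised length ``L_m(k)`` of the subseries starting at sample m.

    ``L_m(k) = (1/k) * [(N-1) / (int((N-m)/k)*k)] * sum_i |y(m+ik) - y(m+(i-1)k)|``
    with i running to ``int((N-m)/k)``.  Zero for a constant subseries.
    """
    y = _as_window(y)
    n = y.size
    _check_km(n, k, m)
    n_i = (n - m) // k
    if n_i < 1:
        raise ParameterError(
            f"window too short for k={k}, m={m}: int((N-m)/k)={n_i} < 1"
        )
    sub = y[m - 1 :: k]
    total = float(np.abs(np.diff(sub)).sum())
    return total * (n - 1) / (n_i * k) / k


def mean_curve_length(y: Sequence[float], k: int) -> float:
    """Mean curve length ``L(k) = (1/k) * sum_{m=1..k} L_m(k)``."""
    y = _as_window(y)
    n = y.size
    if k < 1 or k >= n:
        raise ParameterError(f"k={k} out of range for N={n}")
    if (n - k) // k < 1:
        raise ParameterError(f"window too short for k={k}: need N >= 2k")
    return float(np.mean([curve_length(y, k, m) for m in range(1, k + 1)]))


def curve_length_profile(y: np.ndarray, k_max: int) -> np.ndarray:
    """``L(k)`` for k = 1..k_max, vectorised.

    For a fixed k the lag-k absolute increments ``|y(j+k) - y(j)|`` are
    shared across the k subseries: increment j belongs to the subseries
    starting at m = (j mod k) + 1.  A bincount over ``j mod k`` therefore
    yields every ``L_m(k)`` in one pass.
    """
    n = y.size
    if n < 2 * k_max:
        raise ParameterError(
            f"window too short for k_max={k_max}: need N >= 2*k_max (N={n})"
        )
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        d = np.abs(y[k:] - y[:-k])
        sums = np.bincount(np.arange(n - k) % k, weights=d, minlength=k)
        counts = np.bincount(np.arange(n - k) % k, minlength=k)
        # counts[m-1] == int((N-m)/k) >= 1 is guaranteed by the N >= 2k check
        lm = sums * (n - 1) / (counts * k) / k
        out[k - 1] = lm.mean()
    return out


def _fit_loglog(lk: np.ndarray, k_max: int, fit_k_min: int) -> HFDFit:
    ks = np.arange(fit_k_min, k_max + 1)
    vals = lk[fit_k_min - 1 : k_max]
    if np.any(vals <= 0):
        raise DegenerateWindowError(
            "L(k) is zero for some k (constant window); FD undefined"
        )
    x = np.log(ks)
    y = np.log(vals)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    resid = y - (ym + slope * (x - xm))
    syy = float(((y - ym) ** 2).sum())
    r2 = 1.0 if syy == 0 else 1.0 - float((resid**2).sum()) / syy
    return HFDFit(
        fd=-slope,
        slope=slope,
        fit_points=np.column_stack([x, y]),
        fit_r2=r2,
        k_max=k_max,
        fit_k_min=fit_k_min,
    )


def higuchi_fd(
    y: Sequence[float], k_max: int = DEFAULT_K_MAX, *, fit_k_min: int = 1
) -> HFDFit:
    """Higuchi fractal dimension of a single window.

    Ordinary least squares of ``log L(k)`` against ``log k`` over
    ``k = fit_k_min .. k_max``; the estimate is ``-slope``.

    Raises
    ------
    ParameterError
        If ``k_max < 2`` or the window is too short (``N < 2*k_max``).
    DegenerateWindowError
        If the window is constant, so that some ``L(k) = 0``.
    """
    y = _as_window(y)
    if k_max < 2:
        raise ParameterError(f"k_max={k_max} must be >= 2")
    if not 1 <= fit_k_min < k_max:
        raise ParameterError(f"fit_k_min={fit_k_min} must satisfy 1 <= fit_k_min < k_max")
    if y.size < 2 * k_max:
        raise ParameterError(
            f"window of N={y.size} samples too short for k_max={k_max} (need N >= 2*k_max)"
        )
    lk = curve_length_profile(y, k_max)
    return _fit_loglog(lk, k_max, fit_k_min)


def _partition(series: np.ndarray, window_samples: int) -> np.ndarray:
    n_windows = series.size // window_samples
    if n_windows < 1:
        raise ParameterError(
            f"series of {series.size} samples shorter than one "
            f"{window_samples}-sample window"
        )
    return series[: n_windows * window_samples].reshape(n_windows, window_samples)


def windowed_hfd(
    series: Sequence[float],
    fs: float,
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    k_max: int = DEFAULT_K_MAX,
    *,
    fit_k_min: int = 1,
    keep_mask: Sequence[bool] | None = None,
) -> WindowedHFD:
    """Time-averaged HFD over consecutive non-overlapping windows.

    The series is cut into ``round(fs * window_seconds)``-sample windows
    (a trailing partial window is discarded), ``higuchi_fd`` is computed
    per window, and the arithmetic mean over windows is returned.  Constant
    windows are dropped with a logged count rather than aborting the
    average; ``keep_mask`` (e.g. from artifact rejection) excludes windows
    up front.
    """
    series = np.asarray(series, dtype=float)
    window_samples = int(round(fs * window_seconds))
    if window_samples < 4:
        raise ParameterError(f"window of {window_samples} samples is too short")
    windows = _partition(series, window_samples)
    if keep_mask is not None:
        keep = np.asarray(keep_mask, dtype=bool)
        if keep.size != windows.shape[0]:
            raise ParameterError(
                f"keep_mask has {keep.size} entries for {windows.shape[0]} windows"
            )
        windows = windows[keep]
        if windows.shape[0] == 0:
            raise ParameterError("all windows excluded by keep_mask")
    fits: list[HFDFit] = []
    dropped = 0
    for w in windows:
        try:
            fits.append(higuchi_fd(w, k_max, fit_k_min=fit_k_min))
        except DegenerateWindowError:
            dropped += 1
    if dropped:
        logger.warning("windowed_hfd: dropped %d constant window(s)", dropped)
    if not fits:
        raise DegenerateWindowError("every window was constant; FD undefined")
    return WindowedHFD(
        fd=float(np.mean([f.fd for f in fits])),
        window_fits=fits,
        n_windows=len(fits),
        n_dropped=dropped,
        window_samples=window_samples,
    )


def _windowed_fd_curve(
    series: np.ndarray,
    window_samples: int,
    grid: np.ndarray,
    fit_k_min: int,
) -> np.ndarray:
    """Mean-over-windows HFD for every k_max in ``grid`` in one pass.

    ``L(k)`` is computed once per window up to ``max(grid)``; the OLS slope
    for each prefix ``k = fit_k_min..g`` is then read off cumulative sums.
    """
    kmax = int(grid.max())
    windows = _partition(series, window_samples)
    logk = np.log(np.arange(1, kmax + 1))
    rows = []
    for w in windows:
        lk = curve_length_profile(w, kmax)
        if np.any(lk <= 0):
            continue
        rows.append(np.log(lk))
    if not rows:
        raise DegenerateWindowError("every window was constant")
    logl = np.stack(rows)  # windows x kmax
    i0 = fit_k_min - 1
    x = logk[i0:]
    ys = logl[:, i0:]
    n = np.arange(1, x.size + 1)
    cx, cxx = np.cumsum(x), np.cumsum(x * x)
    cy = np.cumsum(ys, axis=1)
    cxy = np.cumsum(ys * x, axis=1)
    sxx = cxx - cx**2 / n
    sxy = cxy - cx * cy / n
    fds = np.full((logl.shape[0], x.size), np.nan)
    valid = n >= 2
    fds[:, valid] = -(sxy[:, valid] / sxx[valid])
    idx = grid - fit_k_min  # prefix index for each grid value
    return fds[:, idx].mean(axis=0)


def kmax_sweep(
    subject_series: dict[str, np.ndarray] | Sequence[np.ndarray],
    fs: float,
    k_max_grid: Sequence[int] = DEFAULT_K_MAX_GRID,
    *,
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    fit_k_min: int = 1,
    groups: Sequence[str] | None = None,
) -> KmaxSweep:
    """Whole-brain average HFD as a function of ``k_max``.

    Each subject contributes a channels x samples matrix (or a single
    series); per grid value, the subject's whole-brain windowed HFD is the
    mean over channels and windows, and the grand average is the mean over
    subjects.  Per-group curves are retained when ``groups`` is given.
    """
    grid = np.asarray(sorted(set(int(g) for g in k_max_grid)))
    if grid.size == 0:
        raise ParameterError("empty k_max grid")
    if grid[0] < 2:
        raise ParameterError("k_max grid values must be >= 2")
    if isinstance(subject_series, dict):
        ids = list(subject_series)
        mats = [np.atleast_2d(np.asarray(v, dtype=float)) for v in subject_series.values()]
    else:
        mats = [np.atleast_2d(np.asarray(v, dtype=float)) for v in subject_series]
        ids = [f"S{i:03d}" for i in range(len(mats))]
    if not mats:
        raise ParameterError("empty subject collection")
    window_samples = int(round(fs * window_seconds))
    if window_samples < 2 * grid[-1]:
        raise ParameterError(
            f"{window_samples}-sample windows too short for k_max={grid[-1]}"
        )
    per_subject = np.empty((len(mats), grid.size))
    for i, mat in enumerate(mats):
        per_channel = np.stack(
            [_windowed_fd_curve(ch, window_samples, grid, fit_k_min) for ch in mat]
        )
        per_subject[i] = per_channel.mean(axis=0)
    sweep = KmaxSweep(
        k_max_grid=grid,
        grand_avg_hfd=per_subject.mean(axis=0),
        per_subject=per_subject,
        subject_ids=ids,
        groups=list(groups) if groups is not None else None,
    )
    sweep.selected_k_max = select_kmax(sweep)
    return sweep


def select_kmax(sweep: KmaxSweep) -> int:
    """The grid value whose grand-average HFD is nearest the median.

    The median of the grand-average curve is taken over all grid entries
    (midpoint of the two central values for an even-length grid); ties in
    distance are broken toward the smaller ``k_max``.
    """
    if sweep.k_max_grid.size == 0:
        raise ParameterError("empty sweep")
    med = float(np.median(sweep.grand_avg_hfd))
    dist = np.abs(sweep.grand_avg_hfd - med)
    # tolerance-aware tie-break toward the smaller k_max
    best = dist.min()
    tol = 1e-9 * max(1.0, abs(med))
    candidates = np.flatnonzero(dist <= best + tol)
    return int(sweep.k_max_grid[candidates[0]])
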