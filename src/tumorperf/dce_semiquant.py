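"""Semi-quantitative DCE-MRI analysis.

Works on the baseline-normalized enhancement

    dSI(t) = (SI(t) - mean baseline SI) / mean baseline SI

and derives, per voxel: the contrast-arrival time T0 (first sustained
crossing of a noise-scaled threshold), the time of maximum enhancement Tmax,
and areas under the dSI(t) curve over configurable windows after bolus
arrival (AUC60/90/150 and to-Tmax).  No pharmacokinetic model and no
arterial input function are involved; AUC is used precisely because it is
more reproducible than model-based parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .series import ImageSeries

logger = logging.getLogger(__name__)

#: AUC integration windows (seconds); "tmax" integrates up to each voxel's Tmax
DEFAULT_WINDOWS = (60.0, 90.0, 150.0, "tmax")


@dataclass
class DSISeries:
    """Baseline-normalized enhancement dSI(t) per voxel.

    ``valid_mask`` flags voxels with a usable (positive) baseline; dSI is
    NaN elsewhere.
    """

    data: np.ndarray  # (ny, nx, n_t)
    times_s: np.ndarray
    baseline_range: tuple[int, int]
    valid_mask: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class DCEMaps:
    """Bundle of semi-quantitative DCE parameter maps."""

    t0_s_map: np.ndarray
    global_arrival_s: float
    tmax_s_map: np.ndarray
    auc_maps: dict
    truncated: dict
    times_s: np.ndarray


def normalize_si(series: ImageSeries, baseline_range: tuple[int, int] = (0, 6)) -> DSISeries:
    """Normalize a dynamic series to its pre-contrast baseline.

    ``baseline_range`` is a half-open (start, stop) range of dynamic indices
    that must precede the bolus.  Voxels with non-positive baseline mean are
    flagged invalid and set to NaN, never silently zeroed.
    """
    if series.axis_kind != "time_s":
        raise ValueError(f"series must have a time_s axis, got {series.axis_kind}")
    i0, i1 = baseline_range
    n_t = series.n_axis
    if not (0 <= i0 < i1 <= n_t):
        raise ValueError(f"baseline_range {baseline_range} invalid for {n_t} dynamics")
    si = series.mean_over_repeats()
    baseline = si[..., i0:i1].mean(axis=-1)
    valid = baseline > 0
    if not np.all(valid):
        logger.warning("normalize_si: %d voxels with non-positive baseline excluded", int(np.sum(~valid)))
    with np.errstate(divide="ignore", invalid="ignore"):
        dsi = (si - baseline[..., None]) / baseline[..., None]
    dsi[~valid] = np.nan
    return DSISeries(dsi, series.axis_values.copy(), (i0, i1), valid)


def detect_bolus_arrival(
    dsi: DSISeries, k: float = 3.0, min_persist: int = 2
) -> tuple[np.ndarray, float]:
    """Per-voxel contrast-arrival time and the global bolus arrival.

    T0 is the first post-baseline time at which dSI exceeds ``k`` times the
    baseline standard deviation of dSI for at least ``min_persist``
    consecutive dynamics (the persistence requirement rejects single-frame
    noise spikes).  In noise-free voxels (zero baseline SD) the test falls
    back to dSI > 0.  Voxels that never cross get NaN; the global arrival is
    the earliest non-sentinel T0.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if min_persist < 1:
        raise ValueError("min_persist must be >= 1")
    i0, i1 = dsi.baseline_range
    if i1 - i0 < 3:
        raise ValueError("need at least 3 baseline frames to estimate the noise SD")
    y = dsi.data
    delta = y[..., i0:i1].std(axis=-1, ddof=1)
    zero_sd = delta <= 0
    if np.any(zero_sd & dsi.valid_mask):
        logger.info(
            "detect_bolus_arrival: %d noise-free voxels, falling back to dSI > 0",
            int(np.sum(zero_sd & dsi.valid_mask)),
        )
    thr = np.where(zero_sd, 0.0, k * delta)
    with np.errstate(invalid="ignore"):
        above = y > thr[..., None]
    # sustained crossing: all of the next min_persist dynamics above threshold
    sustained = above.copy()
    for j in range(1, min_persist):
        shifted = np.zeros_like(above)
        shifted[..., :-j] = above[..., j:]
        sustained &= shifted
    sustained[..., :i1] = False  # search after the baseline period
    any_hit = sustained.any(axis=-1)
    first = np.argmax(sustained, axis=-1)
    t0 = np.where(any_hit, dsi.times_s[first], np.nan)
    t0[~dsi.valid_mask] = np.nan
    finite = np.isfinite(t0)
    global_arrival = float(np.min(t0[finite])) if np.any(finite) else float("nan")
    return t0, global_arrival


def compute_tmax(dsi: DSISeries) -> np.ndarray:
    """Per-voxel time of maximum enhancement; ties break to the earliest time."""
    if dsi.data.shape[-1] == 0:
        raise ValueError("empty series")
    y = dsi.data
    all_nan = np.all(~np.isfinite(y), axis=-1)
    y_safe = np.where(np.isfinite(y), y, -np.inf)
    idx = np.argmax(y_safe, axis=-1)  # first occurrence on ties
    tmax = dsi.times_s[idx].astype(float)
    tmax[all_nan] = np.nan
    return tmax


def _integral_to(y: np.ndarray, times: np.ndarray, s) -> np.ndarray:
    """Integral of the piecewise-linear interpolant of y from times[0] to s.

    ``s`` may be a scalar or a per-voxel array; it is clipped to the time
    range (the caller flags truncation).
    """
    F = cumulative_trapezoid(y, times, axis=-1, initial=0.0)
    s = np.asarray(s, dtype=np.float64)
    s = np.broadcast_to(s, y.shape[:-1]).astype(np.float64)
    s_clip = np.clip(s, times[0], times[-1])
    j = np.searchsorted(times, np.nan_to_num(s_clip, nan=times[0]), side="right") - 1
    j = np.clip(j, 0, times.size - 2)
    t0 = times[j]
    t1 = times[j + 1]
    y0 = np.take_along_axis(y, j[..., None], axis=-1)[..., 0]
    y1 = np.take_along_axis(y, (j + 1)[..., None], axis=-1)[..., 0]
    F0 = np.take_along_axis(F, j[..., None], axis=-1)[..., 0]
    h = s_clip - t0
    ys = y0 + (y1 - y0) * h / (t1 - t0)
    out = F0 + h * (y0 + ys) / 2.0
    out = np.where(np.isfinite(s), out, np.nan)
    return out


def compute_auc(
    dsi: DSISeries, start_s: float, window, tmax_s_map: np.ndarray | None = None
) -> tuple[np.ndarray, bool]:
    """Trapezoidal AUC of dSI over [start, start + window] (units dSI * s).

    ``window`` is a duration in seconds or the string ``"tmax"``, in which
    case each voxel integrates from ``start`` to its own Tmax (requires
    ``tmax_s_map``).  Window edges falling between dynamics are handled by
    linear interpolation.  A window extending past the acquisition is
    integrated to the end and reported as truncated.
    """
    times = dsi.times_s
    if isinstance(window, str):
        if window != "tmax":
            raise ValueError(f"window must be a duration in seconds or 'tmax', got {window!r}")
        if tmax_s_map is None:
            raise ValueError("tmax window requires tmax_s_map")
        end = np.asarray(tmax_s_map, dtype=np.float64)
    else:
        if window <= 0:
            raise ValueError("window must be > 0")
        end = float(start_s) + float(window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        truncated = bool(np.any(np.asarray(end) > times[-1] + 1e-9))
    if truncated:
        logger.warning("compute_auc: window extends past acquisition end; integral truncated")
    auc = _integral_to(dsi.data, times, end) - _integral_to(dsi.data, times, start_s)
    return auc, truncated


def analyze_dce(
    series: ImageSeries,
    baseline_range: tuple[int, int] = (0, 6),
    k: float = 3.0,
    windows=DEFAULT_WINDOWS,
) -> DCEMaps:
    """Full semi-quantitative analysis of one dynamic series."""
    dsi = normalize_si(series, baseline_range)
    t0_map, global_arrival = detect_bolus_arrival(dsi, k=k)
    tmax_map = compute_tmax(dsi)
    auc_maps: dict = {}
    truncated: dict = {}
    if np.isfinite(global_arrival):
        for w in windows:
            key = "tmax" if isinstance(w, str) else int(w)
            auc_maps[key], truncated[key] = compute_auc(
                dsi, global_arrival, w, tmax_s_map=tmax_map
            )
    else:
        logger.warning("analyze_dce: no bolus arrival detected in any voxel; AUC maps skipped")
    return DCEMaps(
        t0_s_map=t0_map,
        global_arrival_s=global_arrival,
        tmax_s_map=tmax_map,
        auc_maps=auc_maps,
        truncated=truncated,
        times_s=dsi.times_s.copy(),
    )
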