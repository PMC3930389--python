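"""FAIR arterial-spin-labeling perfusion quantification.

FAIR (Flow-sensitive Alternating Inversion Recovery) interleaves
slice-selective and nonselective (global) inversions.  After a nonselective
inversion, inflowing arterial blood is inverted like the static tissue; after
a slice-selective inversion, fresh (non-inverted) blood flows into the slice
and accelerates the apparent recovery.  The magnetization difference

    dM(TI) = M_ss(TI) - M_ns(TI)

therefore carries the perfusion signal.  With negligible transit time the
single-compartment kinetic model gives

    dM(TI) = 2 M0 alpha (f/lambda) *
             (exp(-TI/T1app) - exp(-TI/T1a)) / (1/T1a - 1/T1app)

with the removable singularity at T1app == T1a handled by the limit
``2 M0 alpha (f/lambda) TI exp(-TI/T1a)``.  Here ``f`` is blood flow,
``lambda`` the blood/tissue water partition coefficient, ``T1a`` the arterial
blood T1 and ``T1app`` the apparent tissue T1 (1/T1app = 1/T1 + f/lambda).

Flow is stored and reported in mL/100 g/min throughout and converted to a
rate (1/ms) only inside the model, via ``f / (100 * 60 * 1000 * lambda)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .relaxometry import T1MapResult
from .series import ImageSeries

logger = logging.getLogger(__name__)

#: conversion from mL/100 g/min divided by lambda (mL/g) to a rate in 1/ms
_F_TO_RATE_MS = 100.0 * 60.0 * 1000.0


@dataclass(frozen=True)
class ASLConstants:
    """Physiological constants entering the FAIR quantification.

    ``lambda_part`` is the blood/tissue water partition coefficient (mL/g),
    ``t1a_ms`` the longitudinal relaxation time of arterial blood at 7 T,
    ``alpha`` the inversion efficiency, and ``transit_time_ms`` the arterial
    transit delay, fixed at zero (spin delivery is effectively instantaneous
    for thin inversion slabs in the mouse).
    """

    lambda_part: float = 0.9
    t1a_ms: float = 2210.0
    alpha: float = 1.0
    transit_time_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_part <= 0:
            raise ValueError("lambda_part must be > 0")
        if self.t1a_ms <= 0:
            raise ValueError("t1a_ms must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.transit_time_ms != 0.0:
            raise ValueError("transit_time_ms is fixed at 0 in this model")


DEFAULT_CONSTANTS = ASLConstants()


@dataclass
class DeltaMSeries:
    """Per-voxel dM(TI): repeat-averaged slice-selective minus nonselective."""

    data: np.ndarray  # (ny, nx, n_ti)
    ti_ms: np.ndarray
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.ti_ms = np.atleast_1d(np.asarray(self.ti_ms, dtype=np.float64))
        if self.data.shape[-1] != self.ti_ms.size:
            raise ValueError("last data axis must match the TI list")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class PerfusionMap:
    """Voxel-wise blood-flow estimate with fit diagnostics and ROI summary.

    ``f_map`` is in mL/100 g/min.  ``inclusion_mask`` marks voxels that
    survived the T1-fit quality filter (R^2 strictly greater than the
    threshold and a converged fit).  ``roi_mean``/``roi_sd`` and the
    histogram are computed over ``stats_mask`` (inclusion intersected with
    the user ROI when one is given).
    """

    f_map: np.ndarray
    residual_map: np.ndarray
    inclusion_mask: np.ndarray
    stats_mask: np.ndarray
    roi_mean: float
    roi_sd: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    r2_threshold: float


def t1app_from_t1(t1_ms, f, lambda_part: float = 0.9):
    """Apparent T1 (ms) from intrinsic T1 (ms) and flow (mL/100 g/min).

    1/T1app = 1/T1 + f/lambda, with f converted to 1/ms before dividing.
    """
    t1_ms = np.asarray(t1_ms, dtype=np.float64)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be > 0")
    f = np.asarray(f, dtype=np.float64)
    rate = 1.0 / t1_ms + f / (_F_TO_RATE_MS * lambda_part)
    return 1.0 / rate


def fair_delta_m_model(f, m0, t1app_ms, ti_ms, consts: ASLConstants | None = None):
    """Noise-free FAIR difference signal dM(TI).

    All arguments broadcast; ``f`` in mL/100 g/min, times in ms.  Returns the
    same signal units as ``m0``.  dM is nonnegative for f >= 0, vanishes at
    TI = 0, and is linear in f at fixed T1app.
    """
    consts = consts or DEFAULT_CONSTANTS
    f = np.asarray(f, dtype=np.float64)
    ti = np.asarray(ti_ms, dtype=np.float64)
    t1app = np.asarray(t1app_ms, dtype=np.float64)
    m0 = np.asarray(m0, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("flow f must be >= 0")
    if np.any(ti < 0):
        raise ValueError("ti_ms must be >= 0")

    r_a = 1.0 / consts.t1a_ms
    with np.errstate(divide="ignore", invalid="ignore"):
        r_app = 1.0 / t1app
        dr = r_a - r_app  # 1/ms
        near = np.abs(dr) < 1e-10
        dr_safe = np.where(near, 1.0, dr)
        general = (np.exp(-ti * r_app) - np.exp(-ti * r_a)) / dr_safe
    limit = ti * np.exp(-ti * r_a)
    shape_term = np.where(near, limit, general)
    k = f / (_F_TO_RATE_MS * consts.lambda_part)  # 1/ms
    return 2.0 * m0 * consts.alpha * k * shape_term


def compute_delta_m(control: ImageSeries, label: ImageSeries) -> DeltaMSeries:
    """Repeat-averaged dM(TI) = slice-selective minus nonselective.

    ``control`` is the nonselective (global) inversion series and ``label``
    the slice-selective one, so that dM is positive when non-inverted blood
    flows into the slice.
    """
    for name, s in (("control", control), ("label", label)):
        if s.axis_kind != "ti_ms":
            raise ValueError(f"{name} series must have a ti_ms axis, got {s.axis_kind}")
    if control.grid_shape != label.grid_shape:
        raise ValueError(
            f"grid mismatch: control {control.grid_shape} vs label {label.grid_shape}"
        )
    if control.repeats != label.repeats:
        raise ValueError("control and label must have the same repeat count")
    if control.n_axis != label.n_axis or not np.allclose(
        control.axis_values, label.axis_values
    ):
        raise ValueError("control and label must share the same TI list")
    dm = label.mean_over_repeats() - control.mean_over_repeats()
    return DeltaMSeries(dm, control.axis_values.copy(), control.pixel_size_mm)


def fit_perfusion(
    delta_m: DeltaMSeries,
    t1fit: T1MapResult,
    consts: ASLConstants | None = None,
    r2_threshold: float = 0.9,
    roi_mask: np.ndarray | None = None,
    allow_negative: bool = False,
    hist_bins: int = 20,
) -> PerfusionMap:
    """Voxel-wise least-squares flow estimate with M0 and T1app held fixed.

    With M0 and T1app taken from the T1-mapping fit, dM(TI) is linear in the
    single free parameter f, so the least-squares estimate is the closed-form
    projection onto the model curve; the nonnegativity bound f >= 0 is
    enforced by clamping (exact for a one-parameter linear model).  Set
    ``allow_negative`` for a sign-preserving diagnostic mode.
    """
    consts = consts or DEFAULT_CONSTANTS
    if delta_m.grid_shape != t1fit.t1_map.shape:
        raise ValueError(
            f"grid mismatch: delta_m {delta_m.grid_shape} vs t1 map {t1fit.t1_map.shape}"
        )
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in [0, 1]")

    valid_t1 = t1fit.converged_mask & np.isfinite(t1fit.t1_map) & (t1fit.t1_map > 0)
    t1app = np.where(valid_t1, t1fit.t1_map, np.nan)
    m0 = np.where(valid_t1, t1fit.m0_map, np.nan)

    ti = delta_m.ti_ms
    # unit-flow basis curve per voxel
    g = fair_delta_m_model(1.0, m0[..., None], t1app[..., None], ti[None, None, :], consts)
    dm = delta_m.data
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sum(g * g, axis=-1)
        num = np.sum(dm * g, axis=-1)
        f = num / np.where(den > 0, den, np.nan)
    if not allow_negative:
        f = np.maximum(f, 0.0)  # NaN propagates
    residual = np.sum((dm - f[..., None] * g) ** 2, axis=-1)

    n_invalid = int(np.sum(~np.isfinite(f)))
    if n_invalid:
        logger.debug("fit_perfusion: %d voxels excluded (invalid T1 fit or zero basis)", n_invalid)

    inclusion = (
        np.isfinite(f)
        & t1fit.converged_mask
        & np.isfinite(t1fit.r2_map)
        & (t1fit.r2_map > r2_threshold)
    )
    stats_mask = inclusion if roi_mask is None else (inclusion & np.asarray(roi_mask, bool))
    vals = f[stats_mask]
    if vals.size:
        roi_mean = float(vals.mean())
        roi_sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        counts, edges = np.histogram(vals, bins=hist_bins)
    else:
        roi_mean, roi_sd = float("nan"), float("nan")
        counts, edges = np.zeros(hist_bins, dtype=int), np.linspace(0, 1, hist_bins + 1)
    return PerfusionMap(
        f_map=f,
        residual_map=residual,
        inclusion_mask=inclusion,
        stats_mask=stats_mask,
        roi_mean=roi_mean,
        roi_sd=roi_sd,
        hist_counts=counts,
        hist_edges=edges,
        r2_threshold=r2_threshold,
    )


def apply_quality_mask(map_arr: np.ndarray, r2_map: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Mask a voxel map to R^2 strictly greater than ``threshold`` (NaN elsewhere)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    map_arr = np.asarray(map_arr, dtype=np.float64)
    r2_map = np.asarray(r2_map, dtype=np.float64)
    if map_arr.shape != r2_map.shape:
        raise ValueError(f"shape mismatch: map {map_arr.shape} vs r2 {r2_map.shape}")
    with np.errstate(invalid="ignore"):
        keep = r2_map > threshold
    return np.where(keep, map_arr, np.nan)
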