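"""Voxel-wise T1 mapping from inversion-recovery and variable-flip-angle data.

Both fits exploit the fact that, once the relaxation rate is fixed, the
remaining parameters enter the signal model linearly (variable projection):

* inversion recovery: S(TI) = M0 (1 - 2 e TI-decay) = a + b exp(-TI/T1),
  with a = M0 and b = -2 M0 * inv_eff;
* spoiled gradient echo: S(theta) = M0 sin(theta)(1-E1)/(1-E1 cos(theta)),
  linear in M0 at fixed E1 = exp(-TR/T1).

The nonlinear dimension (T1) is profiled on a coarse log grid and refined by
a vectorized golden-section search, which converges to the continuous
least-squares optimum for every voxel simultaneously.

Magnitude IR data lose the sign of the early-TI points.  Polarity is
restored by trying sign flips of the points up to (and including) the
minimum-magnitude sample and keeping the candidate with the lower residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import ImageSeries

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0
T1_BOUNDS_MS = (50.0, 10000.0)


@dataclass
class T1MapResult:
    """Per-voxel three-parameter fit output.

    ``t1_map`` is the fitted longitudinal relaxation time in ms; when the
    series was acquired at the ASL slice with slice-selective inversion this
    is the apparent T1 (T1app).  ``r2_map`` is the coefficient of
    determination in [0, 1]; non-converged voxels are flagged, never silently
    filled.
    """

    m0_map: np.ndarray
    t1_map: np.ndarray
    r2_map: np.ndarray
    converged_mask: np.ndarray
    inv_eff_map: np.ndarray | None = None
    sse_map: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.t1_map.shape


def ir_signal(m0, t1_ms, inv_eff, ti_ms, magnitude: bool = False):
    """Three-parameter inversion-recovery signal S(TI) = M0 (1 - 2 k e^(-TI/T1)).

    ``inv_eff`` (k) is the inversion efficiency in [0, 1].  Returns the
    signed value, or its absolute value when ``magnitude`` is set.
    """
    t1_ms = np.asarray(t1_ms, dtype=np.float64)
    inv_eff = np.asarray(inv_eff, dtype=np.float64)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be > 0")
    if np.any((inv_eff < 0) | (inv_eff > 1)):
        raise ValueError("inv_eff must be in [0, 1]")
    s = np.asarray(m0, dtype=np.float64) * (
        1.0 - 2.0 * inv_eff * np.exp(-np.asarray(ti_ms, dtype=np.float64) / t1_ms)
    )
    return np.abs(s) if magnitude else s


def spgr_signal(m0, t1_ms, flip_deg, tr_ms):
    """Steady-state spoiled gradient-echo (FLASH) signal."""
    t1_ms = np.asarray(t1_ms, dtype=np.float64)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be > 0")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be > 0")
    e1 = np.exp(-tr_ms / t1_ms)
    th = np.deg2rad(np.asarray(flip_deg, dtype=np.float64))
    return np.asarray(m0, dtype=np.float64) * np.sin(th) * (1.0 - e1) / (1.0 - e1 * np.cos(th))


def _golden_min(sse_fun, lo, hi, iters: int = 60):
    """Vectorized golden-section minimizer over per-voxel brackets."""
    a = np.asarray(lo, dtype=np.float64).copy()
    b = np.asarray(hi, dtype=np.float64).copy()
    for _ in range(iters):
        w = b - a
        c = b - _INVPHI * w
        d = a + _INVPHI * w
        fc = sse_fun(c)
        fd = sse_fun(d)
        right = fc > fd  # minimum lies in [c, b]
        a = np.where(right, c, a)
        b = np.where(right, b, d)
    return 0.5 * (a + b)


def _ir_linear_solve(y, ti, t1):
    """Profile out (a, b) of a + b exp(-TI/T1) for per-voxel T1.

    ``y``: (nv, nt), ``t1``: (nv,).  Returns (sse, a, b).
    """
    n = ti.size
    E = np.exp(-ti[None, :] / t1[:, None])
    s1e = E.sum(axis=1)
    see = (E * E).sum(axis=1)
    s1y = y.sum(axis=1)
    sey = (E * y).sum(axis=1)
    syy = (y * y).sum(axis=1)
    det = n * see - s1e**2
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (n * sey - s1e * s1y) / det
        a = (s1y - b * s1e) / n
        sse = syy - a * s1y - b * sey
    sse = np.where(np.isfinite(sse), np.maximum(sse, 0.0), np.inf)
    return sse, a, b


def _ir_fit_candidate(y, ti, bounds, grid_size=60, iters=60):
    """Full VarPro fit of one signed-data candidate; returns (sse, t1, a, b)."""
    grid = np.geomspace(bounds[0], bounds[1], grid_size)
    # coarse profile: T1 shared across voxels at each grid node
    sse_grid = np.empty((grid_size, y.shape[0]))
    for j, t1 in enumerate(grid):
        sse_grid[j], _, _ = _ir_linear_solve(y, ti, np.full(y.shape[0], t1))
    jbest = np.argmin(sse_grid, axis=0)
    lo = grid[np.maximum(jbest - 1, 0)]
    hi = grid[np.minimum(jbest + 1, grid_size - 1)]
    t1 = _golden_min(lambda t: _ir_linear_solve(y, ti, t)[0], lo, hi, iters)
    sse, a, b = _ir_linear_solve(y, ti, t1)
    return sse, t1, a, b


def fit_ir_t1(
    series: ImageSeries,
    magnitude: bool = True,
    t1_bounds: tuple[float, float] = T1_BOUNDS_MS,
) -> T1MapResult:
    """Voxel-wise three-parameter IR fit (M0, T1, inversion efficiency).

    Requires at least four distinct inversion times.  For magnitude data the
    polarity of the early-TI points is restored by residual comparison.
    """
    if series.axis_kind != "ti_ms":
        raise ValueError(f"series must have a ti_ms axis, got {series.axis_kind}")
    ti = series.axis_values
    if np.unique(ti).size < 4:
        raise ValueError(
            f"need at least 4 distinct TIs for a three-parameter fit, got {np.unique(ti).size}"
        )
    order = np.argsort(ti)
    ti = ti[order]
    ny, nx = series.grid_shape
    y0 = series.mean_over_repeats()[..., order].reshape(-1, ti.size)
    nv, nt = y0.shape

    if magnitude:
        m = np.argmin(np.abs(y0), axis=1)
        cols = np.arange(nt)[None, :]
        candidates = [
            np.where(cols < m[:, None], -y0, y0),
            np.where(cols < (m + 1)[:, None], -y0, y0),
        ]
    else:
        candidates = [y0]

    best = None
    for y in candidates:
        sse, t1, a, b = _ir_fit_candidate(y, ti, t1_bounds)
        if best is None:
            best = [sse, t1, a, b, y]
        else:
            take = sse < best[0]
            for k, new in enumerate((sse, t1, a, b, y)):
                best[k] = np.where(take if k < 4 else take[:, None], new, best[k])
    sse, t1, a, b, ywin = best

    ybar = ywin.mean(axis=1, keepdims=True)
    sstot = ((ywin - ybar) ** 2).sum(axis=1)
    scale = np.maximum(np.abs(ywin).max(axis=1), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sstot > 1e-20 * scale**2, 1.0 - sse / sstot, np.nan)
    r2 = np.clip(r2, 0.0, 1.0)

    lo, hi = t1_bounds
    converged = (
        np.isfinite(t1)
        & (t1 > lo * 1.02)
        & (t1 < hi * 0.98)
        & (a > 0)
        & (b < 0)
        & np.isfinite(r2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_eff = np.where(a != 0, -b / (2.0 * a), np.nan)

    shape = (ny, nx)
    return T1MapResult(
        m0_map=a.reshape(shape),
        t1_map=t1.reshape(shape),
        r2_map=r2.reshape(shape),
        converged_mask=converged.reshape(shape),
        inv_eff_map=inv_eff.reshape(shape),
        sse_map=sse.reshape(shape),
    )


def _vfa_sse(y, th, tr_ms, t1):
    """Profile out M0 of the SPGR model for per-voxel T1; returns (sse, m0)."""
    e1 = np.exp(-tr_ms / t1)[:, None]
    g = np.sin(th)[None, :] * (1.0 - e1) / (1.0 - e1 * np.cos(th)[None, :])
    sgy = (g * y).sum(axis=1)
    sgg = (g * g).sum(axis=1)
    syy = (y * y).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = sgy / sgg
        sse = syy - sgy**2 / sgg
    sse = np.where(np.isfinite(sse), np.maximum(sse, 0.0), np.inf)
    return sse, m0


def fit_vfa_t1(
    series: ImageSeries,
    tr_ms: float,
    t1_bounds: tuple[float, float] = T1_BOUNDS_MS,
    grid_size: int = 60,
) -> T1MapResult:
    """Voxel-wise T1 from a variable-flip-angle SPGR series.

    Initialized on a coarse T1 grid (equivalent to the classical
    S/sin-vs-S/tan linearization up to noise weighting) and refined by
    golden-section search.  When the data carry no E1 information (signal
    proportional to sin(theta)), the optimum pins to the T1 bound and the
    voxel is flagged non-converged.
    """
    if series.axis_kind != "flip_deg":
        raise ValueError(f"series must have a flip_deg axis, got {series.axis_kind}")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be > 0")
    angles = series.axis_values
    if angles.size < 2:
        raise ValueError("need at least 2 flip angles")
    if np.any((angles <= 0) | (angles >= 90)):
        raise ValueError("flip angles must lie strictly inside (0, 90) degrees")
    th = np.deg2rad(angles)
    ny, nx = series.grid_shape
    y = series.mean_over_repeats().reshape(-1, angles.size)
    nv = y.shape[0]

    grid = np.geomspace(t1_bounds[0], t1_bounds[1], grid_size)
    sse_grid = np.empty((grid_size, nv))
    for j, t1 in enumerate(grid):
        sse_grid[j], _ = _vfa_sse(y, th, tr_ms, np.full(nv, t1))
    jbest = np.argmin(sse_grid, axis=0)
    lo = grid[np.maximum(jbest - 1, 0)]
    hi = grid[np.minimum(jbest + 1, grid_size - 1)]
    t1 = _golden_min(lambda t: _vfa_sse(y, th, tr_ms, t)[0], lo, hi)
    sse, m0 = _vfa_sse(y, th, tr_ms, t1)

    ybar = y.mean(axis=1, keepdims=True)
    sstot = ((y - ybar) ** 2).sum(axis=1)
    scale = np.maximum(np.abs(y).max(axis=1), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sstot > 1e-20 * scale**2, 1.0 - sse / sstot, np.nan)
    r2 = np.clip(r2, 0.0, 1.0)

    blo, bhi = t1_bounds
    converged = (
        np.isfinite(t1) & (t1 > blo * 1.02) & (t1 < bhi * 0.98) & (m0 > 0) & np.isfinite(r2)
    )
    shape = (ny, nx)
    return T1MapResult(
        m0_map=m0.reshape(shape),
        t1_map=t1.reshape(shape),
        r2_map=r2.reshape(shape),
        converged_mask=converged.reshape(shape),
        inv_eff_map=None,
        sse_map=sse.reshape(shape),
    )
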