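"""Digital tumor phantom: synthetic acquisitions with known ground truth.

The phantom is a 2D slice holding a two-compartment elliptical tumor
(well-perfused rim, hypoperfused/necrotic core), a kidney disc as a
high-flow reference region, and homogeneous background tissue.  From one
:class:`PhantomSpec` it can emit

* a multi-TI FAIR control/label EPI pair (nonselective / slice-selective),
* an inversion-recovery series for T1app mapping at the same slice,
* a dynamic contrast-enhanced series with gamma-variate enhancement,
* non-overlapping synthetic vessel masks for histology-style metrics,

all consistent with the kinetic model used by the quantification modules, so
that forward-simulated data can be inverted and checked against the stored
:class:`PhantomTruth`.

Noise is additive zero-mean Gaussian on the magnitude signal; at the SNR of
averaged acquisitions the Rician floor is negligible and is deliberately not
modeled.  A single integer seed drives all draws, with a deterministic
sub-stream per series type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from . import asl_quant
from .series import ImageSeries

DEFAULT_ASL_TI_MS = (100.0, 350.0, 750.0, 1500.0, 2500.0, 4000.0)
DEFAULT_IR_TI_MS = (10.0, 100.0, 500.0, 1000.0, 2000.0, 5000.0, 8000.0)
DEFAULT_DCE_DT_S = 3.1
DEFAULT_BOLUS_DYNAMIC = 6

_STREAMS = {"asl": 1, "ir": 2, "dce": 3, "vessel": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class TumorGeometry:
    """Elliptical rim/core tumor in voxel coordinates (row, col)."""

    center: tuple[float, float] = (24.0, 30.0)
    rim_radii: tuple[float, float] = (14.0, 16.0)
    core_radii: tuple[float, float] = (7.0, 8.0)


@dataclass(frozen=True)
class DCECurveSpec:
    """Gamma-variate enhancement parameters per compartment.

    The curve is dSI(t) = amp * (x/(alpha*beta))^alpha * exp(alpha - x/beta)
    with x = t - onset, normalized so the peak equals ``amp`` at
    x = alpha * beta.  Onsets are bolus time plus a compartment delay.
    """

    alpha: float = 2.0
    beta_s: float = 12.0
    amp_rim: float = 1.5
    amp_core: float = 0.4
    amp_background: float = 0.15
    amp_kidney: float = 2.5
    delay_rim_s: float = 3.0
    delay_core_s: float = 9.0
    delay_background_s: float = 6.0
    delay_kidney_s: float = 1.5


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters and noise of one simulated animal.

    Flows in mL/100 g/min, T1s in ms, ``noise_sd`` as a fraction of
    ``m0_scale`` per single acquired frame.  Identical (spec, seed) pairs
    yield bit-identical outputs.
    """

    grid_shape: tuple[int, int] = (48, 64)
    pixel_size_mm: float = 0.44
    tumor: TumorGeometry = field(default_factory=TumorGeometry)
    f_rim: float = 90.0
    f_core: float = 15.0
    f_kidney: float = 250.0
    t1_rim: float = 1500.0
    t1_core: float = 1800.0
    t1_background: float = 1100.0
    t1_kidney: float = 1600.0
    m0_scale: float = 1000.0
    noise_sd: float = 0.02
    n_repeats: int = 40
    seed: int = 0
    kidney_center: tuple[float, float] = (24.0, 54.0)
    kidney_radius: float = 5.0
    dce: DCECurveSpec = field(default_factory=DCECurveSpec)

    def validate(self) -> None:
        for name in ("f_rim", "f_core", "f_kidney"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("t1_rim", "t1_core", "t1_background", "t1_kidney"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.m0_scale <= 0:
            raise ValueError("m0_scale must be > 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 4:
            raise ValueError("grid_shape must be a 2D shape of at least 4x4")
        for name in ("delay_rim_s", "delay_core_s", "delay_background_s", "delay_kidney_s"):
            if getattr(self.dce, name) < 0:
                raise ValueError(f"dce.{name} must be >= 0")
        for name in ("amp_rim", "amp_core", "amp_background", "amp_kidney"):
            if getattr(self.dce, name) < 0:
                raise ValueError(f"dce.{name} must be >= 0")
        if self.dce.alpha <= 0 or self.dce.beta_s <= 0:
            raise ValueError("dce.alpha and dce.beta_s must be > 0")


@dataclass
class PhantomTruth:
    """Ground-truth maps shared by all series simulated from one spec."""

    f_map: np.ndarray
    t1_map: np.ndarray
    m0_map: np.ndarray
    tumor_mask: np.ndarray
    core_mask: np.ndarray
    kidney_mask: np.ndarray
    dce_amplitude_map: np.ndarray
    dce_onset_s_map: np.ndarray
    dce_alpha: float
    dce_beta_s: float
    bolus_time_s: float
    pixel_size_mm: float
    vessel_mask: np.ndarray | None = None

    def t1app_map(self, lambda_part: float = 0.9) -> np.ndarray:
        """Apparent T1 (ms) implied by the truth T1 and flow maps."""
        return asl_quant.t1app_from_t1(self.t1_map, self.f_map, lambda_part)

    def dce_tmax_s_map(self) -> np.ndarray:
        """Time of peak enhancement; NaN where the amplitude is zero."""
        tmax = self.dce_onset_s_map + self.dce_alpha * self.dce_beta_s
        return np.where(self.dce_amplitude_map > 0, tmax, np.nan)

    def dce_auc_map(self, t_start_s: float, t_end_s: float) -> np.ndarray:
        """Closed-form integral of the truth enhancement over [t_start, t_end]."""
        return gamma_variate_auc(
            self.dce_amplitude_map,
            self.dce_onset_s_map,
            self.dce_alpha,
            self.dce_beta_s,
            t_start_s,
            t_end_s,
        )

    def first_enhanced_dynamic(self, dt_s: float) -> np.ndarray:
        """Index of the first dynamic with strictly positive truth enhancement."""
        r = self.dce_onset_s_map / dt_s
        r_round = np.round(r)
        on_grid = np.abs(r - r_round) < 1e-6
        return np.where(on_grid, r_round + 1, np.ceil(r)).astype(int)


def spec_from_dict(d: dict) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a (possibly nested) plain mapping.

    ``tumor`` and ``dce`` sub-mappings override fields of
    :class:`TumorGeometry` and :class:`DCECurveSpec`; tuples may be given as
    lists (e.g. from YAML).
    """
    d = dict(d)
    tumor = TumorGeometry(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.pop("tumor", {}).items()})
    dce = DCECurveSpec(**d.pop("dce", {}))
    for key in ("grid_shape", "kidney_center"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return PhantomSpec(tumor=tumor, dce=dce, **d)


def spec_to_dict(spec: PhantomSpec) -> dict:
    """Plain-dict form of a spec (JSON/YAML serializable)."""
    import dataclasses

    return dataclasses.asdict(spec)


def gamma_variate(t_s, amplitude, onset_s, alpha: float, beta_s: float):
    """Peak-normalized gamma-variate enhancement curve (broadcasts)."""
    x = np.asarray(t_s, dtype=np.float64) - np.asarray(onset_s, dtype=np.float64)
    u = np.maximum(x, 0.0) / beta_s
    return np.asarray(amplitude, dtype=np.float64) * (u / alpha) ** alpha * np.exp(alpha - u)


def gamma_variate_auc(amplitude, onset_s, alpha: float, beta_s: float, t_start_s, t_end_s):
    """Exact integral of :func:`gamma_variate` over [t_start, t_end] (dSI * s)."""
    amplitude = np.asarray(amplitude, dtype=np.float64)
    onset_s = np.asarray(onset_s, dtype=np.float64)
    u1 = np.maximum(np.asarray(t_start_s, dtype=np.float64) - onset_s, 0.0) / beta_s
    u2 = np.maximum(np.asarray(t_end_s, dtype=np.float64) - onset_s, 0.0) / beta_s
    const = beta_s * np.exp(alpha) * alpha ** (-alpha) * special.gamma(alpha + 1.0)
    return amplitude * const * (special.gammainc(alpha + 1.0, u2) - special.gammainc(alpha + 1.0, u1))


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / radii[0]) ** 2 + ((xx - center[1]) / radii[1]) ** 2 <= 1.0


def build_truth(spec: PhantomSpec, bolus_time_s: float | None = None) -> PhantomTruth:
    """Construct the ground-truth maps for a spec (no noise involved)."""
    spec.validate()
    if bolus_time_s is None:
        bolus_time_s = DEFAULT_BOLUS_DYNAMIC * DEFAULT_DCE_DT_S
    shape = tuple(spec.grid_shape)
    tumor = _ellipse_mask(shape, spec.tumor.center, spec.tumor.rim_radii)
    core = _ellipse_mask(shape, spec.tumor.center, spec.tumor.core_radii) & tumor
    kidney = _ellipse_mask(shape, spec.kidney_center, (spec.kidney_radius, spec.kidney_radius))
    if np.any(kidney & tumor):
        raise ValueError("kidney_center/kidney_radius overlap the tumor")
    rim = tumor & ~core

    f = np.zeros(shape)
    f[rim] = spec.f_rim
    f[core] = spec.f_core
    f[kidney] = spec.f_kidney
    t1 = np.full(shape, spec.t1_background)
    t1[rim] = spec.t1_rim
    t1[core] = spec.t1_core
    t1[kidney] = spec.t1_kidney
    m0 = np.full(shape, spec.m0_scale)

    d = spec.dce
    amp = np.full(shape, d.amp_background)
    amp[rim] = d.amp_rim
    amp[core] = d.amp_core
    amp[kidney] = d.amp_kidney
    onset = np.full(shape, bolus_time_s + d.delay_background_s)
    onset[rim] = bolus_time_s + d.delay_rim_s
    onset[core] = bolus_time_s + d.delay_core_s
    onset[kidney] = bolus_time_s + d.delay_kidney_s

    return PhantomTruth(
        f_map=f,
        t1_map=t1,
        m0_map=m0,
        tumor_mask=tumor,
        core_mask=core,
        kidney_mask=kidney,
        dce_amplitude_map=amp,
        dce_onset_s_map=onset,
        dce_alpha=d.alpha,
        dce_beta_s=d.beta_s,
        bolus_time_s=bolus_time_s,
        pixel_size_mm=spec.pixel_size_mm,
    )


def generate_asl_series(
    spec: PhantomSpec,
    ti_ms=DEFAULT_ASL_TI_MS,
    consts: asl_quant.ASLConstants | None = None,
) -> tuple[ImageSeries, ImageSeries, PhantomTruth]:
    """Simulate a FAIR control/label pair with one frame per (TI, repeat).

    The control series is the nonselective (global) inversion recovery of the
    tissue; the label (slice-selective) series adds the kinetic-model
    perfusion difference, so label - control equals the noise-free FAIR
    signal plus independent Gaussian noise on each frame.
    """
    consts = consts or asl_quant.DEFAULT_CONSTANTS
    truth = build_truth(spec)
    ti = np.asarray(ti_ms, dtype=np.float64)
    if ti.size == 0 or np.any(ti < 0):
        raise ValueError("ti_ms must be a non-empty list of nonnegative times")
    t1app = truth.t1app_map(consts.lambda_part)

    base_ns = truth.m0_map[..., None] * (1.0 - 2.0 * np.exp(-ti[None, None, :] / truth.t1_map[..., None]))
    dm = asl_quant.fair_delta_m_model(
        truth.f_map[..., None], truth.m0_map[..., None], t1app[..., None], ti[None, None, :], consts
    )
    base_ss = base_ns + dm

    rng = _rng(spec.seed, "asl")
    sigma = spec.noise_sd * spec.m0_scale
    frames_ns = np.tile(base_ns, (1, 1, spec.n_repeats))
    frames_ss = np.tile(base_ss, (1, 1, spec.n_repeats))
    if sigma > 0:
        frames_ns = frames_ns + rng.normal(0.0, sigma, frames_ns.shape)
        frames_ss = frames_ss + rng.normal(0.0, sigma, frames_ss.shape)

    mk = lambda data, tag: ImageSeries(
        data,
        axis_kind="ti_ms",
        axis_values=ti,
        repeats=spec.n_repeats,
        pixel_size_mm=spec.pixel_size_mm,
        provenance=f"phantom-{tag}(seed={spec.seed})",
    )
    return mk(frames_ns, "fair-nonselective"), mk(frames_ss, "fair-sliceselective"), truth


def generate_ir_series(spec: PhantomSpec, ti_ms=DEFAULT_IR_TI_MS) -> ImageSeries:
    """Simulate the magnitude inversion-recovery series used for T1app mapping.

    Per voxel: |M0 (1 - 2 exp(-TI/T1app_true))| plus Gaussian noise, where
    T1app_true follows from the truth T1 and flow maps (slice-selective
    inversion at the imaging slice).
    """
    truth = build_truth(spec)
    ti = np.asarray(ti_ms, dtype=np.float64)
    if ti.size == 0:
        raise ValueError("ti_ms must not be empty")
    if np.any(ti <= 0) or np.any(np.diff(ti) <= 0):
        raise ValueError("ti_ms must be strictly increasing and positive")
    t1app = truth.t1app_map()
    signal = np.abs(
        truth.m0_map[..., None] * (1.0 - 2.0 * np.exp(-ti[None, None, :] / t1app[..., None]))
    )
    sigma = spec.noise_sd * spec.m0_scale
    if sigma > 0:
        signal = signal + _rng(spec.seed, "ir").normal(0.0, sigma, signal.shape)
    return ImageSeries(
        signal,
        axis_kind="ti_ms",
        axis_values=ti,
        repeats=1,
        pixel_size_mm=spec.pixel_size_mm,
        provenance=f"phantom-ir(seed={spec.seed})",
    )


def generate_dce_series(
    spec: PhantomSpec,
    n_dynamics: int = 100,
    dt_s: float = DEFAULT_DCE_DT_S,
    bolus_dynamic: int = DEFAULT_BOLUS_DYNAMIC,
) -> tuple[ImageSeries, PhantomTruth]:
    """Simulate a DCE dynamic series with gamma-variate enhancement.

    SI(t) = baseline * (1 + dSI_true(t)) + noise, with the bolus injected at
    ``bolus_dynamic * dt_s`` and per-compartment onsets at or after it.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    if n_dynamics < bolus_dynamic + 2:
        raise ValueError("n_dynamics must be >= bolus_dynamic + 2")
    truth = build_truth(spec, bolus_time_s=bolus_dynamic * dt_s)
    t = np.arange(n_dynamics) * dt_s
    dsi = gamma_variate(
        t[None, None, :],
        truth.dce_amplitude_map[..., None],
        truth.dce_onset_s_map[..., None],
        truth.dce_alpha,
        truth.dce_beta_s,
    )
    si = truth.m0_map[..., None] * (1.0 + dsi)
    sigma = spec.noise_sd * spec.m0_scale
    if sigma > 0:
        si = si + _rng(spec.seed, "dce").normal(0.0, sigma, si.shape)
    series = ImageSeries(
        si,
        axis_kind="time_s",
        axis_values=t,
        repeats=1,
        pixel_size_mm=spec.pixel_size_mm,
        provenance=f"phantom-dce(seed={spec.seed})",
    )
    return series, truth


def generate_vessel_mask(
    spec: PhantomSpec,
    n_vessels: int,
    vessel_radius_px: float = 2.0,
    max_tries: int = 5000,
) -> np.ndarray:
    """Place ``n_vessels`` non-touching discs inside the tumor mask.

    Disc centers keep a separation of at least ``2 r + 2`` pixels, which
    leaves every inter-disc pixel distance >= 2 so the components stay
    disjoint under 8-connectivity.  Raises if placement fails within the
    retry budget.
    """
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    truth = build_truth(spec)
    shape = tuple(spec.grid_shape)
    mask = np.zeros(shape, dtype=bool)
    if n_vessels == 0:
        return mask
    rng = _rng(spec.seed, "vessel")
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    centers: list[tuple[float, float]] = []
    tumor_idx = np.argwhere(truth.tumor_mask)
    tries = 0
    r = float(vessel_radius_px)
    while len(centers) < n_vessels:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_vessels} non-overlapping vessels of radius {r} "
                f"after {max_tries} tries"
            )
        cy, cx = tumor_idx[rng.integers(len(tumor_idx))]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if not np.all(truth.tumor_mask[disc]):
            continue
        if any((cy - py) ** 2 + (cx - px) ** 2 < (2 * r + 2) ** 2 for py, px in centers):
            continue
        centers.append((cy, cx))
        mask |= disc
    return mask
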