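# Methods

## FAIR-ASL quantification

The perfusion signal is the repeat-averaged difference ΔM(TI) between the
slice-selective ("label") and nonselective ("control") inversion-recovery
images. We model it with the single-compartment kinetic solution at zero
arterial transit time:

    ΔM(TI) = 2 M₀ α (f/λ) · (e^(−TI/T1app) − e^(−TI/T1a)) / (1/T1a − 1/T1app)

with the removable singularity at T1app = T1a replaced by its limit
2 M₀ α (f/λ) TI e^(−TI/T1a) whenever |1/T1a − 1/T1app| < 10⁻¹⁰ /ms. The
zero-transit assumption is appropriate for thin inversion slabs in the
mouse, where spin delivery is effectively instantaneous; no transit-time
estimation is attempted.

Constants and units: λ = 0.9 mL/g (blood/tissue water partition
coefficient), T1a = 2210 ms (arterial blood at 7 T), α = 1 (adiabatic
inversion efficiency). Flow f is carried in mL/100 g/min everywhere and
converted to a rate only inside the model via f/(100·60·1000·λ) per ms.
Worked check: f = 90, T1 = 1500 ms gives f/λ = 0.0167 s⁻¹ and
T1app = 1463.4 ms.

M₀ and T1app are taken from the three-parameter IR fit of the T1-mapping
series acquired at the ASL slice: because that acquisition uses
slice-selective inversion, the fitted time constant already is the
*apparent* T1 (inflow included), and we use it directly rather than
reassembling T1app from a separately measured T1 and f. With M₀ and T1app
fixed, ΔM(TI) is linear in the single free parameter f, so the
least-squares flow estimate is the closed-form projection of ΔM onto the
unit-flow model curve; the physical bound f ≥ 0 is enforced by clamping,
which is exact for a one-parameter linear model. A sign-preserving
diagnostic mode (`allow_negative=True`) is available.

Quality control is inherited from the T1 fit: a voxel enters ROI statistics
only if its IR fit converged and has R² strictly greater than 0.9. The ROI
summary is the plain arithmetic mean/SD over included voxels, plus a
histogram (default 20 bins) to expose intratumoral heterogeneity.

## T1 mapping

Both fits use variable projection: for any fixed relaxation rate the
remaining parameters are linear, so the profiled residual is minimized over
T1 alone — first on a 60-point log grid over [50, 10000] ms, then by a
vectorized golden-section refinement (60 iterations) that drives every
voxel to the continuous optimum simultaneously. This is deterministic,
derivative-free, and has no per-voxel Python loop.

* **Inversion recovery:** S(TI) = a + b·e^(−TI/T1) with M₀ = a and
  inversion efficiency = −b/(2a). Magnitude data lose the early-TI sign;
  polarity is restored by fitting two sign-flip candidates (flip all points
  strictly before the minimum-magnitude sample, or through it) and keeping
  the lower-residual one. For noise-free data this recovers the exact signed
  curve. Requires ≥ 4 distinct TIs.
* **Variable flip angle (SPGR):** S(θ) = M₀ sinθ (1−E1)/(1−E1 cosθ),
  E1 = e^(−TR/T1), linear in M₀ at fixed E1. When the data carry no E1
  information (signal ∝ sinθ, the TR ≫ T1 limit) the optimum pins to the T1
  bound and the voxel is flagged non-converged rather than reported.

R² = 1 − SS_res/SS_tot, clipped to [0, 1]; voxels with zero total variance
(constant series) get R² = NaN and are flagged, never filled. Convergence
additionally requires T1 strictly inside the bounds (2% margin), positive
M₀ and, for IR, a negative exponential coefficient (an inversion actually
present). No B1 correction or slice-profile modeling is attempted.

## Semi-quantitative DCE

ΔSI(t) = (SI(t) − S̄I_base)/S̄I_base with the baseline mean over the
pre-bolus dynamics (default dynamics 0–5; bolus at dynamic 6, 3.1 s per
dynamic). Voxels with non-positive baseline are excluded and logged.

Arrival detection: per voxel, T0 is the first post-baseline time with
ΔSI > k·δ sustained for ≥ 2 consecutive dynamics, where δ is the SD of ΔSI
over the baseline (ddof = 1) and k = 3 by default. The persistence rule
rejects single-frame spikes. The exact threshold multiplier used in
practice varies between labs, so k is a configuration knob. In noise-free
voxels (δ = 0) the test degrades to ΔSI > 0, logged. The global bolus
arrival is the earliest per-voxel T0; AUC windows start there. Tmax is the
time of the per-voxel maximum, ties broken to the earliest occurrence.

AUC is the integral of the piecewise-linear interpolant of ΔSI (exact
trapezoid with linear interpolation at fractional window edges), over
60/90/150 s and a per-voxel to-Tmax window; units are ΔSI·s. Windows
extending past the acquisition are integrated to the end and flagged
truncated. AUC magnitudes depend on the (arbitrary) enhancement scale, so
group comparisons use scale-free percent changes. No Tofts-type modeling,
AIF estimation or gadolinium-concentration conversion is performed — the
semi-quantitative parameters are used precisely for their reproducibility.

## QC, vessel metrics, statistics

* **Jaccard:** J = |A∩B|/|A∪B|; two empty masks are defined as J = 1
  (vacuous agreement) with a warning. The overlap gate passes strictly
  above 0.6, mirroring the strictness of the R² rule. The gate is a
  descriptive filter, not an automatic exclusion.
* **Vessels:** components under 8-connectivity (stained cross-sections are
  blob-like); density = count/tissue area, size = vessel area/count,
  ratio = vessel area/tissue area, so ratio = density × size holds exactly.
  No minimum-size exclusion by default (configurable), since absolute
  counts depend on segmentation conventions that are not standardized.
* **Statistics:** two-tailed Student t-tests (scipy), two-way group×time
  ANOVA with interaction (statsmodels OLS, type-II), plus cell-wise
  contrasts: between-group t-tests at each timepoint and within-group
  paired t-tests across two timepoints when animal identities align.
  Pearson correlation with two-tailed p. Significance at p < 0.05; no
  multiple-testing correction, matching common practice for these designs.
  Tumor volume V = l·w²/2 (modified-ellipsoid caliper formula; swapped
  length/width corrected with a warning) and
  %TGI = (V_ctrl,X − V_trt,X)/(V_ctrl,X − V_ctrl,0)·100.

## The phantom: what it emulates and what it does not

A 2D 48×64 slice (0.44 mm pixels) holds an elliptical tumor with a
well-perfused rim (default 90 mL/100 g/min, T1 1500 ms) around a
hypoperfused core (15 mL/100 g/min, T1 1800 ms — the necrotic-core /
viable-periphery structure of mature xenografts), background tissue
(flow 0, T1 1100 ms) and a kidney disc (250 mL/100 g/min) as a high-flow
reference ROI. M₀ is uniform. The FAIR pair is generated from the same
kinetic model the fitter uses (nonselective recovery with intrinsic T1;
slice-selective = nonselective + ΔM), which is deliberate: it makes
forward-inverse recovery a sharp test of the estimation chain rather than
of model mismatch. Acquisition defaults follow the emulated protocol: ASL
TIs {100, 350, 750, 1500, 2500, 4000} ms × 40 repeats; IR TIs
{10, 100, 500, 1000, 2000, 5000, 8000} ms; DCE 100 dynamics at 3.1 s with
the bolus at dynamic 6.

DCE enhancement is a peak-normalized gamma-variate
amp·(x/αβ)^α·e^(α−x/β) (α = 2, β = 12 s, x = t − onset) with
compartment-specific amplitudes (rim 1.5, core 0.4, kidney 2.5,
background 0.15) and onset delays after the bolus (rim 3 s, core 9 s,
kidney 1.5 s, background 6 s). The gamma-variate was chosen because its
integral has a closed form (regularized incomplete gamma), giving an
analytic oracle for every AUC window.

Noise is additive zero-mean Gaussian on the magnitude signal with
SD = noise_sd·M₀ per frame, default noise_sd = 0.02 (SNR ≈ 50, typical of
spin-echo EPI with a dedicated surface coil at 7 T). At this SNR, and after
40 averages, the Rician floor is negligible, so no Rician correction is
applied — a deliberate simplification. The phantom also omits EPI/k-space
physics, susceptibility distortion (QC masks are warped geometrically when
needed), motion, partial-volume mixing and B1 inhomogeneity. Passing tests
therefore demonstrate the correctness of the estimation and statistics
chain under the stated noise model, not robustness to those real-world
artifacts.

One integer seed drives everything; sub-streams are derived
deterministically per series type (ASL/IR/DCE/vessels), so identical
(spec, seed) pairs are bit-identical and different series are independent.
Synthetic vessel masks place non-overlapping discs inside the tumor with
center separation ≥ 2r + 2 px, the minimum that keeps components disjoint
under 8-connectivity, and fail loudly when the requested packing does not
fit.

## Cohort simulations

`simulate_treatment_study` draws each animal's true tumor flow from a
normal distribution around its arm mean (control 92.6 mL/100 g/min;
treated = 48.4% of control, the chronic-treatment effect size) and runs the
full measurement chain per animal on a compact 16×20 phantom. The
between-animal coefficient of variation defaults to 30%: a power analysis
at that CV gives a two-sample t-test at n = 10 per arm > 99% power for the
halving of perfusion the study is designed around, so the simulated design
is adequately powered rather than marginal; real xenograft cohorts can be
more variable (CVs of 35–45% are common), in which case power at n = 10
drops below 90% — the CV is an explicit argument for exploring that.
Measurement noise contributes little at this grid size (ROI-mean SE
≈ 1 mL/100 g/min), so study power is dominated by the biological CV, as in
real cohorts.

## Numerical choices and conventions

* ΔM sign: slice-selective minus nonselective (positive for inflow);
  `compute_delta_m(control, label)` takes the nonselective series as
  control.
* Frame layout: repeat-major (all TIs of repeat 0, then repeat 1, …);
  sidecars declare axis length × repeats = frame count and readers reject
  mismatches.
* Strict inequalities at both quality gates (R² > 0.9, J > 0.6).
* Golden-section tolerance: 60 iterations shrink the bracket by ~3×10⁻¹³,
  i.e. T1 is limited by the SSE noise floor, not the search; noise-free
  recovery is exact to ≈ 10⁻⁵ relative.
* The kinetic-model singularity threshold (10⁻¹⁰ /ms on the rate
  difference) keeps the general branch free of catastrophic cancellation.
* Histogram bin count (20) and bounds are taken from the included voxels;
  counts always sum to the included-voxel count.
* Times and TIs are physical units (ms, s, degrees) at every interface;
  voxel indices are 0-based; masks are stored as uint8 NIfTI; series as
  float64 NIfTI (bit-exact round-trip).

## Known limitations

λ is assumed constant at 0.9 mL/g, though tumor tissue can deviate
substantially and regionally; single 2D slice, no 3D labeling geometry; no
registration between modalities (the Jaccard gate only measures the
consequence of distortion); vessel metrics depend on the upstream
segmentation and are not comparable across segmentation pipelines in
absolute terms; the two-way ANOVA treats animals as independent between
timepoints except in the explicit paired contrasts.
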