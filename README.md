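# tumorperf

Quantitative tumor-perfusion MRI analysis for preclinical treatment-response
studies, built around arterial spin labeling (ASL) with a FAIR labeling
scheme and semi-quantitative dynamic contrast-enhanced (DCE) MRI. The
package targets the workflow used to detect antiangiogenic drug effects in
xenograft models: measure tumor blood flow absolutely with ASL, corroborate
with DCE enhancement areas, gate out distorted acquisitions, and test
control-vs-treated group differences — all exercisable end to end on a
digital tumor phantom with known ground truth, so every stage is testable
without any scanner data.

## What it computes

**FAIR-ASL blood flow.** FAIR alternates slice-selective and nonselective
(global) inversions; their difference ΔM(TI) across inversion times carries
the perfusion signal. With zero transit time the kinetic model is

    ΔM(TI) = 2 M₀ α (f/λ) · (e^(−TI/T1app) − e^(−TI/T1a)) / (1/T1a − 1/T1app),
    1/T1app = 1/T1 + f/λ

with partition coefficient λ = 0.9 mL/g, arterial blood T1a = 2210 ms at
7 T, inversion efficiency α = 1. M₀ and T1app come from a voxel-wise
three-parameter inversion-recovery fit (`relaxometry.fit_ir_t1`); flow f
(mL/100 g/min) is then the single free parameter of a least-squares fit,
with voxels kept only when the T1 fit has R² > 0.9 (strict). A
variable-flip-angle SPGR fit (`fit_vfa_t1`) is included for DCE T1 mapping.

**Semi-quantitative DCE.** Enhancement ΔSI(t) = (SI(t) − S̄I_base)/S̄I_base;
per-voxel bolus-arrival time T0 (first sustained crossing of k·δ above
baseline, δ = baseline SD), time of maximum enhancement Tmax, and
trapezoidal areas under ΔSI over 60/90/150 s and to-Tmax windows after the
global bolus arrival.

**QC, histology, statistics.** Jaccard overlap between EPI- and FLASH-drawn
ROIs with a strict J > 0.6 gate; vessel density / size / area-ratio from
binary vessel masks (8-connected components); caliper tumor volume
V = l·w²/2, tumor growth inhibition, percent changes, two-sample t-tests,
two-way group×time ANOVA with cell contrasts, and Pearson correlation.

**Digital phantom.** A rim/core elliptical tumor (well-perfused rim,
hypoperfused core) plus a kidney reference disc, emitting FAIR control/label
pairs, IR series, gamma-variate DCE dynamics and synthetic vessel masks —
all with stored truth maps and closed-form DCE integrals for oracle tests.

## Worked example

```python
from tumorperf import (PhantomSpec, generate_asl_series, generate_ir_series,
                       fit_ir_t1, compute_delta_m, fit_perfusion)

spec = PhantomSpec(seed=42)            # 48x64 slice, rim 90 / core 15 mL/100 g/min
control, label, truth = generate_asl_series(spec)   # 6 TIs x 40 repeats
t1fit = fit_ir_t1(generate_ir_series(spec))         # 7-TI three-parameter IR fit
pm = fit_perfusion(compute_delta_m(control, label), t1fit,
                   roi_mask=truth.tumor_mask)
rim = truth.tumor_mask & ~truth.core_mask & pm.inclusion_mask
core = truth.core_mask & pm.inclusion_mask
print(f"tumor ROI mean flow: {pm.roi_mean:.1f} +/- {pm.roi_sd:.1f} mL/100 g/min "
      f"({int(pm.stats_mask.sum())} voxels)")
print(f"rim mean: {pm.f_map[rim].mean():.1f} (true 90.0)   "
      f"core mean: {pm.f_map[core].mean():.1f} (true 15.0)")
```

prints

```
tumor ROI mean flow: 71.4 +/- 33.9 mL/100 g/min (697 voxels)
rim mean: 90.1 (true 90.0)   core mean: 15.6 (true 15.0)
```

The ROI mean (71.4) sits between the rim and core truth values because the
tumor ROI mixes both compartments — exactly the heterogeneity the histogram
in `PerfusionMap` is meant to expose; the per-compartment means recover the
injected flows to within the noise of 40 averaged repeats.

The same pipeline is scriptable from the shell:

```
tumorperf simulate --seed 1 --out run/        # phantom ASL + IR + DCE + truth
tumorperf fit-t1 ir --series run/ir.nii --out run/t1
tumorperf fit-asl --control run/asl_control.nii --label run/asl_label.nii \
    --t1map run/t1/t1_map.nii --m0map run/t1/m0_map.nii --r2map run/t1/r2_map.nii \
    --roi run/tumor_mask.nii --out run/asl
tumorperf dce --dynamics run/dce.nii --out run/dce
```

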