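"""Vessel quantification from binary vessel masks.

Given a stained-vessel segmentation and a tissue mask, computes the three
standard microvascularity summaries: vessel density (vessels per mm^2 of
tissue), vessel size (mean area per vessel, mm^2) and area ratio (vessel
area fraction of the tissue).  Vessels are connected components under
8-connectivity, since stained cross-sections are blob-like.  The identity
``area_ratio == vessel_density * vessel_size`` holds exactly by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure


@dataclass(frozen=True)
class VesselMetrics:
    """Microvascularity summary of one section.

    ``vessel_size_mm2`` is NaN (undefined) when the mask holds no vessels.
    """

    n_vessels: int
    vessel_density_per_mm2: float
    vessel_size_mm2: float
    area_ratio: float
    tissue_area_mm2: float


def vessel_metrics(
    vessel_mask: np.ndarray,
    tissue_mask: np.ndarray,
    pixel_size_mm: float,
    min_size_px: int = 0,
) -> VesselMetrics:
    """Count vessels and compute density / size / area-ratio metrics.

    ``min_size_px`` optionally drops components smaller than the given pixel
    count (no exclusion by default).
    """
    vessel = np.asarray(vessel_mask).astype(bool)
    tissue = np.asarray(tissue_mask).astype(bool)
    if vessel.shape != tissue.shape:
        raise ValueError(f"mask shapes differ: {vessel.shape} vs {tissue.shape}")
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be > 0")
    if not tissue.any():
        raise ValueError("tissue mask is empty")
    if np.any(vessel & ~tissue):
        raise ValueError("vessel mask must lie inside the tissue mask")

    labels = measure.label(vessel, connectivity=2)  # 8-connectivity
    if min_size_px > 0 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_size_px)
        labels[np.isin(labels, small[small > 0])] = 0
        labels = measure.label(labels > 0, connectivity=2)
    n = int(labels.max())
    px_area = pixel_size_mm**2
    tissue_area = float(tissue.sum()) * px_area
    vessel_area = float(np.sum(labels > 0)) * px_area
    density = n / tissue_area
    size = vessel_area / n if n > 0 else float("nan")
    ratio = vessel_area / tissue_area
    return VesselMetrics(
        n_vessels=n,
        vessel_density_per_mm2=density,
        vessel_size_mm2=size,
        area_ratio=ratio,
        tissue_area_mm2=tissue_area,
    )
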