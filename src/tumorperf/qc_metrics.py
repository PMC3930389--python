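"""Distortion / overlap quality control via the Jaccard index.

EPI acquisitions are prone to susceptibility distortion; the overlap between
a tumor ROI drawn on the EPI image and the same ROI drawn on an undistorted
FLASH image quantifies its severity.  J = |A n B| / |A u B| ranges from 0 to
1, with 1 meaning perfect overlap; values above 0.6 indicate a strong degree
of overlap.
"""

from __future__ import annotations

import warnings

import numpy as np


def jaccard_index(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks on the same grid.

    Two empty masks are defined as J = 1 (vacuous perfect agreement) with a
    warning, rather than NaN.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.sum(a | b)
    if union == 0:
        warnings.warn("jaccard_index: both masks empty; returning 1.0", stacklevel=2)
        return 1.0
    return float(np.sum(a & b) / union)


def qc_gate(j: float, threshold: float = 0.6) -> bool:
    """Pass/fail overlap gate: pass iff J is strictly greater than the threshold."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard index must be in [0, 1], got {j}")
    return j > threshold
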