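"""In-memory container for 2D MRI slice series with a per-frame physical axis.

A series is a stack of 2D frames acquired while one acquisition parameter is
varied: the inversion time (``ti_ms``) for inversion-recovery / ASL data, the
dynamic time (``time_s``) for DCE data, or the excitation flip angle
(``flip_deg``) for variable-flip-angle T1 mapping.  Repeated measurements
(signal averages) are stored as extra frames, ordered repeat-major: frame
``r * n_axis + i`` holds the ``i``-th axis value of repeat ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_KINDS = ("ti_ms", "time_s", "flip_deg")


@dataclass
class ImageSeries:
    """A 2D slice acquired repeatedly along one physical axis.

    Parameters
    ----------
    data:
        Array of shape ``(ny, nx, n_frames)`` with
        ``n_frames == len(axis_values) * repeats``.
    axis_kind:
        One of ``"ti_ms"``, ``"time_s"``, ``"flip_deg"``.
    axis_values:
        Physical value of each axis position (ms, s or degrees).
    repeats:
        Number of repeated measurements (averages) per axis value.
    pixel_size_mm:
        In-plane pixel size.
    provenance:
        Free-text note on where the data came from (generator spec, file, ...).
    """

    data: np.ndarray
    axis_kind: str
    axis_values: np.ndarray
    repeats: int = 1
    pixel_size_mm: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.axis_values = np.atleast_1d(np.asarray(self.axis_values, dtype=np.float64))
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"axis_kind must be one of {AXIS_KINDS}, got {self.axis_kind!r}")
        if self.data.ndim != 3:
            raise ValueError(f"data must be (ny, nx, n_frames), got shape {self.data.shape}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        expected = self.axis_values.size * self.repeats
        if self.data.shape[-1] != expected:
            raise ValueError(
                f"frame count {self.data.shape[-1]} does not equal "
                f"axis length {self.axis_values.size} x repeats {self.repeats} = {expected}"
            )

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_axis(self) -> int:
        return int(self.axis_values.size)

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[-1])

    def frames_by_axis(self) -> np.ndarray:
        """Reshape to ``(ny, nx, repeats, n_axis)``."""
        ny, nx = self.grid_shape
        return self.data.reshape(ny, nx, self.repeats, self.n_axis)

    def mean_over_repeats(self) -> np.ndarray:
        """Average over repeats, returning ``(ny, nx, n_axis)``."""
        if self.repeats == 1:
            return self.data.copy()
        return self.frames_by_axis().mean(axis=2)
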