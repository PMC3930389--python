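"""ROI summaries, tumor-growth quantities and group statistics.

Holds the caliper tumor-volume formula, tumor growth inhibition (TGI),
percent-change comparisons between treatment groups, two-sample and two-way
(group x time) significance tests, and Pearson correlation between imaging
readouts.  Animal-level records travel as a pandas DataFrame with one row
per (animal, timepoint); see :data:`RECORD_COLUMNS` for the column
dictionary.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

ALPHA = 0.05

#: column dictionary for animal-record tables
RECORD_COLUMNS = {
    "animal": "animal identifier (one row per animal and timepoint)",
    "group": "treatment arm: control | treated",
    "timepoint": "measurement time label, e.g. 0h, 24h, chronic",
    "roi_mean_f": "tumor-ROI mean blood flow, mL/100 g/min",
    "roi_auc60": "tumor-ROI mean DCE AUC60, dSI*s",
    "length_mm": "caliper tumor length (longest side), mm",
    "width_mm": "caliper tumor width (perpendicular), mm",
    "vessel_density_per_mm2": "histology vessel density",
    "vessel_size_mm2": "histology mean vessel size",
    "area_ratio": "histology vessel area fraction",
}


@dataclass
class AnimalRecord:
    """One animal at one timepoint; optional measures default to NaN."""

    animal: str
    group: str
    timepoint: str
    roi_mean_f: float = float("nan")
    roi_auc60: float = float("nan")
    length_mm: float = float("nan")
    width_mm: float = float("nan")
    vessel_density_per_mm2: float = float("nan")
    vessel_size_mm2: float = float("nan")
    area_ratio: float = float("nan")


def records_to_frame(records) -> pd.DataFrame:
    """Build a group table from AnimalRecord objects (or dicts)."""
    rows = [asdict(r) if isinstance(r, AnimalRecord) else dict(r) for r in records]
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["animal", "timepoint"])
    if dup.any():
        raise ValueError(f"duplicate (animal, timepoint) rows: {df.loc[dup, 'animal'].tolist()}")
    return df


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume V = length * width^2 / 2 (mm^3).

    Length is the longest side, width the perpendicular; swapped inputs are
    corrected with a warning.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("length and width must be > 0")
    if width_mm > length_mm:
        warnings.warn("width > length; swapping to keep length the longest side", stacklevel=2)
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm**2 / 2.0


def tgi(v_ctrl_dayx: float, v_trt_dayx: float, v_ctrl_day0: float) -> float:
    """Tumor growth inhibition in percent.

    %TGI = (V_ctrl,dayX - V_trt,dayX) / (V_ctrl,dayX - V_ctrl,day0) * 100;
    values above 100% indicate regression below the baseline volume.
    """
    denom = v_ctrl_dayx - v_ctrl_day0
    if denom == 0:
        raise ValueError("control volume unchanged from baseline; TGI undefined")
    return (v_ctrl_dayx - v_trt_dayx) / denom * 100.0


def percent_change(reference: float, comparison: float) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return (comparison - reference) / reference * 100.0


def group_summary(table: pd.DataFrame, measure: str, by=("group",)) -> pd.DataFrame:
    """Per-group mean, SD and n for one measure."""
    return (
        table.groupby(list(by))[measure]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )


def _check_cells(table, measure, cols):
    counts = table.dropna(subset=[measure]).groupby(cols, observed=True)[measure].count()
    for cell, n in counts.items():
        if n < 2:
            raise ValueError(f"cell {cell} has fewer than 2 animals with {measure}")
    if counts.empty:
        raise ValueError(f"no complete cells for measure {measure}")
    return counts


def compare_groups(
    table: pd.DataFrame,
    measure: str,
    design: str = "two-sample",
    group_col: str = "group",
    time_col: str = "timepoint",
) -> dict:
    """Group comparison for one measure.

    ``two-sample``: two-tailed Student t-test between the two groups.
    ``two-way``: group x time ANOVA with interaction, plus cell-wise
    contrasts (between groups at each timepoint; across time within each
    group, paired on the animal when both timepoints are present).
    Significance is judged at p < 0.05.
    """
    df = table.dropna(subset=[measure])
    groups = sorted(df[group_col].unique())
    if design == "two-sample":
        if len(groups) != 2:
            raise ValueError(f"two-sample design needs exactly 2 groups, got {groups}")
        _check_cells(df, measure, [group_col])
        a = df.loc[df[group_col] == groups[0], measure].to_numpy()
        b = df.loc[df[group_col] == groups[1], measure].to_numpy()
        t, p = sps.ttest_ind(a, b)
        return {
            "design": design,
            "measure": measure,
            "groups": groups,
            "means": {groups[0]: float(a.mean()), groups[1]: float(b.mean())},
            "sds": {groups[0]: float(a.std(ddof=1)), groups[1]: float(b.std(ddof=1))},
            "t": float(t),
            "p": float(p),
            "df": int(a.size + b.size - 2),
            "significant": bool(p < ALPHA),
        }
    if design == "two-way":
        _check_cells(df, measure, [group_col, time_col])
        data = df.rename(columns={measure: "_y", group_col: "_g", time_col: "_t"})
        model = ols("_y ~ C(_g) * C(_t)", data=data).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        contrasts = {}
        for tp in sorted(df[time_col].unique()):
            sub = df[df[time_col] == tp]
            arrs = [sub.loc[sub[group_col] == g, measure].to_numpy() for g in groups]
            if all(a.size >= 2 for a in arrs) and len(arrs) == 2:
                t, p = sps.ttest_ind(*arrs)
                contrasts[f"between-groups@{tp}"] = {"t": float(t), "p": float(p)}
        times = sorted(df[time_col].unique())
        if len(times) == 2 and "animal" in df.columns:
            for g in groups:
                sub = df[df[group_col] == g]
                wide = sub.pivot(index="animal", columns=time_col, values=measure).dropna()
                if len(wide) >= 2:
                    t, p = sps.ttest_rel(wide[times[0]], wide[times[1]])
                    contrasts[f"within-{g}:{times[0]}-vs-{times[1]}"] = {
                        "t": float(t),
                        "p": float(p),
                        "paired": True,
                    }
        p_named = {
            "group": float(anova.loc["C(_g)", "PR(>F)"]),
            "time": float(anova.loc["C(_t)", "PR(>F)"]),
            "interaction": float(anova.loc["C(_g):C(_t)", "PR(>F)"]),
        }
        return {
            "design": design,
            "measure": measure,
            "anova": anova,
            "p": p_named,
            "contrasts": contrasts,
            "significant": {k: bool(v < ALPHA) for k, v in p_named.items()},
        }
    raise ValueError(f"design must be 'two-sample' or 'two-way', got {design!r}")


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with two-tailed p between paired per-animal values."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
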